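"""Core definition of the Zipf / log-series abundance-distribution continuum.

A single one-parameter family of heavy-tailed distributions on n >= 1,

    q(n) = k * n**-1 * exp(-lam * (n**beta - 1) / beta),

interpolates between two classic abundance patterns:

* ``beta -> 0``: the pure power law q(n) = lam * n**-(1 + lam).  With the
  average-abundance constraint driving lam -> 1 this is Zipf's law
  (rank-size slope of minus one).
* ``beta = 1``: the log series q(n) ∝ p**n / n with p = exp(-lam), the
  canonical species-abundance distribution of ecology.

The family arises by writing a probability pattern generically as
k * exp(-lam * T) with scale function T = (exp(beta * w) - 1) / beta on an
underlying process scale w = r = log n.  ``k`` adjusts so total probability
is one; ``lam`` adjusts so the average abundance matches its conserved
value.  Conservation of those two quantities makes the pattern invariant
to affine maps T -> a + b*T, which is checked numerically here rather than
derived symbolically.

Intermediate ``beta`` gives distributions that mix the two endpoint
behaviours; ``beta > 1`` is permitted numerically but lies outside the
Zipf <-> log-series continuum and is flagged by :func:`outside_continuum`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from scipy import integrate, optimize

__all__ = [
    "BETA_SWITCH",
    "QUAD_RTOL",
    "ScaleFamily",
    "AbundanceDistribution",
    "DiscreteLogSeries",
    "generic_T",
    "scale_T_n",
    "normalization_constant",
    "pdf",
    "logpdf",
    "cdf",
    "survival",
    "mean_abundance",
    "solve_lambda",
    "logseries_pmf",
    "logseries_mean",
    "change_of_variable_check",
    "affine_invariance_check",
    "outside_continuum",
]

# Below this curvature the direct formula (e**(beta*w) - 1)/beta loses more
# precision in double arithmetic than the series limit branch, so we switch.
BETA_SWITCH = 1e-6

# Relative tolerance for the adaptive quadratures behind k, cdf and moments.
QUAD_RTOL = 1e-11

_QUAD_LIMIT = 200


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


# ---------------------------------------------------------------------------
# Scale functions
# ---------------------------------------------------------------------------

def generic_T(w, beta: float):
    """Generic affine-invariant scale T(w) = (exp(beta*w) - 1) / beta.

    For ``beta`` below :data:`BETA_SWITCH` the analytic limit branch
    ``w + beta*w**2/2`` is used (T -> w as beta -> 0); the two branches
    agree across the threshold to better than 1e-9 for abs(w) <= 10.

    Parameters
    ----------
    w : float or array_like
        Value on the underlying (process) scale.
    beta : float
        Curvature parameter, must be >= 0.
    """
    _require(beta >= 0.0, f"beta must be >= 0, got {beta}")
    w = np.asarray(w, dtype=float)
    if beta < BETA_SWITCH:
        out = w * (1.0 + 0.5 * beta * w)
    else:
        # overflow to +inf deep in the tail is benign: e^{-lam T} -> 0
        with np.errstate(over="ignore"):
            out = np.expm1(beta * w) / beta
    return out if out.ndim else float(out)


def scale_T_n(n, beta: float, lam: float):
    """Affine-invariant scale on the abundance axis.

    T_n = log(n)/lam + (n**beta - 1)/beta, combining the logarithmic
    (process) part and the power part whose relative weight is set by
    ``beta``.  T_n(1) = 0 for every parameter choice.  At the beta -> 0
    endpoint with lam = 1 the scale collapses to 2*log(n).
    """
    _require(lam > 0.0, f"lam must be > 0, got {lam}")
    n = np.asarray(n, dtype=float)
    _require(bool(np.all(n >= 1.0)), "abundance n must be >= 1")
    out = np.log(n) / lam + generic_T(np.log(n), beta)
    return out if np.ndim(out) else float(out)


def outside_continuum(beta: float) -> bool:
    """True when beta lies outside the Zipf (0) <-> log-series (1) range."""
    return beta < 0.0 or beta > 1.0


# ---------------------------------------------------------------------------
# Normalization and density
# ---------------------------------------------------------------------------

def _neg_lam_T(u, beta: float, lam: float):
    """Exponent -lam * T(u) of the process-scale density at u = log n."""
    return -lam * generic_T(u, beta)


def normalization_constant(beta: float, lam: float) -> float:
    """Constant k making ∫₁^∞ k n⁻¹ exp(-lam (n^beta - 1)/beta) dn = 1.

    k always adjusts so total probability is conserved.  beta = 0 has the
    closed form k = lam (pure power law on [1, inf), integrable only for
    lam > 0).  For beta > 0 the integral is computed after the substitution
    u = log n, which turns the integrand into exp(-lam*T(u)) on [0, inf)
    and removes the 1/n singularity-like weighting.
    """
    _require(beta >= 0.0, f"beta must be >= 0, got {beta}")
    if lam <= 0.0:
        raise ValueError(
            "non-integrable parameters: lam must be > 0 so that total "
            f"probability on [1, inf) is finite (got lam={lam})"
        )
    if beta < BETA_SWITCH:
        # beta -> 0 limit: integrand exp(-lam*u) integrates to 1/lam.
        # Keep the limit-branch correction consistent with generic_T.
        if beta == 0.0:
            return lam
    val, _ = integrate.quad(
        lambda u: math.exp(_neg_lam_T(u, beta, lam)),
        0.0,
        np.inf,
        epsabs=0.0,
        epsrel=QUAD_RTOL,
        limit=_QUAD_LIMIT,
    )
    return 1.0 / val


@dataclass(frozen=True)
class ScaleFamily:
    """The generic scale T(w) together with its affine constants.

    ``a`` and ``b`` record a shift/stretch T -> a + b*T of the scale;
    the normalized probability pattern is invariant to them (k and lam
    reabsorb the transformation), which :func:`affine_invariance_check`
    verifies numerically.
    """

    beta: float
    a: float = 0.0
    b: float = 1.0

    def __post_init__(self) -> None:
        _require(self.beta >= 0.0, f"beta must be >= 0, got {self.beta}")
        _require(self.b > 0.0, f"stretch b must be > 0, got {self.b}")

    def T(self, w):
        return self.a + self.b * generic_T(w, self.beta)


@dataclass(frozen=True)
class AbundanceDistribution:
    """A member of the continuum: density k n⁻¹ e^{-λ(n^β-1)/β} on n >= 1.

    Parameters
    ----------
    beta : float
        Curvature of the defining scale; 0 is the Zipf / power-law
        endpoint, 1 the log-series endpoint.
    lam : float
        Constraint multiplier (> 0); adjusts to hold the average
        abundance at its conserved value.

    The normalization constant ``k`` is derived state, recomputed from
    (beta, lam), never user-settable.
    """

    beta: float
    lam: float
    n_min: float = field(default=1.0, init=False)

    def __post_init__(self) -> None:
        _require(self.beta >= 0.0, f"beta must be >= 0, got {self.beta}")
        _require(self.lam > 0.0, f"lam must be > 0, got {self.lam}")

    @cached_property
    def k(self) -> float:
        return normalization_constant(self.beta, self.lam)

    # -- density ----------------------------------------------------------

    def logpdf(self, n):
        n = np.asarray(n, dtype=float)
        _require(bool(np.all(n >= 1.0)), "abundance n must be >= 1")
        u = np.log(n)
        out = math.log(self.k) - u - self.lam * generic_T(u, self.beta)
        return out if np.ndim(out) else float(out)

    def pdf(self, n):
        out = np.exp(self.logpdf(n))
        return out if np.ndim(out) else float(out)

    # -- distribution function -------------------------------------------

    def _mass(self, u_lo: float, u_hi: float) -> float:
        """Probability mass between abundances e^u_lo and e^u_hi."""
        val, _ = integrate.quad(
            lambda u: math.exp(_neg_lam_T(u, self.beta, self.lam)),
            u_lo,
            u_hi,
            epsabs=0.0,
            epsrel=QUAD_RTOL,
            limit=_QUAD_LIMIT,
        )
        return self.k * val

    def cdf(self, n):
        n = np.asarray(n, dtype=float)
        _require(bool(np.all(n >= 1.0)), "abundance n must be >= 1")
        if self.beta < BETA_SWITCH and self.beta == 0.0:
            out = -np.expm1(-self.lam * np.log(n))
        else:
            out = np.vectorize(lambda x: self._mass(0.0, math.log(x)))(n)
        return out if np.ndim(out) else float(out)

    def survival(self, n):
        n = np.asarray(n, dtype=float)
        _require(bool(np.all(n >= 1.0)), "abundance n must be >= 1")
        if self.beta == 0.0:
            out = np.exp(-self.lam * np.log(n))
        else:
            out = np.vectorize(
                lambda x: self._mass(math.log(x), np.inf)
            )(n)
        return out if np.ndim(out) else float(out)

    # -- moments -----------------------------------------------------------

    def mean(self) -> float:
        return mean_abundance(self)

    def scale_T(self, n):
        return scale_T_n(n, self.beta, self.lam)


def pdf(n, dist: AbundanceDistribution):
    """Density of ``dist`` at abundance ``n`` (per unit n)."""
    return dist.pdf(n)


def logpdf(n, dist: AbundanceDistribution):
    """log density; stable for large n where pdf underflows."""
    return dist.logpdf(n)


def cdf(n, dist: AbundanceDistribution):
    """P(N <= n); 0 at the lower support bound n = 1."""
    return dist.cdf(n)


def survival(n, dist: AbundanceDistribution):
    """P(N > n) = 1 - cdf; beta = 0 closed form n**-lam."""
    return dist.survival(n)


def mean_abundance(dist: AbundanceDistribution) -> float:
    """Average abundance ∫₁^∞ n q(n) dn, or +inf when it diverges.

    beta = 0 with lam <= 1 (Zipf's law itself at lam = 1) has a divergent
    mean; this is reported as ``math.inf``, a legitimate state of the
    family, never an exception.  beta = 0, lam > 1 has the closed form
    lam / (lam - 1).  For beta > 0 the integrand exp(u - lam*T(u)) is
    integrated on the u = log n axis around its analytic maximum.
    """
    beta, lam = dist.beta, dist.lam
    if beta == 0.0:
        return lam / (lam - 1.0) if lam > 1.0 else math.inf

    def phi(u):  # log integrand of k * ∫ e^{u - lam T(u)} du
        return u - lam * generic_T(u, beta)

    # phi'(u) = 1 - lam * e^{beta u}: the integrand peaks at u* > 0
    # whenever lam < 1, otherwise decays from u = 0.
    if beta < BETA_SWITCH:
        u_peak = 0.0 if lam >= 1.0 else math.log(1.0 / lam) / max(beta, 1e-300)
    else:
        u_peak = 0.0 if lam >= 1.0 else math.log(1.0 / lam) / beta
    if phi(u_peak) > 700.0:
        # Mean exceeds the double-precision range: report divergence-in-
        # practice as the distinguished infinite state.
        return math.inf
    # Find where the log integrand has fallen 60 nats below its peak.
    u_hi = u_peak + 1.0
    while phi(u_hi) > phi(u_peak) - 60.0:
        u_hi = u_peak + 2.0 * (u_hi - u_peak)
    pieces = [0.0, u_peak, u_hi] if u_peak > 0.0 else [0.0, u_hi]
    total = 0.0
    for lo, hi in zip(pieces[:-1], pieces[1:]):
        val, _ = integrate.quad(
            lambda u: math.exp(phi(u)),
            lo,
            hi,
            epsabs=0.0,
            epsrel=QUAD_RTOL,
            limit=_QUAD_LIMIT,
        )
        total += val
    return dist.k * total


def solve_lambda(beta: float, mean_target: float) -> float:
    """Constraint multiplier lam attaining a given average abundance.

    beta = 0 has the printed closed form lam = 1 / (1 - 1/<n>); as the
    target mean grows, lam -> 1, which is Zipf's law.  For beta > 0 the
    map lam -> mean is strictly decreasing, so a bracketed root-find
    (Brent) recovers lam to 1e-8 relative.
    """
    _require(beta >= 0.0, f"beta must be >= 0, got {beta}")
    if mean_target <= 1.0:
        raise ValueError(
            f"mean_target must exceed 1 (support starts at 1), got {mean_target}"
        )
    if beta == 0.0:
        return 1.0 / (1.0 - 1.0 / mean_target)

    def excess(lam: float) -> float:
        return mean_abundance(AbundanceDistribution(beta, lam)) - mean_target

    lo, hi = 1e-6, 64.0
    tries = 0
    while not (math.isinf(excess(lo)) or excess(lo) > 0.0) and tries < 8:
        lo /= 16.0
        tries += 1
    while excess(hi) > 0.0 and hi < 1e9:
        hi *= 8.0
    f_lo = excess(lo)
    f_hi = excess(hi)
    if not ((math.isinf(f_lo) or f_lo > 0.0) and f_hi < 0.0):
        raise RuntimeError(
            f"could not bracket lam for beta={beta}, mean={mean_target}: "
            f"tried [{lo}, {hi}] with excess ({f_lo}, {f_hi})"
        )

    def finite_excess(lam: float) -> float:
        e = excess(lam)
        return 1e308 if math.isinf(e) else e

    return float(optimize.brentq(finite_excess, lo, hi, rtol=1e-10, xtol=1e-12))


# ---------------------------------------------------------------------------
# Discrete log series
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiscreteLogSeries:
    """Exact integer-support log series q_n = k p^n / n, n = 1, 2, ...

    The normalization k = -1/log(1-p) follows from the log-series identity
    sum p^n/n = -log(1-p).  Links to the continuum's beta = 1 member by
    p = exp(-lam).
    """

    p: float

    def __post_init__(self) -> None:
        _require(0.0 < self.p < 1.0, f"p must lie in (0,1), got {self.p}")

    @cached_property
    def k(self) -> float:
        return -1.0 / math.log1p(-self.p)

    def pmf(self, n):
        n = np.asarray(n)
        _require(bool(np.all(n >= 1)), "n must be >= 1")
        _require(bool(np.all(np.equal(np.mod(n, 1), 0))), "n must be integer")
        out = self.k * np.power(self.p, n.astype(float)) / n.astype(float)
        return out if np.ndim(out) else float(out)

    def mean(self) -> float:
        # sum n * k p^n / n = k p / (1 - p)
        return self.k * self.p / (1.0 - self.p)

    @property
    def lam(self) -> float:
        """Intensity of the matching continuum member: p = exp(-lam)."""
        return -math.log(self.p)


def logseries_pmf(n, p: float):
    """P(N = n) under the discrete log series with parameter p in (0,1)."""
    return DiscreteLogSeries(p).pmf(n)


def logseries_mean(p: float) -> float:
    """Mean p / ((1-p) * (-log(1-p))) of the discrete log series."""
    return DiscreteLogSeries(p).mean()


# ---------------------------------------------------------------------------
# Executable identity checks
# ---------------------------------------------------------------------------

def change_of_variable_check(n, dist: AbundanceDistribution):
    """Residual of the process-scale <-> abundance-scale change of variable.

    The process-scale density q_r(r) = k exp(-lam*T(r)) at r = log n,
    multiplied by the Jacobian dr/dn = 1/n, must reproduce the abundance
    density q_n(n) exactly.  Returns |q_r(log n)/n - q_n(n)|.
    """
    n = np.asarray(n, dtype=float)
    _require(bool(np.all(n >= 1.0)), "abundance n must be >= 1")
    r = np.log(n)
    q_r = dist.k * np.exp(-dist.lam * generic_T(r, dist.beta))
    out = np.abs(q_r / n - dist.pdf(n))
    return out if np.ndim(out) else float(out)


def affine_invariance_check(
    dist: AbundanceDistribution,
    a: float,
    b: float,
    n_grid=None,
) -> float:
    """Max density discrepancy under the affine map T -> a + b*T.

    Conserved total probability absorbs the shift a into k
    (k = k_a e^{-lam a}); the conserved average absorbs the stretch b into
    lam (lam = lam_b b, i.e. the transformed scale pairs with lam/b).  The
    transformed density is rebuilt with T' = a + b*T, lam' = lam/b and a
    freshly renormalized k', and compared with the original on a grid.
    """
    _require(b > 0.0, f"stretch b must be > 0, got {b}")
    if n_grid is None:
        n_grid = np.logspace(0.0, 4.0, 41)
    lam_p = dist.lam / b

    def integrand(u: float) -> float:
        return math.exp(-lam_p * (a + b * generic_T(u, dist.beta)))

    val, _ = integrate.quad(
        integrand, 0.0, np.inf, epsabs=0.0, epsrel=QUAD_RTOL, limit=_QUAD_LIMIT
    )
    k_p = 1.0 / val
    u = np.log(n_grid)
    q_transformed = (
        k_p / n_grid * np.exp(-lam_p * (a + b * generic_T(u, dist.beta)))
    )
    return float(np.max(np.abs(q_transformed - dist.pdf(n_grid))))
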