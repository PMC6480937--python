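# Methods

## The model

The package implements a one-parameter family of probability
distributions for abundances n ≥ 1,

    q(n) = k · n⁻¹ · exp(−λ T_β(log n)),      T_β(w) = (e^{βw} − 1)/β,

with T_β(w) → w as β → 0.  The family is the generic exponential form
k·e^{−λT} written on the abundance scale: the process variable r = log n
is the accumulated total of proportional growth processes
(r = ∫₀^τ m(t) dt with initial abundance 1, so n = e^r), and the change
of variables r ↦ log n, dr ↦ n⁻¹dn produces the n⁻¹ prefactor.

Two conservation laws fix the free constants and give the family its
structure:

* conserved total probability — k adjusts so ∫₁^∞ q = 1, making the
  pattern invariant to shifts T ↦ a + T (k absorbs e^{−λa});
* a conserved average abundance — λ adjusts so ⟨n⟩ attains its value,
  making the pattern invariant to stretches T ↦ bT (λ absorbs the b).

The package does not re-derive this affine invariance symbolically; it
verifies it numerically (`affine_invariance_check`,
`change_of_variable_check`) by rebuilding the transformed density with
λ′ = λ/b and a renormalized k′ and comparing pointwise, with residual
tolerances of 1e−9 on a standard grid.

Endpoints:

* β → 0: q(n) = λ n^{−(1+λ)} exactly; the mean constraint gives
  λ = 1/(1 − 1/⟨n⟩), so λ → 1 for any large average — Zipf's law, with
  rank-size log-log slope −1 and affine-invariant scale collapsing to
  2 log n.
* β = 1: q(n) ∝ pⁿ/n with p = e^{−λ} — the log series.  The scale
  T_n = (1/λ) log n + n changes character with magnitude: logarithmic at
  small n, linear at large n.

β > 1 is permitted numerically but lies outside the Zipf ↔ log-series
continuum; `outside_continuum` flags it.

### Continuous vs discrete support

The continuum is defined on continuous n ∈ [1, ∞); every printed closed
form (power-law normalization k = λ, survival n^{−λ}, the mean formulas)
holds there.  Observed abundances are integers, so the package also
ships the *exact* integer-support log series q_n = k pⁿ/n with
k = −1/log(1 − p) as a separate type (`DiscreteLogSeries`), rather than
claiming a particular discretization of the continuum.  The synthetic
generator exposes its rounding rule (`round_half_up` default, `ceiling`
offered) instead of hiding it.  The two objects are deliberately not
interchangeable: the continuous β = 1 member and the discrete log series
have different normalizations, and likelihoods computed under one do not
maximize at the other's parameters (see "Fitting" below).

## Key parameters

| parameter | meaning | domain | default |
|---|---|---|---|
| β | scale curvature; 0 = Zipf endpoint, 1 = log series | ≥ 0 | — |
| λ | constraint multiplier holding the conserved mean | > 0 | — |
| k | normalization constant (derived, never user-set) | > 0 | recomputed |
| p | discrete log-series parameter, p = e^{−λ} | (0, 1) | — |

All are dimensionless.  An infinite mean (β = 0 with λ ≤ 1, which
includes Zipf's law itself) is a first-class state returned as `inf`,
not an error; such members are sampleable, and only moment-based
diagnostics are meaningless for them.

## Numerics

* **Branch switch.**  (e^{βw} − 1)/β is evaluated directly (via `expm1`)
  for β ≥ 1e−6 and by the series limit w(1 + βw/2) below; in double
  precision the direct formula's relative error exceeds the limit
  branch's below that point.  The branches agree across the threshold to
  better than 1e−9 for |w| ≤ 10.
* **Quadrature.**  All improper integrals are computed after the
  substitution u = log n, which removes the n⁻¹ weighting and turns the
  normalization integrand into exp(−λT_β(u)) on [0, ∞); adaptive
  quadrature runs at relative tolerance 1e−11.  The test suite
  cross-checks k, the CDF and the survival against the independent
  exponential-integral closed form k = β e^{−λ/β}/E₁(λ/β) (the
  β = 1, λ = 1 case is 1/(e·E₁(1)) ≈ 1.6769).
* **Means.**  The mean integrand exp(u − λT_β(u)) is integrated around
  its analytic maximum (at u* = log(1/λ)/β when λ < 1).  If the peak
  log-integrand exceeds 700 nats the mean is beyond double-precision
  range and is reported as the infinite state.
* **Constraint solving.**  λ ↦ ⟨n⟩ is strictly decreasing, so
  `solve_lambda` brackets and runs Brent's method (β = 0 uses the closed
  form); round-trip accuracy is 1e−6 relative or better.
* **Exponent convention.**  The exponent is −λ(nᵝ − 1)/β with the "−1"
  shift kept; dropping it is an affine shift of T and describes the same
  normalized pattern, which the shift-invariance test exercises rather
  than a second code path.

## Sampling

Inversion throughout.  β = 0 inverts the survival n^{−λ} in closed form,
so Zipf sampling has no interpolation error.  β > 0 tabulates the CDF on
a grid linear in u = log n (4096 points to n = 1e9 by default) using
16-point Gauss–Legendre segment masses, and inverts with a monotone
cubic (PCHIP) interpolant.  Rejection sampling was rejected as a design:
near β = 0 the tails are too heavy for robust envelopes, while
tabulation error is controllable.  The grid automatically extends until
the tail mass beyond it is below 1e−9; that tail is logged and any draw
landing in it is clamped to the grid edge with a warning, never silently
dropped.  Process-scale sampling returns the u-draws directly (β = 0:
exponential with rate λ), so exponentiating them reproduces abundance
draws in distribution — tested by two-sample KS across the family.

The discrete log-series sampler inverts the cumulative pmf sum, with the
table extended until the neglected tail is below 1e−13.

Identical seed and configuration give bit-identical streams
(`numpy.random.default_rng`).

## Fitting

The continuum likelihood for a sample {n_i} is
Σ [log k(β,λ) − log n_i − λ T_β(log n_i)].  The maximizer is found by a
profile search: bounded 1-D optimization over β ∈ [0, 2] (with an
explicit boundary check at β = 0) around a bounded inner 1-D search over
log λ, recomputing k at every evaluation.  β and λ trade off along a
likelihood ridge — nearby (β, λ) pairs produce similar density shapes —
which makes joint 2-D quasi-Newton steps unreliable; the nested 1-D
searches are robust to the ridge.  Standard errors come from the
observed-information curvature (finite differences; one-sided in β at
the boundary), and a flat likelihood yields `converged=False` rather
than an exception.

The continuous likelihood is applied to integer counts directly, with no
continuity correction.  This is an approximation with two documented
consequences:

* counts from a member concentrated near n = 1 (large λ, or β = 1 with
  small mean) are informative mostly through their rounding cell, and
  the fitted member can be pulled toward the β = 0 endpoint;
* exact discrete log-series data are *not* fitted consistently by the
  continuous β = 1 likelihood — the integral and sum normalizations
  differ, shifting the score equation.  For such data use
  `fit_logseries_discrete`, the exact discrete MLE (which reduces to
  matching the sample mean to p/((1−p)(−log(1−p)))).

Endpoint selection fits the free-β model and the two fixed-β endpoints
and compares AIC = 2·params − 2·loglik (2 vs 1 parameters); a runner-up
within 2 AIC units is reported as indistinguishable.  Likelihood-ratio
statistics for the nested pairs are reported alongside, with the caveat
that the χ²₁ reference is anti-conservative when the null lies on the
β = 0 boundary.

## Rank-abundance analysis

Abundances are sorted descending with ordinal ranks (ties get distinct
consecutive ranks: the rank-size convention indexes entities, not
values).  The log-log regression of rank on abundance deduplicates by
abundance value, keeping the smallest rank per value, and restricts to
an abundance quantile window, by default (0, 0.999): the few
largest-abundance points otherwise dominate ordinary least squares.  The
window is part of the returned result.  For β = 0 members the survival
n^{−λ} makes the expected slope −λ; the theory does not specify over
what finite-sample range linearity should hold, so the window is a
declared convention of this package.

As a curvature diagnostic distinguishing log-series from power-law
samples, the suite fits a degree-2 polynomial to the same points: the
quadratic coefficient is systematically negative (≈ −0.5 at p = 0.95)
for log-series samples and near zero for β = 0 samples.  The
equal-count tercile-residual version of this diagnostic is unstable
because the deduplicated points crowd the tail of the axis, so the
quadratic coefficient is the reported form.

## Synthetic data

The generator draws communities either directly from a family member
(continuous draws, then the stated rounding rule with a floor at 1) or
by exponentiating accumulated proportional-process histories.  Process
intensities are limited to exactly integrable forms — constant,
piecewise-constant — plus i.i.d. per-step increments (normal, uniform,
exponential); there is no quadrature inside the generator, so every
fixture is reproducible bit-for-bit from its recorded provenance (the
manifest stores generator type, parameters, seed, discretization rule
and package version).  The shipped intensity families are illustrations
of proportional process, not mechanistic claims.

The log-series fixtures are exact discrete draws (so their small-count
frequencies match the discrete pmf); the β = 0 and β = 0.5 fixtures are
rounded continuous draws.

What the generator does *not* emulate: sampling a finite community from
a larger pool (no detection/veil-line effects), interspecific
correlation, temporal turnover, or spatial structure.  Passing
round-trip tests therefore shows estimator self-consistency under the
model, not robustness to the ways field data violate it.

## Problem sizes

Statistical tests run at the sizes their tolerances were designed for:
rank-size slope checks on 2×10⁵ continuous draws (slope −1 ± 0.05 at the
Zipf endpoint), parameter recovery on 2×10⁴ draws over five seeds
(β within ±0.1, λ within ±0.15 in at least four of five), estimator
consistency at n ∈ {10³, 10⁴, 10⁵} with medians over 11 seeds, and
sampler diagnostics at 10⁴–10⁶ draws with 3-standard-error bands.  KS
comparisons across 20 random family members use the 1% level with an
allowance of two chance failures (the per-test level makes one failure
in twenty likely under the null).

## Known limitations

* The continuous-likelihood-on-integers approximation above; use the
  discrete log-series route for genuinely discrete log-series data.
* Standard errors assume a locally quadratic log likelihood; on the
  β ridge with small samples they can understate uncertainty, and at the
  β = 0 boundary the β standard error is one-sided.
* Members with β ≈ 0 and λ ≤ 1 have infinite means; mean-constrained
  construction (`solve_lambda`) requires a finite target and will refuse
  targets ≤ 1.
* The rank-regression window and tie conventions are declared choices;
  other conventions (average ranks, different windows) give slightly
  different slopes on tied data.
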