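import numpy as np
import pytest
from scipy.special import exp1

from zipfseries import AbundanceDistribution, SamplerConfig, sample_abundance


def k_exp1_oracle(beta: float, lam: float) -> float:
    """Independent closed form for the normalization constant.

    Substituting v = n**beta turns the normalization integral into the
    exponential-integral identity, giving k = beta * exp(-lam/beta) /
    E1(lam/beta) for beta > 0 (and k = lam at beta = 0).
    """
    if beta == 0.0:
        return lam
    x = lam / beta
    return beta * np.exp(-x) / exp1(x)


def survival_exp1_oracle(n: float, beta: float, lam: float) -> float:
    """Closed-form survival E1(lam*n^beta/beta) / E1(lam/beta), beta > 0."""
    return exp1(lam * n**beta / beta) / exp1(lam / beta)


def total_probability(dist) -> float:
    """Total probability mass, recomputed from an independent formula.

    Integrates exp(-lam*(e^(beta*u) - 1)/beta) (written out directly, not
    through the package's scale function) on a finite u interval chosen so
    the omitted tail is below 1e-300, and multiplies by the package's k.
    """
    import math

    from scipy import integrate

    beta, lam = dist.beta, dist.lam

    def T(u):
        if beta == 0.0:
            return u
        if beta * u > 700.0:
            return math.inf
        return math.expm1(beta * u) / beta

    def integrand(u):
        e = -lam * T(u)
        return 0.0 if e < -745.0 else math.exp(e)

    u_hi = 1.0
    while lam * T(u_hi) < 750.0:
        u_hi *= 2.0
    val, _ = integrate.quad(integrand, 0.0, u_hi, epsrel=1e-11, limit=400)
    return dist.k * val


@pytest.fixture(scope="session")
def zipf_draws_2e5():
    """2e5 continuous draws from the beta=0, lam=1 (Zipf) member."""
    dist = AbundanceDistribution(0.0, 1.0)
    return sample_abundance(dist, 200_000, SamplerConfig(seed=11))
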