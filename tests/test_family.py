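"""Core family: scale functions, normalization, densities, constraints."""

import math

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from zipfseries import (
    AbundanceDistribution,
    DiscreteLogSeries,
    affine_invariance_check,
    change_of_variable_check,
    generic_T,
    logseries_mean,
    logseries_pmf,
    mean_abundance,
    normalization_constant,
    scale_T_n,
    solve_lambda,
)

from conftest import k_exp1_oracle, survival_exp1_oracle, total_probability


def T_series_oracle(w: float, beta: float, terms: int = 60) -> float:
    """(e^{beta w} - 1)/beta by its power series sum_k beta^{k-1} w^k / k!."""
    total, term = 0.0, w
    for k in range(1, terms + 1):
        total += term
        term *= beta * w / (k + 1)
    return total


class TestGenericT:
    @pytest.mark.parametrize(
        "w, beta, expected, tol",
        [
            (0.0, 3.0, 0.0, 0.0),
            (1.5, 1e-10, 1.5, 1e-6),  # T -> w as beta -> 0
            (1.0, 2.0, (math.e**2 - 1) / 2, 1e-12),
        ],
    )
    def test_values(self, w, beta, expected, tol):
        assert generic_T(w, beta) == pytest.approx(expected, abs=tol)

    def test_matches_series_expansion(self):
        for w, beta in [(1.0, 2.0), (2.5, 0.3), (-1.2, 0.8), (0.7, 1.0)]:
            assert generic_T(w, beta) == pytest.approx(
                T_series_oracle(w, beta), rel=1e-12
            )

    def test_negative_beta_rejected(self):
        with pytest.raises(ValueError, match="beta"):
            generic_T(1.0, -0.5)

    def test_continuous_across_switch_threshold(self):
        w = np.linspace(-10, 10, 41)
        below = generic_T(w, 1e-6 * (1 - 1e-9))
        above = generic_T(w, 1e-6 * (1 + 1e-9))
        assert np.max(np.abs(below - above)) < 1e-9

    @given(
        w1=st.floats(-10, 10),
        dw=st.floats(1e-3, 5),
        beta=st.floats(0, 3),
    )
    @settings(deadline=None, derandomize=True)
    def test_strictly_increasing_in_w(self, w1, dw, beta):
        assert generic_T(w1 + dw, beta) > generic_T(w1, beta)


class TestScaleTn:
    def test_zero_at_lower_support_bound(self):
        assert scale_T_n(1.0, 0.7, 2.0) == 0.0

    def test_zipf_endpoint_scale_is_twice_log_n(self):
        # at beta -> 0 with lam = 1 the scale collapses to 2 log n
        ratio = scale_T_n(math.e, 1e-12, 1.0) / math.log(math.e)
        assert ratio == pytest.approx(2.0, abs=1e-6)

    def test_direct_evaluation(self):
        assert scale_T_n(3.0, 1.0, 2.0) == pytest.approx(
            math.log(3) / 2 + 2.0, rel=1e-14
        )

    def test_below_support_rejected(self):
        with pytest.raises(ValueError, match=">= 1"):
            scale_T_n(0.5, 1.0, 1.0)


class TestNormalization:
    def test_power_law_closed_form(self):
        assert normalization_constant(0.0, 2.0) == 2.0

    def test_logseries_endpoint_vs_exponential_integral(self):
        # independent oracle: 1/(e * E1(1))
        assert normalization_constant(1.0, 1.0) == pytest.approx(
            k_exp1_oracle(1.0, 1.0), rel=1e-9
        )

    def test_quadrature_self_consistent(self):
        # total probability of the normalized density, recomputed with an
        # independent quadrature on the abundance axis
        dist = AbundanceDistribution(0.5, 1.0)
        total, _ = integrate.quad(dist.pdf, 1.0, np.inf, epsrel=1e-10, limit=200)
        assert abs(total - 1.0) < 1e-8

    def test_non_integrable_parameters_named(self):
        with pytest.raises(ValueError, match="lam"):
            normalization_constant(0.5, -1.0)

    def test_random_members_normalized(self):
        rng = np.random.default_rng(2024)
        for _ in range(50):
            beta = rng.uniform(0.0, 2.0)
            lam = rng.uniform(0.2, 5.0)
            dist = AbundanceDistribution(beta, lam)
            assert abs(total_probability(dist) - 1.0) < 1e-8


class TestPdfLogpdf:
    def test_power_law_values(self):
        d = AbundanceDistribution(0.0, 1.0)
        assert d.pdf(1.0) == pytest.approx(1.0, rel=1e-14)
        assert d.pdf(10.0) == pytest.approx(0.01, rel=1e-12)
        assert d.logpdf(10.0) == pytest.approx(math.log(0.01), rel=1e-12)

    def test_logseries_endpoint_composition(self):
        k = k_exp1_oracle(1.0, 0.5)
        d = AbundanceDistribution(1.0, 0.5)
        assert d.pdf(3.0) == pytest.approx(k * (1 / 3) * math.exp(-1.0), rel=1e-9)

    def test_logpdf_stable_where_pdf_underflows(self):
        d = AbundanceDistribution(1.0, 1.0)
        lp = d.logpdf(1e6)
        assert math.isfinite(lp)
        assert math.exp(lp) == 0.0  # underflow of the direct density
        # stable route agrees with log(k) - log(n) - lam*T exactly
        assert lp == pytest.approx(
            math.log(d.k) - math.log(1e6) - 1.0 * generic_T(math.log(1e6), 1.0),
            rel=1e-12,
        )

    def test_logpdf_matches_log_of_pdf(self):
        d = AbundanceDistribution(0.5, 1.5)
        for n in [1.0, 2.0, 7.3, 50.0]:
            assert d.logpdf(n) == pytest.approx(math.log(d.pdf(n)), abs=1e-12)

    def test_strictly_decreasing_in_n(self):
        # on the log scale, to dodge the underflow plateau deep in the tail
        grid = np.logspace(0, 4, 200)
        for beta, lam in [(0.0, 1.0), (0.5, 0.7), (1.0, 2.0), (1.7, 0.3)]:
            vals = AbundanceDistribution(beta, lam).logpdf(grid)
            assert np.all(np.diff(vals) < 0)

    def test_scale_consistency(self):
        # exp(-lam*(n^beta-1)/beta)/n reproduces pdf/k
        d = AbundanceDistribution(0.8, 1.3)
        n = np.array([1.0, 2.5, 10.0, 123.0])
        lhs = np.exp(-d.lam * generic_T(np.log(n), d.beta)) / n
        assert np.max(np.abs(lhs - d.pdf(n) / d.k)) < 1e-12

    def test_below_support_rejected(self):
        with pytest.raises(ValueError, match=">= 1"):
            AbundanceDistribution(1.0, 1.0).pdf(0.9)


class TestCdfSurvival:
    def test_boundary_values(self):
        for beta, lam in [(0.0, 1.0), (1.0, 1.0), (0.5, 2.0)]:
            d = AbundanceDistribution(beta, lam)
            assert d.cdf(1.0) == pytest.approx(0.0, abs=1e-12)
            assert d.survival(1.0) == pytest.approx(1.0, rel=1e-10)

    def test_power_law_closed_form_survival(self):
        d = AbundanceDistribution(0.0, 1.0)
        assert d.survival(4.0) == pytest.approx(0.25, rel=1e-12)
        # cross-check by quadrature of the density
        tail, _ = integrate.quad(d.pdf, 4.0, np.inf, epsrel=1e-10, limit=200)
        assert tail == pytest.approx(0.25, rel=1e-8)

    def test_complementarity(self):
        for beta, lam in [(1.0, 1.0), (0.5, 0.7), (0.3, 2.0)]:
            d = AbundanceDistribution(beta, lam)
            for n in [1.5, 2.0, 10.0, 200.0]:
                assert d.cdf(n) + d.survival(n) == pytest.approx(1.0, abs=1e-10)

    def test_against_exponential_integral_oracle(self):
        for beta, lam in [(1.0, 1.0), (0.5, 0.7), (0.25, 1.5)]:
            d = AbundanceDistribution(beta, lam)
            for n in [2.0, 5.0, 30.0]:
                assert d.survival(n) == pytest.approx(
                    survival_exp1_oracle(n, beta, lam), rel=1e-9
                )

    def test_survival_strictly_decreasing(self):
        d = AbundanceDistribution(0.6, 1.1)
        vals = [d.survival(n) for n in [1.0, 2.0, 5.0, 20.0, 100.0]]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestMeanAndConstraint:
    def test_power_law_closed_form_mean(self):
        assert mean_abundance(AbundanceDistribution(0.0, 2.0)) == pytest.approx(2.0)

    def test_zipf_mean_diverges(self):
        assert mean_abundance(AbundanceDistribution(0.0, 1.0)) == math.inf
        assert mean_abundance(AbundanceDistribution(0.0, 0.5)) == math.inf

    def test_mean_decreasing_in_lam(self):
        means = [
            mean_abundance(AbundanceDistribution(0.5, lam))
            for lam in [0.3, 0.7, 1.5, 3.0]
        ]
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_solve_lambda_power_law_closed_form(self):
        assert solve_lambda(0.0, 2.0) == pytest.approx(2.0, rel=1e-12)

    def test_large_mean_approaches_zipf(self):
        # lam -> 1 for any large finite average abundance: Zipf's law
        assert solve_lambda(0.0, 1e6) == pytest.approx(1.000001, rel=1e-9)

    @pytest.mark.parametrize("beta", [0.0, 0.25, 0.5, 1.0])
    def test_constraint_round_trip(self, beta):
        for target in [2.0, 5.0]:
            lam = solve_lambda(beta, target)
            assert mean_abundance(AbundanceDistribution(beta, lam)) == pytest.approx(
                target, rel=1e-6
            )

    def test_mean_target_at_most_one_rejected(self):
        with pytest.raises(ValueError, match="mean_target"):
            solve_lambda(0.5, 1.0)


class TestDiscreteLogSeries:
    def test_pmf_value(self):
        assert logseries_pmf(1, 0.5) == pytest.approx(0.5 / math.log(2), rel=1e-12)

    def test_total_probability(self):
        n = np.arange(1, 10**6 + 1)
        assert abs(np.sum(logseries_pmf(n, 0.9)) - 1.0) < 1e-10

    def test_mean_identity(self):
        p = 0.5
        expected = p / ((1 - p) * (-math.log(1 - p)))
        assert logseries_mean(p) == pytest.approx(expected, rel=1e-12)
        # term-wise summation oracle
        n = np.arange(1, 2_000)
        assert np.sum(n * logseries_pmf(n, p)) == pytest.approx(expected, rel=1e-10)

    def test_matches_scipy_logser(self):
        n = np.arange(1, 50)
        for p in [0.2, 0.7, 0.95]:
            assert np.allclose(
                logseries_pmf(n, p), scipy.stats.logser.pmf(n, p), rtol=1e-12
            )

    def test_strictly_decreasing(self):
        vals = logseries_pmf(np.arange(1, 100), 0.9)
        assert np.all(np.diff(vals) < 0)

    def test_links_to_continuum_intensity(self):
        dls = DiscreteLogSeries(math.exp(-0.4))
        assert dls.lam == pytest.approx(0.4, rel=1e-12)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.2, 1.5])
    def test_parameter_domain(self, p):
        with pytest.raises(ValueError, match="p"):
            logseries_pmf(1, p)


class TestIdentityChecks:
    def test_change_of_variable_pointwise(self):
        assert change_of_variable_check(1.0, AbundanceDistribution(1.0, 1.0)) < 1e-12
        assert change_of_variable_check(7.3, AbundanceDistribution(0.5, 2.0)) < 1e-10

    def test_change_of_variable_sweep(self):
        rng = np.random.default_rng(5)
        grid = np.array([1.0, 2.0, 5.0, 10.0, 100.0, 1e4])
        worst = 0.0
        for _ in range(20):
            dist = AbundanceDistribution(rng.uniform(0, 2), rng.uniform(0.2, 5))
            worst = max(worst, float(np.max(change_of_variable_check(grid, dist))))
        assert worst < 1e-9

    def test_affine_identity_transform(self):
        assert affine_invariance_check(
            AbundanceDistribution(0.5, 1.0), a=0.0, b=1.0
        ) < 1e-14

    def test_shift_invariance(self):
        # k reabsorbs the shift: k = k_a e^{-lam a}
        assert affine_invariance_check(
            AbundanceDistribution(1.0, 1.2), a=3.0, b=1.0
        ) < 1e-10

    def test_stretch_invariance(self):
        # lam reabsorbs the stretch: lam = lam_b b
        assert affine_invariance_check(
            AbundanceDistribution(0.7, 1.3), a=1.7, b=2.5
        ) < 1e-9

    def test_nonpositive_stretch_rejected(self):
        with pytest.raises(ValueError, match="b"):
            affine_invariance_check(AbundanceDistribution(1.0, 1.0), a=0.0, b=0.0)


class TestEndpointEquivalence:
    def test_small_beta_matches_power_law(self):
        lam = 1.3
        d = AbundanceDistribution(1e-8, lam)
        n = np.logspace(0, 4, 60)
        power = lam * n ** (-(1 + lam))
        assert np.max(np.abs(d.pdf(n) - power) / power) < 1e-6

    def test_beta_one_proportional_to_logseries_form(self):
        lam = 0.9
        p = math.exp(-lam)
        d = AbundanceDistribution(1.0, lam)
        n = np.arange(1.0, 40.0)
        ratio = d.pdf(n) / (p**n / n)
        assert np.max(np.abs(ratio - ratio[0])) < 1e-10 * ratio[0]
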