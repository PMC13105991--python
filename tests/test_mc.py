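"""Latin-Hypercube Monte Carlo: samplers, stratification, THQ propagation."""

import math

import numpy as np
import pytest
from scipy import stats

import reference_values as ref
from ricerisk import (
    ExposureScenario,
    InvalidInputError,
    exceedance_probability,
    lhs_sample,
    shifted_lognormal,
    shifted_lognormal_inverse_cdf,
    simulate_thq,
    triangular,
    triangular_inverse_cdf,
)


def published_scenario(seed=1, **overrides):
    kwargs = dict(
        concentration=shifted_lognormal(**ref.CD_LOGNORMAL),
        intake_g_day=triangular(
            ref.INTAKE_TRIANGULAR["a"], ref.INTAKE_TRIANGULAR["c"], ref.INTAKE_TRIANGULAR["b"]
        ),
        bw=ref.MC_BW,
        rfd=ref.MC_RFD,
        n_iterations=ref.MC_ITERATIONS,
        seed=seed,
    )
    kwargs.update(overrides)
    return ExposureScenario(**kwargs)


class TestTriangularInverseCdf:
    def test_endpoints_and_right_triangle(self):
        assert triangular_inverse_cdf(0.0, 1.0, 2.0, 3.0) == 1.0
        assert triangular_inverse_cdf(1.0, 1.0, 2.0, 3.0) == 3.0
        # right triangle a=0, c=b=1: F^{-1}(u) = sqrt(u)
        assert triangular_inverse_cdf(0.25, 0.0, 1.0, 1.0) == pytest.approx(0.5)

    def test_mode_round_trip(self):
        a, c, b = 121.63, 231.56, 308.42
        u_mode = (c - a) / (b - a)
        assert u_mode == pytest.approx(0.58853, abs=1e-5)
        assert triangular_inverse_cdf(u_mode, a, c, b) == pytest.approx(c)

    def test_monotone_within_support(self):
        u = np.linspace(0, 1, 1001)
        q = triangular_inverse_cdf(u, 10.0, 15.0, 30.0)
        assert np.all(np.diff(q) >= 0)
        assert np.all((q >= 10.0) & (q <= 30.0))

    def test_invalid_probability(self):
        with pytest.raises(InvalidInputError):
            triangular_inverse_cdf(1.5, 0.0, 0.5, 1.0)

    def test_matches_scipy(self):
        u = np.linspace(0.01, 0.99, 99)
        ours = triangular_inverse_cdf(u, 121.63, 231.56, 308.42)
        theirs = triangular(121.63, 231.56, 308.42).ppf(u)
        assert np.allclose(ours, theirs)


class TestShiftedLognormalInverseCdf:
    def test_median_is_shift_plus_exp_mu(self, cd_distribution):
        q = shifted_lognormal_inverse_cdf(0.5, cd_distribution)
        assert q == pytest.approx(0.0868, abs=2e-4)

    def test_one_sigma_identity(self, cd_distribution):
        p = cd_distribution.params
        u = stats.norm.cdf(1.0)
        expected = p["tau"] + math.exp(p["mu_log"] + p["sigma_log"])
        assert shifted_lognormal_inverse_cdf(u, cd_distribution) == pytest.approx(expected)

    def test_degenerate_sigma_limit(self):
        dist = shifted_lognormal(0.1, 1e-9, 0.05)
        for u in (0.1, 0.5, 0.9):
            assert shifted_lognormal_inverse_cdf(u, dist) == pytest.approx(0.15, rel=1e-4)

    def test_boundary_probabilities_rejected(self, cd_distribution):
        for u in (0.0, 1.0):
            with pytest.raises(InvalidInputError):
                shifted_lognormal_inverse_cdf(u, cd_distribution)

    def test_strictly_increasing(self, cd_distribution):
        u = np.linspace(0.001, 0.999, 500)
        q = shifted_lognormal_inverse_cdf(u, cd_distribution)
        assert np.all(np.diff(q) > 0)


class TestLatinHypercube:
    def test_midpoint_uniform_strata(self):
        dist = triangular(0.0, 0.5, 1.0)
        # use the uniform-like check via the CDF: midpoints map to (i-0.5)/n
        draws = lhs_sample(dist, 4, rng=0, position="midpoint")
        u = np.sort(dist.cdf(draws))
        assert np.allclose(u, [0.125, 0.375, 0.625, 0.875])

    def test_one_draw_per_stratum(self, cd_distribution):
        n = 5000
        draws = lhs_sample(cd_distribution, n, rng=3)
        u = cd_distribution.cdf(draws)
        counts = np.histogram(u, bins=np.linspace(0, 1, n + 1))[0]
        assert np.all(counts == 1)

    def test_sample_mean_matches_analytic(self, cd_distribution):
        p = ref.CD_LOGNORMAL
        analytic_mean = p["m"] + p["tau"]  # 0.16628 mg/kg
        draws = lhs_sample(cd_distribution, 5000, rng=11)
        se = p["s"] / math.sqrt(5000)
        assert abs(draws.mean() - analytic_mean) < 3 * se

    def test_variance_reduction_vs_plain_mc(self, cd_distribution, intake_distribution):
        """Across 200 replicates the LHS mean-THQ estimator has variance no
        larger than plain Monte Carlo at equal n."""
        n, reps = 200, 200
        k = ref.MC_BW * ref.MC_RFD
        lhs_means, mc_means = [], []
        for rep in range(reps):
            c = lhs_sample(cd_distribution, n, rng=rep)
            ir = lhs_sample(intake_distribution, n, rng=10_000 + rep)
            lhs_means.append(np.mean(np.clip(c, 0, None) * ir / 1000 / k))
            rng = np.random.default_rng(20_000 + rep)
            c = np.clip(cd_distribution.ppf(rng.uniform(1e-12, 1 - 1e-12, n)), 0, None)
            ir = intake_distribution.ppf(rng.uniform(0, 1, n))
            mc_means.append(np.mean(c * ir / 1000 / k))
        assert np.var(lhs_means) <= np.var(mc_means)


class TestSimulateThq:
    def test_fixed_inputs_collapse_to_deterministic(self):
        res = simulate_thq(
            published_scenario(concentration=0.124, intake_g_day=231.56, bw=64.0, rfd=0.0005)
        )
        assert res.sd == 0.0
        assert res.mean == pytest.approx(0.898, abs=1e-3)
        assert res.exceedance_probability == 0.0

    def test_reproduces_published_mean_and_exceedance(self):
        res = simulate_thq(published_scenario(seed=1))
        assert res.mean == pytest.approx(ref.MC_MEAN_THQ, abs=0.05)
        assert res.exceedance_probability == pytest.approx(ref.MC_P_THQ_GE_1, abs=0.015)

    def test_mean_within_three_se_of_closed_form(self):
        res = simulate_thq(published_scenario(seed=5))
        p, t = ref.CD_LOGNORMAL, ref.INTAKE_TRIANGULAR
        analytic = (p["m"] + p["tau"]) * ((t["a"] + t["c"] + t["b"]) / 3 / 1000) / (
            ref.MC_BW * ref.MC_RFD
        )
        se = res.sd / math.sqrt(res.n_iterations)
        assert abs(res.mean - analytic) < 3 * se

    def test_bit_reproducibility(self):
        a = simulate_thq(published_scenario(seed=42))
        b = simulate_thq(published_scenario(seed=42))
        assert np.array_equal(a.thq_draws, b.thq_draws)
        assert a.summary() == b.summary()

    def test_seed_changes_draws(self):
        a = simulate_thq(published_scenario(seed=1))
        b = simulate_thq(published_scenario(seed=2))
        assert not np.array_equal(a.thq_draws, b.thq_draws)

    def test_raising_rfd_lowers_every_draw(self):
        lo = simulate_thq(published_scenario(seed=7, rfd=0.001))
        hi = simulate_thq(published_scenario(seed=7, rfd=0.002))
        assert np.all(hi.thq_draws <= lo.thq_draws)

    def test_invalid_scenario(self):
        with pytest.raises(InvalidInputError):
            published_scenario(bw=0.0)
        with pytest.raises(InvalidInputError):
            published_scenario(n_iterations=10)

    def test_rank_correlation_injection(self):
        res = simulate_thq(published_scenario(seed=9, spearman_r=0.8))
        rho = stats.spearmanr(res.c_draws, res.ir_draws).statistic
        assert rho == pytest.approx(0.8, abs=0.05)


class TestExceedanceProbability:
    def test_inclusive_threshold(self):
        assert exceedance_probability([0.5, 1.5]) == 0.5
        assert exceedance_probability([1.0, 1.0]) == 1.0

    def test_monotone_in_threshold(self):
        draws = np.linspace(0, 2, 101)
        assert exceedance_probability(draws, 0.5) >= exceedance_probability(draws, 1.5)

    def test_plain_mc_oracle_brackets_lhs_estimate(self, cd_distribution, intake_distribution):
        """A 1e6-draw plain-MC estimate of P(THQ >= 1) sits inside the
        published band and agrees with the LHS run."""
        rng = np.random.default_rng(123)
        c = np.clip(cd_distribution.ppf(rng.uniform(1e-12, 1 - 1e-12, 10**6)), 0, None)
        ir = intake_distribution.ppf(rng.uniform(0, 1, 10**6))
        thq = c * ir / 1000 / (ref.MC_BW * ref.MC_RFD)
        oracle = exceedance_probability(thq)
        assert 0.15 < oracle < 0.17
        lhs = simulate_thq(published_scenario(seed=4)).exceedance_probability
        assert lhs == pytest.approx(oracle, abs=0.015)

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            exceedance_probability([])
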