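import numpy as np
import pytest
import statsmodels.api as sm

from mrscan import (egger, ivw, mode_estimator, ratio_estimates, run_mr,
                    simple_median, wald_ratio, weighted_median)
from mrscan.errors import InsufficientInstrumentsError, ParameterError
from mrscan.estimators import (_mode_point, _silverman_bandwidth,
                               _weighted_median_point)

from conftest import make_harmonized


class TestWaldRatio:
    def test_arithmetic(self):
        h = make_harmonized([0.5], [0.25], se_out=[0.05])
        res = wald_ratio(h.retained[0])
        assert res.estimate == pytest.approx(0.5)
        assert res.se == pytest.approx(0.1)
        assert res.n_snp == 1

    def test_null_case(self):
        h = make_harmonized([1.0], [0.0])
        assert wald_ratio(h.retained[0]).estimate == 0.0

    def test_zero_beta_exp_raises(self):
        h = make_harmonized([0.0], [0.1])
        with pytest.raises(ParameterError):
            wald_ratio(h.retained[0])

    def test_negative_beta_exp_se_positive(self):
        h = make_harmonized([-0.5], [0.25], se_out=[0.05])
        res = wald_ratio(h.retained[0])
        assert res.estimate == pytest.approx(-0.5)
        assert res.se == pytest.approx(0.1)

    def test_delta_se_against_monte_carlo(self, rng):
        # Monte-Carlo oracle for the first-order delta SE of a ratio
        bx, sx, by, sy = 0.2, 0.01, 0.1, 0.02
        draws_x = rng.normal(bx, sx, size=1_000_000)
        draws_y = rng.normal(by, sy, size=1_000_000)
        mc_sd = np.std(draws_y / draws_x)
        h = make_harmonized([bx], [by], se_exp=[sx], se_out=[sy])
        res = wald_ratio(h.retained[0])
        assert res.se == pytest.approx(mc_sd, rel=0.10)


class TestIVW:
    def test_exact_consensus(self, simple_harmonized):
        fe = ivw(simple_harmonized, mode="fixed")
        re = ivw(simple_harmonized, mode="random")
        assert fe.estimate == pytest.approx(0.5)
        assert re.estimate == pytest.approx(0.5)
        assert re.se == pytest.approx(fe.se)  # Q=0 -> no inflation

    def test_single_snp_reduces_to_wald(self):
        h = make_harmonized([0.5], [0.25], se_out=[0.05])
        res = ivw(h)
        wald = wald_ratio(h.retained[0])
        assert res.estimate == pytest.approx(wald.estimate, abs=1e-15)
        assert res.se == pytest.approx(wald.se, abs=1e-15)

    def test_closed_form_example(self):
        # normal-equations oracle: theta = 0.075 / 0.14
        h = make_harmonized([0.1, 0.2, 0.3], [0.05, 0.08, 0.18],
                            se_out=[0.01, 0.01, 0.01])
        res = ivw(h, mode="fixed")
        assert res.estimate == pytest.approx(0.075 / 0.14, rel=1e-12)

    def test_against_wls_oracle(self, rng):
        bx = rng.normal(0.1, 0.03, size=10)
        by = rng.normal(0.05, 0.02, size=10)
        sy = rng.uniform(0.005, 0.02, size=10)
        h = make_harmonized(bx, by, se_out=sy)
        res = ivw(h, mode="fixed")
        fit = sm.WLS(by, bx, weights=1.0 / sy**2).fit()
        assert res.estimate == pytest.approx(fit.params[0], rel=1e-10)

    def test_fixed_se_never_exceeds_random_se(self, rng):
        for seed in range(10):
            r = np.random.default_rng(seed)
            h = make_harmonized(r.normal(0.1, 0.02, 8), r.normal(0.02, 0.03, 8),
                                se_out=r.uniform(0.005, 0.03, 8))
            assert ivw(h, mode="fixed").se <= ivw(h, mode="random").se + 1e-15

    def test_empty_raises(self):
        h = make_harmonized([], [])
        with pytest.raises(InsufficientInstrumentsError):
            ivw(h)

    def test_bad_mode(self, simple_harmonized):
        with pytest.raises(ParameterError):
            ivw(simple_harmonized, mode="bayesian")


class TestEgger:
    def test_perfect_proportional_fit(self):
        h = make_harmonized([0.1, 0.2, 0.3, 0.4], [0.03, 0.06, 0.09, 0.12])
        res = egger(h)
        assert res.estimate == pytest.approx(0.3, abs=1e-12)
        assert res.extra["intercept"] == pytest.approx(0.0, abs=1e-12)

    def test_exact_affine_fit(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        h = make_harmonized(bx, 0.1 + 0.3 * bx)
        res = egger(h)
        assert res.estimate == pytest.approx(0.3, abs=1e-10)
        assert res.extra["intercept"] == pytest.approx(0.1, abs=1e-10)

    def test_saturated_three_point_fit(self):
        bx = np.array([0.1, 0.2, 0.3])
        h = make_harmonized(bx, 0.05 + 0.7 * bx)
        res = egger(h)
        assert res.estimate == pytest.approx(0.7, abs=1e-12)
        assert res.extra["intercept"] == pytest.approx(0.05, abs=1e-12)

    def test_against_wls_oracle(self, rng):
        bx = np.abs(rng.normal(0.1, 0.05, size=10))
        by = rng.normal(0.02 + 0.4 * bx, 0.01)
        sy = rng.uniform(0.005, 0.02, size=10)
        h = make_harmonized(bx, by, se_out=sy)
        res = egger(h)
        X = sm.add_constant(bx)
        fit = sm.WLS(by, X, weights=1.0 / sy**2).fit()
        assert res.estimate == pytest.approx(fit.params[1], rel=1e-10)
        assert res.extra["intercept"] == pytest.approx(fit.params[0], rel=1e-10)
        # SE convention: WLS se with residual scale clamped at >= 1
        sigma = np.sqrt(fit.scale)
        factor = max(1.0, sigma) / sigma
        assert res.se == pytest.approx(fit.bse[1] * factor, rel=1e-10)

    def test_orientation_invariance(self, rng):
        """Flipping the allele orientation of any subset leaves Egger unchanged."""
        bx = np.abs(rng.normal(0.1, 0.05, size=8)) + 0.01
        by = rng.normal(0.03 + 0.5 * bx, 0.01)
        h1 = make_harmonized(bx, by)
        signs = np.where(rng.uniform(size=8) < 0.5, -1.0, 1.0)
        h2 = make_harmonized(bx * signs, by * signs)
        r1, r2 = egger(h1), egger(h2)
        assert r1.estimate == pytest.approx(r2.estimate, rel=1e-12)
        assert r1.extra["intercept"] == pytest.approx(r2.extra["intercept"],
                                                      rel=1e-12)

    def test_too_few_instruments(self):
        h = make_harmonized([0.1, 0.2], [0.05, 0.1])
        with pytest.raises(InsufficientInstrumentsError):
            egger(h)


class TestWeightedMedian:
    def test_middle_element_equal_weights(self):
        assert _weighted_median_point(np.array([0.1, 0.5, 0.9]),
                                      np.ones(3)) == pytest.approx(0.5)

    def test_hand_interpolation(self):
        # p = (0.45, 0.95); interpolating 0.5 between (0.45, 0) and (0.95, 1)
        est = _weighted_median_point(np.array([0.0, 1.0]),
                                     np.array([0.9, 0.1]))
        assert est == pytest.approx(0.1)

    def test_full_estimator_consensus(self, simple_harmonized):
        res = weighted_median(simple_harmonized, n_boot=200, seed=1)
        assert res.estimate == pytest.approx(0.5)
        assert res.se > 0

    def test_robust_to_minority_outliers(self):
        # 3 valid instruments at ratio 0.2 dominate 2 outliers by weight
        h = make_harmonized([0.2, 0.25, 0.3, 0.1, 0.12],
                            [0.04, 0.05, 0.06, 0.2, 0.3],
                            se_out=[0.005, 0.005, 0.005, 0.05, 0.05])
        res = weighted_median(h, n_boot=200, seed=1)
        assert res.estimate == pytest.approx(0.2, abs=0.02)

    def test_deterministic_given_seed(self, simple_harmonized):
        a = weighted_median(simple_harmonized, n_boot=100, seed=7)
        b = weighted_median(simple_harmonized, n_boot=100, seed=7)
        assert a.se == b.se

    def test_simple_median_equal_weights(self):
        h = make_harmonized([0.1, 0.1, 0.1], [0.01, 0.05, 0.09],
                            se_out=[0.001, 0.01, 0.02])
        res = simple_median(h, n_boot=100, seed=1)
        assert res.estimate == pytest.approx(0.5)  # middle ratio 0.05/0.1


class TestModeEstimator:
    def test_dominant_cluster(self):
        h = make_harmonized([0.1] * 4, [0.02, 0.02, 0.02, 0.08])
        res = mode_estimator(h, n_boot=100, seed=1)
        assert res.estimate == pytest.approx(0.2, abs=0.05)

    def test_all_identical_exact(self):
        h = make_harmonized([0.1, 0.2, 0.4], [0.05, 0.1, 0.2])
        res = mode_estimator(h, n_boot=50, seed=1)
        assert res.estimate == 0.5

    def test_argmax_matches_fine_grid_oracle(self, rng):
        b = np.concatenate([rng.normal(0.2, 0.01, 6), rng.normal(0.8, 0.01, 3)])
        w = np.ones_like(b)
        est = _mode_point(b, w, 1.0)
        bw = _silverman_bandwidth(b)
        fine = np.linspace(b.min() - 3 * bw, b.max() + 3 * bw, 200_001)
        dens = np.exp(-0.5 * ((fine[:, None] - b[None, :]) / bw) ** 2).sum(axis=1)
        oracle = fine[np.argmax(dens)]
        grid_step = (b.max() - b.min() + 6 * bw) / 511
        assert abs(est - oracle) <= grid_step

    def test_bad_bandwidth(self, simple_harmonized):
        with pytest.raises(ParameterError):
            mode_estimator(simple_harmonized, bandwidth_factor=0.0)


class TestRunMR:
    def test_single_snp_skips_multi_methods(self):
        h = make_harmonized([0.5], [0.25])
        results = run_mr(h, ["ivw", "egger"])
        assert [r.method for r in results] == ["ivw_re"]
        assert results[0].estimate == pytest.approx(0.5)

    def test_empty_method_list_raises(self, simple_harmonized):
        with pytest.raises(ParameterError):
            run_mr(simple_harmonized, [])

    def test_unknown_method_raises(self, simple_harmonized):
        with pytest.raises(ParameterError):
            run_mr(simple_harmonized, ["mr_presso"])

    def test_all_skipped_raises(self):
        h = make_harmonized([0.5], [0.25])
        with pytest.raises(InsufficientInstrumentsError):
            run_mr(h, ["egger", "weighted_median"])

    def test_four_method_consistent_sign(self):
        from mrscan import SimulationConfig, harmonize_set, simulate_sumstats
        cfg = SimulationConfig(n_snp=24, theta=-0.3, gamma_mean=0.1,
                               gamma_sd=0.02, seed=42)
        exp, out, _ = simulate_sumstats(cfg)
        h = harmonize_set(exp, out)
        results = run_mr(h, ["ivw_re", "egger", "weighted_median",
                             "weighted_mode"], n_boot=200, seed=42)
        assert len(results) == 4
        assert all(r.estimate < 0 for r in results)
        assert all(r.ci_low <= r.estimate <= r.ci_high for r in results)


class TestEquivariance:
    @pytest.mark.parametrize("seed", range(5))
    def test_sign_equivariance_outcome(self, seed):
        r = np.random.default_rng(seed)
        bx = np.abs(r.normal(0.1, 0.03, 6)) + 0.01
        by = r.normal(0.05, 0.02, 6)
        h_pos = make_harmonized(bx, by)
        h_neg = make_harmonized(bx, -by)
        for fn in (lambda h: ivw(h, mode="fixed"), egger,
                   lambda h: weighted_median(h, n_boot=50, seed=seed)):
            assert fn(h_neg).estimate == pytest.approx(-fn(h_pos).estimate,
                                                       rel=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_sign_equivariance_exposure(self, seed):
        r = np.random.default_rng(seed)
        bx = np.abs(r.normal(0.1, 0.03, 6)) + 0.01
        by = r.normal(0.05, 0.02, 6)
        h_pos = make_harmonized(bx, by)
        h_neg = make_harmonized(-bx, by)
        assert ivw(h_neg, mode="fixed").estimate == pytest.approx(
            -ivw(h_pos, mode="fixed").estimate, rel=1e-9)

    @pytest.mark.parametrize("c", [0.5, 2.0, 10.0])
    def test_scale_equivariance(self, c, rng):
        bx = np.abs(rng.normal(0.1, 0.03, 6)) + 0.01
        by = rng.normal(0.05, 0.02, 6)
        sy = rng.uniform(0.005, 0.02, 6)
        h1 = make_harmonized(bx, by, se_out=sy)
        h2 = make_harmonized(bx, c * by, se_out=c * sy)
        for mode in ("fixed", "random"):
            r1, r2 = ivw(h1, mode=mode), ivw(h2, mode=mode)
            assert r2.estimate == pytest.approx(c * r1.estimate, rel=1e-10)
            assert r2.se == pytest.approx(c * r1.se, rel=1e-10)
        e1, e2 = egger(h1), egger(h2)
        assert e2.estimate == pytest.approx(c * e1.estimate, rel=1e-10)


class TestRatioEstimates:
    def test_values_and_weights(self):
        h = make_harmonized([0.5, 0.2], [0.25, 0.1], se_out=[0.05, 0.02])
        ratios = ratio_estimates(h)
        np.testing.assert_allclose(ratios.b, [0.5, 0.5])
        np.testing.assert_allclose(ratios.se_b, [0.1, 0.1])
        assert np.all(ratios.w > 0)

    def test_zero_beta_exp_raises(self):
        h = make_harmonized([0.0, 0.2], [0.1, 0.1])
        with pytest.raises(ParameterError):
            ratio_estimates(h)
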