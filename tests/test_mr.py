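"""MR estimators against independent oracles and their statistical properties."""

import numpy as np
import pytest
from scipy import stats

from drugmr.mr import (
    InsufficientInstrumentsError,
    UndefinedRatioError,
    egger,
    ivw_mre,
    leave_one_out,
    mr_power_binary,
    mr_power_continuous,
    wald_ratio,
    weighted_median,
    weighted_mode,
)
from tests.conftest import make_hset, random_hset


class TestWaldRatio:
    @pytest.mark.parametrize(
        "bx,sex,by,sey,theta,se",
        [(0.5, 0.01, 0.25, 0.05, 0.5, 0.1),
         (-0.2, 0.01, 0.1, 0.02, -0.5, 0.1),
         (0.3, 0.02, 0.06, 0.03, 0.2, 0.1)],
    )
    def test_examples(self, bx, sex, by, sey, theta, se):
        got_theta, got_se = wald_ratio(bx, sex, by, sey)
        assert got_theta == pytest.approx(theta)
        assert got_se == pytest.approx(se)

    def test_first_order_delta_method(self):
        """se equals the symbolic first-order delta expansion d(by/bx)/d(by) * sey."""
        import sympy

        bx_s, by_s = sympy.symbols("bx by")
        grad_by = sympy.diff(by_s / bx_s, by_s)
        bx, by, sey = 0.3, 0.06, 0.03
        expected = float(abs(grad_by.subs({bx_s: bx, by_s: by}))) * sey
        assert wald_ratio(bx, 0.01, by, sey)[1] == pytest.approx(expected, abs=1e-12)

    def test_zero_bx_raises(self):
        with pytest.raises(UndefinedRatioError):
            wald_ratio(0.0, 0.01, 0.1, 0.02)


def wls_origin_oracle(hset):
    """Independent IVW oracle: statsmodels WLS through the origin, with the
    multiplicative residual-variance inflation floored at 1."""
    import statsmodels.api as sm

    bx = np.array([r.beta_exposure for r in hset.records])
    by = np.array([r.beta_outcome for r in hset.records])
    sy = np.array([r.se_outcome for r in hset.records])
    fit = sm.WLS(by, bx, weights=1 / sy**2).fit()
    se_fixed = float(np.sqrt(1 / np.sum(bx**2 / sy**2)))
    # statsmodels scales by weighted RSS / (J-1) without the floor
    return float(fit.params[0]), max(float(fit.bse[0]), se_fixed)


class TestIvwMre:
    def test_single_instrument_reduces_to_wald(self):
        hs = make_hset([0.5], [0.01], [0.25], [0.05])
        est = ivw_mre(hs)
        theta, se = wald_ratio(0.5, 0.01, 0.25, 0.05)
        assert est.b == theta and est.se == se
        assert est.phi == 1.0 and est.q is None

    def test_zero_residual_case(self):
        hs = make_hset([0.1, 0.2, 0.3], [0.01] * 3, [0.2, 0.4, 0.6], [0.05, 0.04, 0.03])
        est = ivw_mre(hs)
        assert est.b == pytest.approx(2.0)
        assert est.q == pytest.approx(0.0, abs=1e-20)
        assert est.phi == 1.0

    def test_matches_wls_oracle_to_ten_decimals(self, rng):
        for _ in range(20):
            hs = random_hset(rng, j=int(rng.integers(3, 12)), slope=float(rng.normal(0, 1)))
            est = ivw_mre(hs)
            b_o, se_o = wls_origin_oracle(hs)
            assert est.b == pytest.approx(b_o, abs=1e-10)
            assert est.se == pytest.approx(se_o, abs=1e-10)

    def test_joint_sign_flip_invariance(self, hset8):
        est = ivw_mre(hset8)
        import copy
        import dataclasses

        flipped = copy.deepcopy(hset8)
        flipped.records = [
            dataclasses.replace(r, beta_exposure=-r.beta_exposure, beta_outcome=-r.beta_outcome)
            if i % 2 else r
            for i, r in enumerate(flipped.records)
        ]
        est2 = ivw_mre(flipped)
        assert est2.b == pytest.approx(est.b, abs=1e-14)
        assert est2.se == pytest.approx(est.se, abs=1e-14)

    def test_or_decrease_transform(self, hset8):
        est = ivw_mre(hset8)
        assert est.or_decrease == pytest.approx(1 / np.exp(est.b))
        assert est.ci_low <= est.or_decrease <= est.ci_high

    def test_empty_raises(self):
        with pytest.raises(InsufficientInstrumentsError):
            ivw_mre(make_hset([], [], [], []))


def _summary_draws(rng, j, slope, intercept=0.0, sx_scale=0.01):
    bx_true = rng.uniform(0.1, 0.4, j)
    sx = np.full(j, sx_scale)
    sy = rng.uniform(0.03, 0.08, j)
    bx = rng.normal(bx_true, sx)
    by = rng.normal(intercept + slope * bx_true, sy)
    return make_hset(bx, sx, by, sy)


class TestEgger:
    def test_two_instruments_raise(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger(make_hset([0.1, 0.2], [0.01] * 2, [0.2, 0.4], [0.05] * 2))

    def test_matches_weighted_regression_oracle(self, rng):
        import statsmodels.api as sm

        hs = random_hset(rng, j=10, slope=0.4)
        est, extras = egger(hs)
        bx = np.abs([r.beta_exposure for r in hs.records])
        by = [np.sign(r.beta_exposure) * r.beta_outcome for r in hs.records]
        sy = np.array([r.se_outcome for r in hs.records])
        fit = sm.WLS(by, sm.add_constant(bx), weights=1 / sy**2).fit()
        assert est.b == pytest.approx(fit.params[1], abs=1e-10)
        assert extras.intercept == pytest.approx(fit.params[0], abs=1e-10)
        # statsmodels scales the covariance by s2 without the floor at 1
        s2 = fit.mse_resid
        factor = np.sqrt(max(1.0, s2) / s2)
        assert est.se == pytest.approx(fit.bse[1] * factor, rel=1e-9)
        assert extras.intercept_se == pytest.approx(fit.bse[0] * factor, rel=1e-9)

    def test_zero_intercept_slope_agrees_with_ivw(self, rng):
        """No pleiotropy and wide betaX spread: Egger and IVW agree on average."""
        diffs = []
        for _ in range(300):
            hs = _summary_draws(rng, j=12, slope=0.5)
            diffs.append(egger(hs)[0].b - ivw_mre(hs).b)
        assert abs(np.mean(diffs)) < 3 * np.std(diffs) / np.sqrt(len(diffs)) + 0.01

    def test_constant_pleiotropy_recovered_as_intercept(self, rng):
        c = 0.08
        intercepts = [egger(_summary_draws(rng, j=12, slope=0.5, intercept=c))[1].intercept
                      for _ in range(300)]
        sem = np.std(intercepts) / np.sqrt(len(intercepts))
        assert np.mean(intercepts) == pytest.approx(c, abs=3 * sem + 0.005)


def grid_search_weighted_median(theta, w):
    """Oracle: scan a fine grid for the point where weight below equals half,
    using the midpoint-interpolated definition."""
    order = np.argsort(theta)
    th, wn = np.asarray(theta)[order], np.asarray(w)[order] / np.sum(w)
    s = np.cumsum(wn) - wn / 2
    grid = np.linspace(th[0], th[-1], 200001)
    interp = np.interp(0.5, s, th)
    return grid[np.argmin(np.abs(grid - interp))]


class TestWeightedMedian:
    def test_equal_weights_gives_simple_median(self):
        bx = [0.2] * 5
        by = [0.2 * t for t in (0.1, 0.3, 0.5, 0.7, 0.9)]
        hs = make_hset(bx, [0.01] * 5, by, [0.05] * 5)
        est = weighted_median(hs, n_boot=200, seed=1)
        assert est.b == pytest.approx(0.5)

    def test_majority_weight_instrument_wins(self):
        bx = [1.0, 0.1, 0.1, 0.1]
        by = [2.0, 0.05, 0.07, 0.06]  # first instrument ratio 2, weight > 50%
        hs = make_hset(bx, [0.01] * 4, by, [0.05] * 4)
        est = weighted_median(hs, n_boot=200, seed=1)
        assert est.b == pytest.approx(2.0, abs=0.05)

    def test_matches_grid_search_oracle(self):
        bx = np.array([0.3, 0.2, 0.25, 0.15])
        by = np.array([0.09, 0.11, 0.02, 0.12])
        sy = np.array([0.05, 0.03, 0.06, 0.02])
        hs = make_hset(bx, [0.01] * 4, by, sy)
        est = weighted_median(hs, n_boot=100, seed=1)
        theta = by / bx
        w = bx**2 / sy**2
        assert est.b == pytest.approx(grid_search_weighted_median(theta, w), abs=1e-5)

    def test_too_few_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            weighted_median(make_hset([0.1, 0.2], [0.01] * 2, [0.1, 0.2], [0.05] * 2))


class TestWeightedMode:
    def test_all_ratios_identical(self):
        hs = make_hset([0.1, 0.2, 0.4], [0.01] * 3, [0.05, 0.1, 0.2], [0.05] * 3)
        est = weighted_mode(hs, n_boot=100, seed=1)
        assert est.b == pytest.approx(0.5, abs=1e-9)

    def test_heavier_cluster_wins(self):
        # 4 instruments with ratio ~1.0 carrying most weight, 2 outliers at 3.0
        bx = [0.3, 0.31, 0.29, 0.3, 0.1, 0.11]
        by = [0.30, 0.32, 0.28, 0.31, 0.30, 0.33]
        sy = [0.03] * 4 + [0.03] * 2
        hs = make_hset(bx, [0.01] * 6, by, sy)
        est = weighted_mode(hs, n_boot=100, seed=1)
        assert est.b == pytest.approx(1.0, abs=0.15)

    def test_permutation_invariance(self, hset8):
        est = weighted_mode(hset8, n_boot=50, seed=3)
        from drugmr.sumstats import HarmonizedSet

        perm = HarmonizedSet(records=list(reversed(hset8.records)))
        est_perm = weighted_mode(perm, n_boot=50, seed=3)
        assert est_perm.b == pytest.approx(est.b, abs=1e-12)


class TestLeaveOneOut:
    def test_homogeneous_set_unflagged(self):
        hs = make_hset([0.1, 0.2, 0.3], [0.01] * 3, [0.05, 0.1, 0.15], [0.01] * 3)
        results = leave_one_out(hs)
        assert len(results) == 3
        assert not any(r.flagged for r in results)

    def test_planted_outlier_flagged(self):
        # the outlier drags the pooled slope positive; omitting it flips the sign
        bx = [0.2, 0.25, 0.3, 0.2]
        by = [-0.01, -0.012, -0.015, 0.5]
        hs = make_hset(bx, [0.01] * 4, by, [0.02] * 4)
        results = leave_one_out(hs)
        flagged = [r.excluded_variant for r in results if r.flagged]
        assert "rs4" in flagged

    def test_output_length_and_error(self, hset8):
        assert len(leave_one_out(hset8)) == len(hset8)
        from tests.conftest import make_hset as mh

        with pytest.raises(InsufficientInstrumentsError):
            leave_one_out(mh([0.1], [0.01], [0.1], [0.05]))


class TestPower:
    def test_null_or_gives_alpha(self):
        assert mr_power_binary(50_000, 0.02, 0.05, 1.0, alpha=0.05) == pytest.approx(0.05)
        assert mr_power_continuous(50_000, 0.02, 0.0, alpha=0.05) == pytest.approx(0.05)

    def test_monotone_in_n(self):
        powers = [mr_power_binary(n, 0.02, 0.05, 0.7) for n in (1e3, 1e4, 1e5, 1e6)]
        assert powers == sorted(powers)
        assert powers[-1] > 0.999

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            mr_power_binary(-5, 0.02, 0.05, 0.7)
        with pytest.raises(ValueError):
            mr_power_binary(100, 0.02, 1.5, 0.7)

    def test_against_two_stage_simulation(self):
        """Rejection rate of the summary-level Wald ratio test under the
        alternative, simulated at the individual level."""
        n, r2, k, or_alt = 50_000, 0.02, 0.05, 0.7
        expected = mr_power_binary(n, r2, k, or_alt, alpha=0.05)
        rng = np.random.default_rng(8)
        n_reps, batch = 2000, 40
        from drugmr.simulate import marginal_linear, marginal_logistic

        rejections = 0
        logb = np.log(or_alt)
        for _ in range(n_reps // batch):
            g = rng.binomial(2, 0.3, size=(n, batch)).astype(float)
            score = (g - g.mean(0)) / g.std(0) * np.sqrt(r2)
            # exposure cohort (independent sample) for the denominator
            g_x = rng.binomial(2, 0.3, size=(n, batch)).astype(float)
            score_x = (g_x - g_x.mean(0)) / g_x.std(0) * np.sqrt(r2)
            e_x = score_x + rng.standard_normal((n, batch)) * np.sqrt(1 - r2)
            e_y = score + rng.standard_normal((n, batch)) * np.sqrt(1 - r2)
            for j in range(batch):
                bx, sx, _ = marginal_linear(g_x[:, [j]], e_x[:, j])
                lp = logb * e_y[:, j]
                a0 = np.log(k / (1 - k)) - lp.mean()
                y = (rng.random(n) < 1 / (1 + np.exp(-(a0 + lp)))).astype(np.int8)
                by, sy, _ = marginal_logistic(g[:, [j]], y)
                theta_se = sy[0] / abs(bx[0])
                z = (by[0] / bx[0]) / theta_se
                rejections += abs(z) > stats.norm.ppf(0.975)
        rate = rejections / n_reps
        assert rate == pytest.approx(expected, abs=0.03)


class TestCalibrationSummaryLevel:
    """Fast summary-level checks of IVW calibration (no genotype simulation)."""

    def test_null_type_one_error_and_q_uniformity(self, rng):
        rejections = 0
        q_pvals = []
        for _ in range(1000):
            hs = _summary_draws(rng, j=10, slope=0.0)
            est = ivw_mre(hs)
            rejections += est.pval < 0.05
            q_pvals.append(est.q_pval)
        assert 0.033 <= rejections / 1000 <= 0.067
        ks = stats.kstest(q_pvals, "uniform").statistic
        assert ks < 0.05

    def test_causal_coverage(self, rng):
        slope = 0.5
        covered = 0
        for _ in range(500):
            hs = _summary_draws(rng, j=10, slope=slope)
            est = ivw_mre(hs)
            covered += est.b - 1.96 * est.se <= slope <= est.b + 1.96 * est.se
        assert 0.93 <= covered / 500 <= 0.98

    def test_weighted_median_beats_ivw_under_40pct_pleiotropy(self, rng):
        wins = 0
        n_reps = 200
        slope = 0.3
        for _ in range(n_reps):
            j = 10
            bx_true = rng.uniform(0.2, 0.4, j)
            sy = np.full(j, 0.02)
            alpha = np.zeros(j)
            alpha[:4] = rng.uniform(0.1, 0.2, 4)  # directional, 40% of instruments
            bx = rng.normal(bx_true, 0.01)
            by = rng.normal(slope * bx_true + alpha, sy)
            hs = make_hset(bx, [0.01] * j, by, sy)
            wm = weighted_median(hs, n_boot=2, seed=0)
            iv = ivw_mre(hs)
            wins += abs(wm.b - slope) < abs(iv.b - slope)
        assert wins / n_reps >= 0.8
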