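"""MR estimators against independent oracles and their invariance properties."""

import numpy as np
import pytest
from scipy.stats import norm

from proteomr.estimators import (
    ivw_fixed,
    mr_presso,
    wald_ratio,
    weighted_median,
    weighted_mode,
)
from proteomr.exceptions import InsufficientInstrumentsError, UndefinedRatioError


def _random_pairs(rng, n, theta=0.3, bx_scale=0.3, by_se_scale=0.02):
    bx = rng.uniform(0.1, bx_scale + 0.1, n) * rng.choice([-1, 1], n)
    bx_se = rng.uniform(0.005, 0.02, n)
    by_se = rng.uniform(0.5, 1.5, n) * by_se_scale
    by = theta * bx + rng.normal(0, by_se)
    return bx, bx_se, by, by_se


class TestWaldRatio:
    @pytest.mark.parametrize("bx,by,by_se,beta,se", [
        (0.5, 0.1, 0.05, 0.2, 0.1),
        (0.5, 0.0, 0.05, 0.0, 0.1),
        (0.2, 0.03, 0.01, 0.15, 0.05),
    ])
    def test_ratio_and_delta_method_se(self, bx, by, by_se, beta, se):
        est = wald_ratio(bx, by, by_se)
        assert est.beta == pytest.approx(beta)
        assert est.se == pytest.approx(se)
        assert est.pvalue == pytest.approx(2 * norm.sf(abs(beta / se)) if beta else 1.0)

    def test_zero_exposure_effect_is_an_error(self):
        with pytest.raises(UndefinedRatioError):
            wald_ratio(0.0, 0.1, 0.05)

    def test_second_order_se_exceeds_first_order(self):
        first = wald_ratio(0.5, 0.1, 0.05)
        second = wald_ratio(0.5, 0.1, 0.05, bx_se=0.1, second_order=True)
        assert second.se > first.se


class TestIVW:
    def test_single_pair_reduces_to_wald(self):
        w = wald_ratio(0.5, 0.1, 0.05)
        i = ivw_fixed([0.5], [0.1], [0.05])
        assert (i.beta, i.se) == (pytest.approx(w.beta), pytest.approx(w.se))

    def test_duplicated_pair_halves_variance(self):
        one = ivw_fixed([0.5], [0.1], [0.05])
        two = ivw_fixed([0.5, 0.5], [0.1, 0.1], [0.05, 0.05])
        assert two.beta == pytest.approx(one.beta)
        assert two.se == pytest.approx(one.se / np.sqrt(2))

    def test_matches_wls_through_origin_oracle(self, rng):
        import statsmodels.api as sm

        for _ in range(100):
            n = int(rng.integers(2, 12))
            bx, _, by, by_se = _random_pairs(rng, n)
            est = ivw_fixed(bx, by, by_se)
            fit = sm.WLS(by, bx, weights=by_se**-2.0).fit()
            assert est.beta == pytest.approx(fit.params[0], rel=1e-12)

    def test_empty_input_is_an_error(self):
        with pytest.raises(InsufficientInstrumentsError):
            ivw_fixed([], [], [])

    def test_cochran_q_zero_for_perfect_fit(self):
        est = ivw_fixed([0.2, 0.4], [0.06, 0.12], [0.01, 0.01])
        assert est.diagnostics["cochran_q"] == pytest.approx(0.0, abs=1e-20)


class TestWeightedMedian:
    def test_degenerate_equal_ratios(self):
        bx = np.array([0.2, 0.4, 0.8])
        est = weighted_median(bx, bx * 0 + 0.01, 0.3 * bx, [0.01, 0.03, 0.02],
                              bootstrap_reps=50, seed=0)
        assert est.beta == pytest.approx(0.3)

    def test_equal_weights_middle_order_statistic(self):
        bx = np.array([1.0, 1.0, 1.0])
        by = np.array([0.1, 0.2, 0.9])
        est = weighted_median(bx, bx * 0 + 0.01, by, np.ones(3), bootstrap_reps=0)
        assert est.beta == pytest.approx(0.2)

    def test_requires_three_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            weighted_median([0.1, 0.2], [0.01, 0.01], [0.1, 0.2], [0.01, 0.01])

    def test_estimate_within_ratio_range(self, rng):
        for _ in range(50):
            bx, bx_se, by, by_se = _random_pairs(rng, int(rng.integers(3, 10)))
            est = weighted_median(bx, bx_se, by, by_se, bootstrap_reps=0)
            ratios = by / bx
            assert ratios.min() - 1e-12 <= est.beta <= ratios.max() + 1e-12

    def test_robust_to_minority_directional_pleiotropy(self, rng):
        # 4 of 10 instruments get a large directional shift (<50% of weight):
        # the median stays near truth while the IVW is pulled away
        theta, reps = 0.3, 400
        med, ivw = [], []
        for _ in range(reps):
            bx = rng.uniform(0.2, 0.4, 10)
            by_se = np.full(10, 0.01)
            by = theta * bx + rng.normal(0, by_se)
            by[:4] += 0.15
            med.append(weighted_median(bx, np.full(10, 0.01), by, by_se,
                                       bootstrap_reps=0).beta)
            ivw.append(ivw_fixed(bx, by, by_se).beta)
        med, ivw = np.array(med), np.array(ivw)
        assert abs(med.mean() - theta) < 3 * med.std()
        assert abs(ivw.mean() - theta) > 3 * ivw.std()
        assert abs(med.mean() - theta) < abs(ivw.mean() - theta) / 3


class TestWeightedMode:
    def test_degenerate_equal_ratios(self):
        bx = np.array([0.2, 0.4, 0.8])
        est = weighted_mode(bx, bx * 0 + 0.01, 0.25 * bx, [0.01, 0.02, 0.01],
                            bootstrap_reps=0)
        assert est.beta == pytest.approx(0.25)

    def test_plurality_cluster_wins(self, rng):
        bx = np.ones(10) * 0.5
        by = 0.5 * np.concatenate([rng.normal(0.3, 0.01, 7), rng.normal(1.5, 0.01, 3)])
        est = weighted_mode(bx, np.full(10, 0.01), by, np.full(10, 0.01),
                            bootstrap_reps=0)
        assert est.beta == pytest.approx(0.3, abs=0.05)

    def test_stable_under_bandwidth_doubling(self, rng):
        bx = np.ones(10) * 0.5
        by = 0.5 * np.concatenate([rng.normal(0.3, 0.01, 7), rng.normal(1.5, 0.01, 3)])
        a = weighted_mode(bx, np.full(10, 0.01), by, np.full(10, 0.01),
                          bandwidth_factor=1.0, bootstrap_reps=0)
        b = weighted_mode(bx, np.full(10, 0.01), by, np.full(10, 0.01),
                          bandwidth_factor=2.0, bootstrap_reps=0)
        assert b.beta == pytest.approx(a.beta, abs=0.05)

    def test_requires_three_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            weighted_mode([0.1], [0.01], [0.1], [0.01])


class TestMRPresso:
    def test_requires_four_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            mr_presso([0.1] * 3, [0.01] * 3, [0.1] * 3, [0.01] * 3)

    def test_clean_instruments_no_correction(self, rng):
        bx, bx_se, by, by_se = _random_pairs(rng, 10)
        est = mr_presso(bx, bx_se, by, by_se, n_simulations=300, seed=5)
        full = ivw_fixed(bx, by, by_se)
        assert est.diagnostics["outlier_indices"] == []
        assert est.beta == pytest.approx(full.beta)
        assert est.n_instruments == 10

    def test_gross_outlier_flagged_and_corrected(self, rng):
        bx, bx_se, by, by_se = _random_pairs(rng, 11, theta=0.3)
        by = by.copy()
        by[7] += 10 * by_se[7]
        est = mr_presso(bx, bx_se, by, by_se, n_simulations=500, seed=6)
        assert 7 in est.diagnostics["outlier_indices"]
        keep = [i for i in range(11) if i not in est.diagnostics["outlier_indices"]]
        clean = ivw_fixed(bx[keep], by[keep], by_se[keep])
        assert est.beta == pytest.approx(clean.beta)
        assert est.diagnostics["global_pvalue"] < 0.05
        assert "distortion_pvalue" in est.diagnostics

    def test_global_null_p_is_not_degenerate(self, rng):
        ps = []
        for _ in range(40):
            bx, bx_se, by, by_se = _random_pairs(rng, 10)
            ps.append(mr_presso(bx, bx_se, by, by_se, n_simulations=200,
                                seed=int(rng.integers(2**31 - 1))).diagnostics["global_pvalue"])
        ps = np.array(ps)
        assert 0.2 < ps.mean() < 0.8  # roughly uniform under the null


class TestEquivariance:
    @pytest.mark.parametrize("method", ["ivw", "median", "mode"])
    def test_sign_equivariance_in_exposure(self, rng, method):
        bx, bx_se, by, by_se = _random_pairs(rng, 8)
        if method == "ivw":
            a, b = ivw_fixed(bx, by, by_se), ivw_fixed(-bx, by, by_se)
        elif method == "median":
            a = weighted_median(bx, bx_se, by, by_se, 200, seed=1)
            b = weighted_median(-bx, bx_se, by, by_se, 200, seed=1)
        else:
            a = weighted_mode(bx, bx_se, by, by_se, bootstrap_reps=200, seed=1)
            b = weighted_mode(-bx, bx_se, by, by_se, bootstrap_reps=200, seed=1)
        assert b.beta == pytest.approx(-a.beta, rel=1e-9)
        if method == "ivw":
            assert b.se == pytest.approx(a.se, rel=1e-12)
        else:
            # bootstrap SEs match in distribution, not draw-for-draw
            assert b.se == pytest.approx(a.se, rel=0.25)

    @pytest.mark.parametrize("k", [0.5, 3.0])
    def test_outcome_scale_equivariance(self, rng, k):
        bx, bx_se, by, by_se = _random_pairs(rng, 8)
        a = ivw_fixed(bx, by, by_se)
        b = ivw_fixed(bx, k * by, k * by_se)
        assert b.beta == pytest.approx(k * a.beta, rel=1e-12)
        assert b.se == pytest.approx(k * a.se, rel=1e-12)
        m1 = weighted_median(bx, bx_se, by, by_se, 0)
        m2 = weighted_median(bx, bx_se, k * by, k * by_se, 0)
        assert m2.beta == pytest.approx(k * m1.beta, rel=1e-9)

    def test_no_pleiotropy_mean_recovery_all_estimators(self, rng):
        # strong instruments, no pleiotropy: every estimator centres on truth
        theta, reps = 0.3, 300
        res = {"ivw": [], "median": [], "mode": []}
        for _ in range(reps):
            bx = rng.uniform(0.2, 0.5, 8)
            bx_se = np.full(8, 0.005)
            by_se = np.full(8, 0.01)
            by = theta * bx + rng.normal(0, by_se)
            res["ivw"].append(ivw_fixed(bx, by, by_se).beta)
            res["median"].append(weighted_median(bx, bx_se, by, by_se, 0).beta)
            res["mode"].append(weighted_mode(bx, bx_se, by, by_se, bootstrap_reps=0).beta)
        for name, vals in res.items():
            vals = np.array(vals)
            mc_se = vals.std() / np.sqrt(reps)
            assert abs(vals.mean() - theta) < 3.5 * mc_se, name
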