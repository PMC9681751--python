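import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metaepi.exceptions import (
    InsufficientClustersError,
    InsufficientDataError,
    NoContrastError,
    ValidationError,
)
from metaepi.meta_core import (
    estimate_tau2,
    meta_regress_binary,
    pool_random_effects,
    robust_se,
)

effects_st = st.lists(st.floats(-3, 3), min_size=3, max_size=8)


def brute_force_wls(y, v, labels, tau2):
    """Independent oracle: explicit 2x2 normal-equations solve."""
    y = np.asarray(y, float)
    w = 1.0 / (np.asarray(v, float) + tau2)
    x = np.asarray(labels, float)
    s_w, s_wx = w.sum(), (w * x).sum()
    s_wxx = (w * x * x).sum()
    s_wy, s_wxy = (w * y).sum(), (w * x * y).sum()
    det = s_w * s_wxx - s_wx**2
    intercept = (s_wxx * s_wy - s_wx * s_wxy) / det
    slope = (s_w * s_wxy - s_wx * s_wy) / det
    se_slope = np.sqrt(s_w / det)
    return intercept, slope, se_slope


class TestTau2:
    def test_identical_effects_give_zero_both_methods(self):
        for method in ("DL", "REML"):
            assert estimate_tau2([0.5, 0.5, 0.5], [0.1, 0.2, 0.3],
                                 method) == pytest.approx(0.0, abs=1e-8)

    def test_dl_hand_computed(self):
        # w = 10,10; Q = 5; C = 10; tau2 = (5-1)/10
        assert estimate_tau2([0.0, 1.0], [0.1, 0.1], "DL") == pytest.approx(0.4)

    @settings(max_examples=50, derandomize=True)
    @given(effects=effects_st, shift=st.floats(-5, 5))
    def test_location_invariance(self, effects, shift):
        v = [0.1 + 0.05 * i for i in range(len(effects))]
        for method in ("DL", "REML"):
            t0 = estimate_tau2(effects, v, method)
            t1 = estimate_tau2([e + shift for e in effects], v, method)
            assert t1 == pytest.approx(t0, abs=1e-6)

    def test_dl_reml_agree_when_q_below_df(self):
        # nearly identical effects with large variances: Q << df
        y = [0.50, 0.51, 0.49, 0.50]
        v = [1.0, 1.2, 0.9, 1.1]
        dl = estimate_tau2(y, v, "DL")
        reml = estimate_tau2(y, v, "REML")
        assert dl == pytest.approx(0.0, abs=1e-6)
        assert reml == pytest.approx(0.0, abs=1e-6)

    def test_single_effect_rejected(self):
        with pytest.raises(InsufficientDataError):
            estimate_tau2([0.5], [0.1])

    def test_zero_variances_rejected(self):
        with pytest.raises(ValidationError):
            estimate_tau2([0.1, 0.5], [0.0, 0.0])


class TestPooling:
    def test_identical_effects_pool_to_that_value(self):
        p = pool_random_effects([0.7, 0.7, 0.7], [0.1, 0.2, 0.4])
        assert p.estimate == pytest.approx(0.7)
        assert p.i2 == 0.0
        assert p.se == pytest.approx(np.sqrt(1 / (10 + 5 + 2.5)))

    def test_hand_computed_two_study_case(self):
        p = pool_random_effects([0.0, 1.0], [0.1, 0.1], method="DL")
        assert p.estimate == pytest.approx(0.5)
        assert p.tau2 == pytest.approx(0.4)
        assert p.i2 == pytest.approx(80.0)

    def test_tau2_zero_equals_fixed_effect_oracle(self):
        y = np.array([0.2, 0.5, -0.1, 0.8])
        v = np.array([0.05, 0.1, 0.2, 0.08])
        p = pool_random_effects(y, v, tau2=0.0)
        w = 1 / v
        assert p.estimate == pytest.approx(float((w * y).sum() / w.sum()),
                                           abs=1e-12)
        assert p.se == pytest.approx(float(np.sqrt(1 / w.sum())), abs=1e-12)

    def test_large_tau2_limit_is_unweighted_mean(self):
        y = [0.1, 0.9, 0.5]
        p = pool_random_effects(y, [0.01, 0.5, 0.1], tau2=1e8)
        assert p.estimate == pytest.approx(np.mean(y), abs=1e-5)

    @settings(max_examples=50, derandomize=True)
    @given(scale=st.floats(0.1, 10))
    def test_i2_is_scale_free(self, scale):
        y = np.array([0.0, 0.4, 1.0, 0.2])
        v = np.array([0.05, 0.1, 0.07, 0.2])
        a = pool_random_effects(y, v, method="DL")
        b = pool_random_effects(y * scale, v * scale**2, method="DL")
        assert b.i2 == pytest.approx(a.i2, abs=1e-9)
        assert 0.0 <= a.i2 <= 100.0

    def test_knapp_hartung_ci_uses_t_quantile(self):
        y = [0.0, 0.3, 0.9, 0.4, 0.6]
        v = [0.1, 0.1, 0.1, 0.1, 0.1]
        wald = pool_random_effects(y, v, ci_method="wald")
        kh = pool_random_effects(y, v, ci_method="knapp_hartung")
        assert wald.estimate == kh.estimate
        assert kh.ci_low != wald.ci_low


class TestMetaRegression:
    def test_saturated_binary_equals_subgroup_pooling(self):
        # with tau2 fixed at 0 the slope is the difference of the
        # inverse-variance weighted subgroup means
        y = np.array([0.2, 0.4, 0.9, 1.3, 1.1])
        v = np.array([0.05, 0.08, 0.1, 0.06, 0.12])
        lab = np.array([0, 0, 1, 1, 1])
        reg = meta_regress_binary(y, v, lab, tau2=0.0)
        w = 1 / v
        m1 = (w[lab == 1] * y[lab == 1]).sum() / w[lab == 1].sum()
        m0 = (w[lab == 0] * y[lab == 0]).sum() / w[lab == 0].sum()
        assert reg.slope == pytest.approx(m1 - m0, abs=1e-10)
        assert reg.intercept == pytest.approx(m0, abs=1e-10)

    def test_shift_moves_intercept_not_slope(self):
        y = [0.2, 0.4, 0.9, 1.3]
        v = [0.1, 0.1, 0.1, 0.1]
        lab = [0, 0, 1, 1]
        a = meta_regress_binary(y, v, lab)
        b = meta_regress_binary([yi + 2.5 for yi in y], v, lab)
        assert b.slope == pytest.approx(a.slope, abs=1e-8)
        assert b.intercept == pytest.approx(a.intercept + 2.5, abs=1e-8)

    def test_label_swap_negates_slope(self):
        y = [0.2, 0.4, 0.9, 1.3, 0.7]
        v = [0.1, 0.2, 0.1, 0.15, 0.1]
        lab = np.array([0, 0, 1, 1, 1])
        a = meta_regress_binary(y, v, lab)
        b = meta_regress_binary(y, v, 1 - lab)
        assert b.slope == pytest.approx(-a.slope, abs=1e-10)
        assert b.se_slope == pytest.approx(a.se_slope, rel=1e-10)

    def test_single_label_value_is_no_contrast(self):
        with pytest.raises(NoContrastError):
            meta_regress_binary([0.1, 0.2, 0.3], [0.1] * 3, [1, 1, 1])

    def test_two_observations_insufficient(self):
        with pytest.raises(InsufficientDataError):
            meta_regress_binary([0.1, 0.2], [0.1, 0.1], [0, 1])

    @settings(max_examples=60, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_brute_force_normal_equations(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 6))
        lab = np.zeros(n, int)
        lab[: max(1, n // 2)] = 1
        rng.shuffle(lab)
        if lab.min() == lab.max():
            lab[0] = 1 - lab[0]
        y = rng.normal(0.5, 1.0, n)
        v = rng.uniform(0.02, 0.5, n)
        for method in ("DL", "REML"):
            reg = meta_regress_binary(y, v, lab, method=method)
            i0, s0, se0 = brute_force_wls(y, v, lab, reg.tau2_residual)
            assert reg.intercept == pytest.approx(i0, abs=1e-8)
            assert reg.slope == pytest.approx(s0, abs=1e-8)
            assert reg.se_slope == pytest.approx(se0, abs=1e-8)

    def test_cross_check_against_statsmodels_wls(self):
        import statsmodels.api as sm

        y = np.array([0.2, 0.4, 0.9, 1.3, 0.7, 1.0])
        v = np.array([0.1, 0.2, 0.1, 0.15, 0.1, 0.3])
        lab = np.array([0, 0, 1, 1, 1, 0])
        reg = meta_regress_binary(y, v, lab, method="DL")
        X = sm.add_constant(lab.astype(float))
        fit = sm.WLS(y, X, weights=1 / (v + reg.tau2_residual)).fit()
        assert reg.slope == pytest.approx(fit.params[1], abs=1e-10)
        assert reg.intercept == pytest.approx(fit.params[0], abs=1e-10)


class TestRobustSE:
    @staticmethod
    def _data(seed=0, n_clusters=12, arms=1):
        rng = np.random.default_rng(seed)
        y, v, lab, cl = [], [], [], []
        for c in range(n_clusters):
            eff = rng.normal(0.5, 0.4)
            for _ in range(arms):
                y.append(eff + rng.normal(0, 0.2))
                v.append(float(rng.uniform(0.05, 0.2)))
                lab.append(c % 2)
                cl.append(f"S{c}")
        return np.array(y), np.array(v), np.array(lab), np.array(cl)

    def test_singleton_clusters_close_to_model_se(self):
        y, v, lab, cl = self._data(seed=3, n_clusters=20)
        reg = meta_regress_binary(y, v, lab)
        rv = robust_se(y, v, lab, cl, tau2=reg.tau2_residual)
        # HC2-type sandwich on homogeneous data: same order of magnitude
        assert rv.se == pytest.approx(reg.se_slope, rel=0.5)
        assert rv.n_clusters == 20

    def test_duplicating_rows_within_clusters_does_not_halve_se(self):
        y, v, lab, cl = self._data(seed=5, n_clusters=10)
        reg = meta_regress_binary(y, v, lab, tau2=0.1)
        base = robust_se(y, v, lab, cl, tau2=0.1)
        y2, v2 = np.tile(y, 2), np.tile(v, 2)
        lab2, cl2 = np.tile(lab, 2), np.tile(cl, 2)
        reg2 = meta_regress_binary(y2, v2, lab2, tau2=0.1)
        dup = robust_se(y2, v2, lab2, cl2, tau2=0.1)
        assert reg2.slope == pytest.approx(reg.slope, abs=1e-10)
        # naive model se shrinks by sqrt(2); CR2 must not
        assert reg2.se_slope == pytest.approx(reg.se_slope / np.sqrt(2),
                                              rel=1e-6)
        assert dup.se > base.se / np.sqrt(2) * 1.2

    def test_single_cluster_rejected(self):
        y, v, lab, _ = self._data(seed=1, n_clusters=4)
        with pytest.raises(InsufficientClustersError):
            robust_se(y, v, lab, ["S0"] * len(y))

    def test_satterthwaite_df_positive_and_below_cluster_count(self):
        y, v, lab, cl = self._data(seed=7, n_clusters=8, arms=3)
        rv = robust_se(y, v, lab, cl)
        assert 0 < rv.df <= rv.n_clusters
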