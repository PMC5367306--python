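import numpy as np
import pytest

from scallopop import (
    colour_index,
    lmm_random_intercept,
    oneway_anova,
    rgb_to_grey,
    run_association,
)


class TestRgbToGrey:
    def test_channel_mean(self):
        img = np.array([[[30, 60, 90]]], dtype=np.uint8)
        assert rgb_to_grey(img)[0, 0] == 60

    def test_bounds(self):
        img = np.array([[[0, 0, 0], [255, 255, 255]]], dtype=np.uint8)
        assert list(rgb_to_grey(img)[0]) == [0, 255]

    def test_rounding_half_up(self):
        img = np.array([[[1, 1, 2], [1, 2, 2]]], dtype=np.uint8)
        # means 1.33 and 1.67 round to 1 and 2
        assert list(rgb_to_grey(img)[0]) == [1, 2]

    def test_wrong_channel_count(self):
        with pytest.raises(ValueError):
            rgb_to_grey(np.zeros((4, 4)))


class TestColourIndex:
    def test_unpigmented_shell(self):
        grey = np.full((5, 5), 200)
        res = colour_index(grey, np.ones((5, 5), bool))
        assert res.pigment_fraction == 0.0 and res.colour_index == 0.0

    def test_fully_pigmented_shell(self):
        grey = np.full((5, 5), 100)
        res = colour_index(grey, np.ones((5, 5), bool))
        assert res.colour_index == pytest.approx(10.0)

    def test_half_pigmented_hand_value(self):
        grey = np.array([[100, 100], [200, 200]])
        res = colour_index(grey, np.ones((2, 2), bool))
        assert res.mean_pigment_grey == 100.0
        assert res.pigment_fraction == 0.5
        assert res.colour_index == pytest.approx(np.sqrt(50.0), abs=1e-4)

    def test_pixels_outside_mask_ignored(self):
        grey = np.array([[100, 0], [200, 0]])
        mask = np.array([[True, False], [True, False]])
        res = colour_index(grey, mask)
        assert res.pigment_fraction == 0.5 and res.mean_pigment_grey == 100.0

    def test_threshold_inclusivity(self):
        grey = np.full((2, 2), 110)
        mask = np.ones((2, 2), bool)
        assert colour_index(grey, mask, inclusive=True).pigment_fraction == 1.0
        assert colour_index(grey, mask, inclusive=False).pigment_fraction == 0.0

    def test_monotone_in_fraction(self):
        mask = np.ones((10, 10), bool)
        vals = []
        for k in (10, 30, 60):
            grey = np.full((10, 10), 200)
            grey.ravel()[:k] = 80
            vals.append(colour_index(grey, mask).colour_index)
        assert vals[0] < vals[1] < vals[2]


class TestOnewayAnova:
    def test_equal_groups_give_zero_f(self):
        res = oneway_anova([1.0, 2.0, 1.0, 2.0], ["a", "a", "b", "b"])
        assert res.statistic == pytest.approx(0.0)

    def test_hand_computed_f(self):
        # SSB = 13.5 on 1 df, SSW = 4 on 4 df -> F = 13.5
        res = oneway_anova([1, 2, 3, 4, 5, 6], ["a", "a", "a", "b", "b", "b"])
        assert res.statistic == pytest.approx(13.5)
        assert res.df == (1, 4)
        from scipy import stats as st

        f_ref, p_ref = st.f_oneway([1, 2, 3], [4, 5, 6])
        assert res.statistic == pytest.approx(float(f_ref), abs=1e-12)
        assert res.p == pytest.approx(float(p_ref), abs=1e-12)

    def test_zero_within_variance_warns(self):
        with pytest.warns(UserWarning):
            res = oneway_anova([1, 1, 2, 2], ["a", "a", "b", "b"])
        assert res.p == 0.0

    def test_type_one_error_calibration(self, rng):
        hits = 0
        reps = 1000
        for _ in range(reps):
            y = rng.normal(0, 1, 30)
            if oneway_anova(y, np.repeat(["a", "b", "c"], 10)).p <= 0.05:
                hits += 1
        assert abs(hits / reps - 0.05) < 0.02


class TestLMM:
    def _simulate(self, rng, n_groups=8, n_per=25, var_b=1.0, beta=(1.0, 0.5)):
        groups = np.repeat([f"g{i}" for i in range(n_groups)], n_per)
        x = rng.normal(0, 1, n_groups * n_per)
        u = rng.normal(0, np.sqrt(var_b), n_groups)
        y = beta[0] + beta[1] * x + u[np.repeat(np.arange(n_groups), n_per)] + rng.normal(
            0, 1, n_groups * n_per
        )
        X = np.column_stack([np.ones_like(x), x])
        return y, X, groups

    def test_boundary_reduces_to_ols(self, rng):
        # noise demeaned within groups puts the ML optimum exactly on the
        # var_between = 0 boundary, where the fit must collapse to OLS
        n_groups, n_per = 6, 100
        groups = np.repeat([f"g{i}" for i in range(n_groups)], n_per)
        x = rng.normal(0, 1, n_groups * n_per)
        eps = rng.normal(0, 1, n_groups * n_per)
        for g in range(n_groups):
            sl = slice(g * n_per, (g + 1) * n_per)
            eps[sl] -= eps[sl].mean()
        y = 1.0 + 0.5 * x + eps
        X = np.column_stack([np.ones_like(x), x])
        fit = lmm_random_intercept(y, X, groups)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert fit.var_between <= 1e-6
        assert np.allclose(fit.fixed_effects, ols, atol=1e-6)

    def test_matches_statsmodels_mixedlm(self, rng):
        import statsmodels.api as sm

        y, X, groups = self._simulate(rng)
        fit = lmm_random_intercept(y, X, groups)
        smf = sm.MixedLM(y, X, groups=groups).fit(reml=False)
        assert np.allclose(fit.fixed_effects, smf.fe_params, atol=1e-5)
        assert np.allclose(fit.se, smf.bse_fe, atol=1e-4)
        assert fit.var_resid == pytest.approx(smf.scale, rel=1e-3)
        assert fit.var_between == pytest.approx(float(np.asarray(smf.cov_re)[0, 0]), rel=1e-2, abs=1e-4)

    def test_location_invariance(self, rng):
        y, X, groups = self._simulate(rng)
        f1 = lmm_random_intercept(y, X, groups)
        f2 = lmm_random_intercept(y + 100.0, X, groups)
        assert np.allclose(f1.fixed_effects[1:], f2.fixed_effects[1:], atol=1e-9)
        assert np.allclose(f1.wald_chi2[1:], f2.wald_chi2[1:], atol=1e-6)

    def test_parameter_recovery(self, rng):
        covered = 0
        runs = 200
        for _ in range(runs):
            y, X, groups = self._simulate(rng, n_groups=10, n_per=30)
            fit = lmm_random_intercept(y, X, groups)
            ok = all(
                abs(fit.fixed_effects[j] - (1.0, 0.5)[j]) <= 3 * fit.se[j] for j in (0, 1)
            )
            covered += ok
        assert covered / runs >= 0.95

    def test_loglik_at_least_ols(self, rng):
        from scipy import stats as st

        y, X, groups = self._simulate(rng)
        fit = lmm_random_intercept(y, X, groups)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        resid = y - X @ ols
        s2 = (resid**2).mean()
        ll_ols = st.norm.logpdf(resid, scale=np.sqrt(s2)).sum()
        assert fit.loglik >= ll_ols - 1e-8

    def test_group_relabelling_invariance(self, rng):
        y, X, groups = self._simulate(rng)
        perm = rng.permutation(len(y))
        f1 = lmm_random_intercept(y, X, groups)
        f2 = lmm_random_intercept(y[perm], X[perm], groups[perm])
        assert np.allclose(f1.fixed_effects, f2.fixed_effects, atol=1e-8)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-6)

    def test_singular_design_rejected(self, rng):
        y, X, groups = self._simulate(rng)
        X2 = np.column_stack([X, X[:, 1]])
        with pytest.raises(ValueError, match="collinear"):
            lmm_random_intercept(y, X2, groups)


class TestRunAssociation:
    def test_type_one_error_calibration(self, rng):
        hits = np.zeros(2)
        reps = 500
        pops = np.repeat([f"p{i}" for i in range(6)], 15)
        for _ in range(reps):
            pcs = rng.normal(0, 1, (90, 2))
            y = rng.normal(0, 1, 90)
            res = run_association(y, pcs, pops)
            hits += [res["PC1"].p <= 0.05, res["PC2"].p <= 0.05]
        assert np.all(np.abs(hits / reps - 0.05) < 0.02 + 0.01)

    def test_detects_pc1_effect_only(self, rng):
        pops = np.repeat([f"p{i}" for i in range(8)], 20)
        pcs = rng.normal(0, 1, (160, 2))
        y = 0.8 * pcs[:, 0] + rng.normal(0, 1, 160)
        res = run_association(y, pcs, pops)
        assert res["PC1"].p <= 0.01
        assert res["PC2"].p > 0.01

    def test_exclusion_removes_population(self, rng):
        pops = np.repeat([f"p{i}" for i in range(5)], 10)
        pcs = rng.normal(0, 1, (50, 2))
        y = rng.normal(0, 1, 50)
        res = run_association(y, pcs, pops, exclude=["p0"])
        assert res["PC1"].meta["n_used"] == 40

    def test_too_few_populations_untestable(self, rng):
        pops = np.repeat(["a", "b", "c"], 10)
        pcs = rng.normal(0, 1, (30, 2))
        y = rng.normal(0, 1, 30)
        res = run_association(y, pcs, pops, exclude=["a"])
        assert not res["PC1"].testable
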