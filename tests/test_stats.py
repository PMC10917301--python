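import itertools

import numpy as np
import pandas as pd
import pytest

from emaswb import stats as st


class TestWithinCenter:
    def test_simple(self):
        df = pd.DataFrame({"participant_id": ["a"] * 3, "x": [1.0, 2, 3]})
        out = st.within_center(df, ["x"])
        np.testing.assert_allclose(out.x, [-1, 0, 1])

    def test_constant_person_all_zero(self):
        df = pd.DataFrame({"participant_id": ["a"] * 4, "x": [2.0] * 4})
        out = st.within_center(df, ["x"])
        np.testing.assert_allclose(out.x, 0.0)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"participant_id": np.repeat(list("abc"), 5),
                           "x": rng.standard_normal(15)})
        once = st.within_center(df, ["x"])
        twice = st.within_center(once, ["x"])
        np.testing.assert_allclose(once.x, twice.x, atol=1e-12)

    def test_invariants(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"participant_id": np.repeat(range(20), 7),
                           "x": rng.standard_normal(140)})
        out = st.within_center(df, ["x"])
        sums = out.groupby("participant_id").x.sum()
        assert np.abs(sums).max() < 1e-9
        assert abs(out.x.mean()) < 1e-9

    def test_single_observation_flagged(self):
        df = pd.DataFrame({"participant_id": ["a", "b", "b"],
                           "x": [5.0, 1.0, 3.0]})
        out = st.within_center(df, ["x"])
        assert out.loc[0, "x"] == 0.0
        assert bool(out.loc[0, "_single_obs"])


class TestFixedEffectR:
    def test_perfect(self):
        x = np.array([-1.0, 0, 1, -2, 2])
        assert st.fixed_effect_r(x, x) == pytest.approx(1.0)

    def test_independent_near_zero(self):
        rng = np.random.default_rng(2)
        assert abs(st.fixed_effect_r(rng.standard_normal(100_000),
                                     rng.standard_normal(100_000))) < 0.02

    def test_equals_standardized_pooled_ols_slope(self):
        # the stage-wise fixed effect equals the standardized OLS slope
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"participant_id": np.repeat(range(40), 8),
                           "x": rng.standard_normal(320)})
        df["y"] = 0.4 * df.x + rng.standard_normal(320)
        cent = st.within_center(df, ["x", "y"])
        r = st.fixed_effect_r(cent.x, cent.y)
        zx = (cent.x - cent.x.mean()) / cent.x.std(ddof=1)
        zy = (cent.y - cent.y.mean()) / cent.y.std(ddof=1)
        beta = np.linalg.lstsq(zx.to_numpy()[:, None], zy.to_numpy(),
                               rcond=None)[0][0]
        assert r == pytest.approx(beta, abs=1e-10)

    def test_generator_within_coupling_recovered(self, day_records):
        from emaswb import preprocess as pp
        pairs = pp.lag_tonight(day_records).dropna(
            subset=["momentary_swb", "anscombe_tonight"])
        cent = st.within_center(pairs, ["momentary_swb", "anscombe_tonight"])
        r = st.fixed_effect_r(cent.momentary_swb, cent.anscombe_tonight)
        assert r == pytest.approx(0.07, abs=0.05)  # small cohort


class TestPermutationP:
    def test_identical_series_minimum_p(self):
        # x = y with distinct values: by the rearrangement inequality every
        # non-identity shuffle strictly lowers the statistic
        rng = np.random.default_rng(0)
        x = rng.standard_normal(12)
        g = np.repeat(list("abcd"), 3)
        p = st.permutation_p(x, x, g, n_perm=999, seed=0)
        assert p == pytest.approx(1 / 1000)

    def test_matches_exhaustive_enumeration_on_3x3(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(9)
        y = rng.standard_normal(9)
        g = np.repeat([0, 1, 2], 3)
        # exhaustive: all 6^3 within-person rearrangements of y
        xc = x - np.repeat([x[:3].mean(), x[3:6].mean(), x[6:].mean()], 3)
        yc = y - np.repeat([y[:3].mean(), y[3:6].mean(), y[6:].mean()], 3)
        obs = abs(xc @ yc)
        perms = list(itertools.permutations(range(3)))
        hits = total = 0
        for pa in perms:
            for pb in perms:
                for pc in perms:
                    yp = np.concatenate([yc[:3][list(pa)], yc[3:6][list(pb)],
                                         yc[6:][list(pc)]])
                    total += 1
                    if abs(xc @ yp) >= obs - 1e-12:
                        hits += 1
        exact = hits / total
        approx = st.permutation_p(x, y, g, n_perm=40_000, seed=1)
        assert approx == pytest.approx(exact, abs=0.02)

    def test_invalid_n_perm(self):
        with pytest.raises(ValueError):
            st.permutation_p([1.0, 2], [1.0, 2], ["a", "a"], n_perm=0)


class TestSteiger:
    def test_equal_correlations_give_z_zero(self):
        res = st.steiger_test(0.4, 0.4, 0.3, 200)
        assert res.z == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_headline_language_vs_rating_comparison(self):
        # |r| = .10 vs .37 sharing an outcome, predictor intercorrelation
        # .69, n = 700 -> decisively significant
        res = st.steiger_test(0.10, 0.37, 0.69, 700)
        assert res.p < 0.001

    def test_sign_flips_when_predictors_swap(self):
        a = st.steiger_test(0.1, 0.5, 0.4, 300)
        b = st.steiger_test(0.5, 0.1, 0.4, 300)
        assert a.z == pytest.approx(-b.z, abs=1e-12)

    def test_non_positive_definite_rejected(self):
        with pytest.raises(ValueError):
            st.steiger_test(0.9, -0.9, 0.9, 100)

    def test_null_calibration(self):
        # simulated null: equal population correlations -> rejection ~ alpha
        rng = np.random.default_rng(5)
        n, reps = 150, 2000
        cov = np.array([[1, 0.3, 0.3], [0.3, 1, 0.5], [0.3, 0.5, 1]])
        L = np.linalg.cholesky(cov)
        rej = 0
        for _ in range(reps):
            X = rng.standard_normal((n, 3)) @ L.T
            R = np.corrcoef(X, rowvar=False)
            res = st.steiger_test(R[0, 1], R[0, 2], R[1, 2], n)
            rej += res.p < 0.05
        assert rej / reps == pytest.approx(0.05, abs=0.02)


class TestGroupDeviation:
    def test_group_at_grand_mean(self):
        g = st.group_deviation_test([1.0, -1.0, 0.5, -0.5], 0.0)
        assert g.p == pytest.approx(1.0)

    def test_large_shift_significant(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(50) + 10
        g = st.group_deviation_test(x, 0.0)
        assert g.p < 1e-10
        assert g.se == pytest.approx(x.std(ddof=1) / np.sqrt(50))

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            st.group_deviation_test([1.0], 0.0)


class TestStdMultipleRegression:
    def test_orthogonal_predictors_betas_equal_correlations(self):
        rng = np.random.default_rng(7)
        n = 60_000
        x1 = rng.standard_normal(n)
        x2 = rng.standard_normal(n)
        y = 0.5 * x1 + 0.3 * x2 + rng.standard_normal(n)
        res = st.std_multiple_regression(y, pd.DataFrame({"a": x1, "b": x2}))
        r_a = np.corrcoef(y, x1)[0, 1]
        r_b = np.corrcoef(y, x2)[0, 1]
        assert res["betas"]["a"] == pytest.approx(r_a, abs=0.01)
        assert res["betas"]["b"] == pytest.approx(r_b, abs=0.01)

    def test_closed_form_half_half(self):
        # r_y1 = r_y2 = .5, r_12 = 0 -> betas .5/.5, R^2 = .5
        rng = np.random.default_rng(8)
        n = 200_000
        x1 = rng.standard_normal(n)
        x2 = rng.standard_normal(n)
        e = rng.standard_normal(n)
        y = x1 + x2 + np.sqrt(2) * e     # population r_yj = 1/2
        res = st.std_multiple_regression(y, pd.DataFrame({"a": x1, "b": x2}))
        assert res["betas"]["a"] == pytest.approx(0.5, abs=0.01)
        assert res["r2"] == pytest.approx(0.5, abs=0.01)

    def test_matches_statsmodels_on_standardized_data(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(9)
        n = 400
        X = pd.DataFrame(rng.standard_normal((n, 3)), columns=list("abc"))
        X["b"] += 0.5 * X["a"]
        y = 0.3 * X.a - 0.2 * X.b + 0.1 * X.c + rng.standard_normal(n)
        res = st.std_multiple_regression(y, X)
        Z = (X - X.mean()) / X.std(ddof=1)
        zy = (y - y.mean()) / y.std(ddof=1)
        fit = sm.OLS(zy, sm.add_constant(Z)).fit()
        for c in "abc":
            assert res["betas"][c] == pytest.approx(fit.params[c], abs=1e-8)
            assert res["p_values"][c] == pytest.approx(fit.pvalues[c],
                                                       rel=0.02)

    def test_singular_rejected(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal(100)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(ValueError):
            st.std_multiple_regression(rng.standard_normal(100), X)


class TestBenjaminiHochberg:
    def test_all_below_line_rejected(self):
        flags = st.bh_correct([0.01, 0.02, 0.03, 0.04, 0.05], q=0.05)
        assert flags.all()

    def test_step_up_none_rejected(self):
        flags = st.bh_correct([0.03, 0.04, 0.2, 0.8], q=0.05)
        assert not flags.any()

    def test_all_ones(self):
        assert not st.bh_correct([1.0, 1.0, 1.0]).any()

    def test_monotone_in_p(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            p = rng.random(25)
            flags = st.bh_correct(p)
            if flags.any():
                assert flags[p <= p[flags].max()].all()

    def test_superset_of_bonferroni(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            p = rng.random(40) ** 3
            bh = st.bh_correct(p, q=0.05)
            bonf = p <= 0.05 / p.size
            assert bh[bonf].all()

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(13)
        p = rng.random(60) ** 2
        ours = st.bh_correct(p, q=0.05)
        theirs = multipletests(p, alpha=0.05, method="fdr_bh")[0]
        np.testing.assert_array_equal(ours, theirs)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            st.bh_correct([0.5, 1.5])
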