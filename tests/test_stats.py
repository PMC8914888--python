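"""VOI-level statistics: residualization, ANCOVA, Sidak, correlations, ICC."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dnqsm.stats import (
    ancova,
    cohort_summary,
    icc_two_way_mixed,
    pairwise_posthoc,
    partial_spearman,
    residualize,
    sidak_adjust,
)


class TestResidualize:
    def test_control_residuals_sum_to_zero(self, rng):
        tiv = rng.normal(1550, 140, 40)
        vol = 200 + 0.4 * tiv + rng.normal(0, 30, 40)
        is_control = np.arange(40) < 25
        z, model = residualize(vol, tiv, is_control)
        raw = vol - model.predict(tiv)
        assert abs(raw[is_control].mean()) < 1e-10
        assert model.n_controls == 25

    def test_known_deviation_recovered_in_sd_units(self, rng):
        n = 2000
        tiv = rng.normal(1550, 140, n)
        noise_sd = 40.0
        vol = 100 + 0.4 * tiv + rng.normal(0, noise_sd, n)
        is_control = np.ones(n, bool)
        is_control[0] = False
        vol[0] = 100 + 0.4 * tiv[0] - 2 * noise_sd  # patient 2 sd below v(TIV)
        z, _ = residualize(vol, tiv, is_control)
        assert z[0] == pytest.approx(-2.0, abs=0.2)

    def test_exact_linear_relationship_rejected(self):
        tiv = np.array([1400.0, 1500, 1600, 1700, 1800, 1900])
        vol = 10 + 0.5 * tiv
        with pytest.raises(ValueError, match="standardize"):
            residualize(vol, tiv, np.array([True, True, True, True, False, False]))

    def test_invariant_under_tiv_unit_change(self, rng):
        tiv = rng.normal(1550, 140, 30)
        vol = 200 + 0.4 * tiv + rng.normal(0, 30, 30)
        is_control = np.arange(30) < 20
        z1, _ = residualize(vol, tiv, is_control)
        z2, _ = residualize(vol, tiv * 1000.0, is_control)  # cm^3 -> mm^3
        np.testing.assert_allclose(z1, z2, rtol=1e-9)

    def test_single_group_rejected(self, rng):
        v = rng.normal(size=10)
        with pytest.raises(ValueError, match="both"):
            residualize(v, v, np.ones(10, bool))


class TestAncova:
    def test_reduces_to_t_test_without_covariate(self, rng):
        dep = np.concatenate([rng.normal(0, 1, 14), rng.normal(0.8, 1, 14)])
        group = np.array(["a"] * 14 + ["b"] * 14)
        res = ancova(dep, group)
        t, _ = sps.ttest_ind(dep[:14], dep[14:], equal_var=True)
        assert res["group"]["F"] == pytest.approx(t**2, rel=1e-10)

    def test_partial_eta_squared_matches_hand_computed_ss(self):
        """Six-point worked example: partial eta^2 from an explicit
        projection-based sum-of-squares decomposition."""
        dep = np.array([3.0, 4.0, 5.0, 7.0, 8.0, 10.0])
        group = np.array(["a", "a", "a", "b", "b", "b"])
        age = np.array([40.0, 50.0, 60.0, 45.0, 55.0, 65.0])
        res = ancova(dep, group, age)
        # hand computation: full model vs model without the group column
        x_full = np.column_stack([np.ones(6), group == "b", age])
        x_red = np.column_stack([np.ones(6), age])
        rss = lambda x: np.sum((dep - x @ np.linalg.lstsq(x, dep, rcond=None)[0]) ** 2)
        ss_err = rss(x_full)
        ss_group = rss(x_red) - ss_err
        assert res["group"]["partial_eta_squared"] == pytest.approx(
            ss_group / (ss_group + ss_err), rel=1e-9)
        f_hand = ss_group / (ss_err / 3.0)
        assert res["group"]["F"] == pytest.approx(f_hand, rel=1e-9)

    def test_agrees_with_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        dep = rng.normal(0, 1, 32)
        group = np.array(["a"] * 16 + ["b"] * 16)
        age = rng.uniform(30, 70, 32)
        res = ancova(dep, group, age)
        df = pd.DataFrame({"dep": dep, "group": group, "age": age})
        pg = pingouin.ancova(data=df, dv="dep", between="group", covar="age")
        row = pg[pg.Source == "group"].iloc[0]
        assert res["group"]["F"] == pytest.approx(row.F, rel=1e-6)
        assert res["group"]["p"] == pytest.approx(row["p_unc"], rel=1e-6)
        assert res["group"]["partial_eta_squared"] == pytest.approx(row.np2, rel=1e-6)

    def test_null_rejection_rate_calibrated(self, rng):
        """Type-I error of the group F test near nominal 0.05 under the null."""
        n_sims, hits = 400, 0
        group = np.array(["a"] * 16 + ["b"] * 16)
        for _ in range(n_sims):
            dep = rng.standard_normal(32)
            age = rng.uniform(30, 70, 32)
            if ancova(dep, group, age)["group"]["p"] < 0.05 :
                hits += 1
        assert 0.02 <= hits / n_sims <= 0.09

    def test_collinear_design_rejected(self, rng):
        dep = rng.normal(size=8)
        group = np.array(["a"] * 4 + ["b"] * 4)
        age = np.full(8, 50.0)  # constant age duplicates the intercept
        with pytest.raises(ValueError, match="collinear"):
            ancova(dep, group, age)

    def test_detects_group_shift_with_age_confounder(self, rng):
        age = rng.uniform(30, 70, 32)
        group = np.array(["patient"] * 16 + ["control"] * 16)
        dep = 0.5 * age + np.where(group == "patient", 3.0, 0.0) + rng.normal(0, 1, 32)
        res = ancova(dep, group, age)
        assert res["group"]["p"] < 0.001
        assert res["age"]["p"] < 0.001


class TestSidak:
    def test_single_comparison_unchanged(self):
        assert sidak_adjust([0.05], 1)[0] == pytest.approx(0.05)

    def test_zero_stays_zero(self):
        assert sidak_adjust([0.0], 15)[0] == 0.0

    def test_worked_value(self):
        assert sidak_adjust([0.01], 15)[0] == pytest.approx(1 - 0.99**15, rel=1e-12)
        assert sidak_adjust([0.01], 15)[0] == pytest.approx(0.1399, abs=5e-5)

    def test_monotone_in_p_and_m(self):
        p = np.linspace(0, 1, 11)
        adj = sidak_adjust(p, 15)
        assert np.all(np.diff(adj) >= 0)
        assert np.all(sidak_adjust(p, 20) >= adj - 1e-15)
        assert np.all(adj >= p - 1e-15)

    def test_m_smaller_than_comparisons_rejected(self):
        with pytest.raises(ValueError, match="smaller"):
            sidak_adjust([0.1, 0.2, 0.3], 2)

    def test_properties_hold_for_arbitrary_inputs(self):
        hypothesis = pytest.importorskip("hypothesis")
        from hypothesis import given, settings, strategies as st

        @settings(deadline=None, derandomize=True, max_examples=200)
        @given(p=st.floats(0.0, 1.0), m=st.integers(1, 500))
        def check(p, m):
            adj = float(sidak_adjust([p], m)[0])
            assert 0.0 <= adj <= 1.0
            assert adj >= p - 1e-12            # adjustment never lowers p
            assert adj == pytest.approx(1.0 - (1.0 - p) ** m, abs=1e-12)

        check()


class TestPosthoc:
    def test_pairwise_matrix_properties(self, rng):
        vals = np.concatenate([rng.normal(0, 1, 10), rng.normal(2, 1, 10),
                               rng.normal(4, 1, 10)])
        groups = np.repeat(["a", "b", "c"], 10)
        cov = rng.uniform(30, 70, 30)
        out = pairwise_posthoc(vals, groups, cov)
        p_raw, p_adj = out["p_raw"], out["p_adj"]
        off = ~np.eye(3, dtype=bool)
        assert np.all(p_adj[off] >= p_raw[off] - 1e-15)
        assert np.all((p_adj[off] >= 0) & (p_adj[off] <= 1))
        np.testing.assert_allclose(p_adj, p_adj.T)
        assert out["m"] == 3
        assert out["direction"][2, 0] == 1.0  # c > a


class TestPartialSpearman:
    def test_monotone_association_detected(self, rng):
        x = rng.normal(size=25)
        y = np.exp(x)  # strictly increasing transform
        cov = rng.normal(size=25)
        res = partial_spearman(x, y, cov)
        assert res.r >= 0.95

    def test_null_association_small(self, rng):
        small = 0
        for _ in range(200):
            x, y, c = rng.normal(size=(3, 25))
            if abs(partial_spearman(x, y, c).r) < 0.4:
                small += 1
        # P(|r| < 0.4) is analytically ~0.948 at n=25; allow sampling slack
        assert small / 200 >= 0.90

    def test_constant_covariate_equals_plain_spearman(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        res = partial_spearman(x, y, np.full(20, 7.0))
        rho, _ = sps.spearmanr(x, y)
        assert res.r == pytest.approx(rho, abs=1e-12)

    def test_agrees_with_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x, y, c = rng.normal(size=(3, 30))
        res = partial_spearman(x, y, c)
        df = pd.DataFrame({"x": x, "y": y, "c": c})
        pg = pingouin.partial_corr(df, x="x", y="y", covar="c", method="spearman")
        assert res.r == pytest.approx(pg["r"].iloc[0], abs=1e-9)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            partial_spearman(np.ones(10), np.arange(10.0), np.arange(10.0))

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            partial_spearman(np.arange(4.0), np.arange(4.0), np.arange(4.0))


class TestIcc:
    def test_identical_raters_give_one(self, rng):
        a = rng.normal(size=10)
        res = icc_two_way_mixed(np.column_stack([a, a]))
        assert res.icc == pytest.approx(1.0)

    def test_shuffled_ratings_near_zero_in_expectation(self, rng):
        a = rng.normal(size=30)
        vals = [icc_two_way_mixed(np.column_stack([a, rng.permutation(a)])).icc
                for _ in range(200)]
        assert abs(np.mean(vals)) < 0.1

    def test_worked_table_matches_mean_squares(self):
        """5x2 table: ICC(3,1) from explicitly computed ANOVA mean squares."""
        r = np.array([[9.0, 10.0], [7.0, 8.0], [5.0, 7.0], [8.0, 7.0], [3.0, 4.0]])
        n, k = r.shape
        ms_rows = k * np.sum((r.mean(1) - r.mean()) ** 2) / (n - 1)
        ss_err = (np.sum((r - r.mean()) ** 2)
                  - k * np.sum((r.mean(1) - r.mean()) ** 2)
                  - n * np.sum((r.mean(0) - r.mean()) ** 2))
        ms_err = ss_err / ((n - 1) * (k - 1))
        expected = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)
        assert icc_two_way_mixed(r).icc == pytest.approx(expected, rel=1e-12)

    def test_agrees_with_pingouin_icc3(self, rng):
        pingouin = pytest.importorskip("pingouin")
        vals = rng.normal(size=(12, 3)) + rng.normal(size=(12, 1)) * 2
        res = icc_two_way_mixed(vals)
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(12), 3),
            "rater": np.tile(np.arange(3), 12),
            "score": vals.ravel(),
        })
        pg = pingouin.intraclass_corr(df, targets="subject", raters="rater",
                                      ratings="score")
        icc3 = pg[pg.Type == "ICC(C,1)"]["ICC"].iloc[0]
        assert res.icc == pytest.approx(icc3, abs=1e-9)

    def test_missing_cells_rejected(self):
        r = np.ones((5, 2))
        r[2, 1] = np.nan
        with pytest.raises(ValueError, match="missing"):
            icc_two_way_mixed(r)


class TestCohortSummary:
    def _table(self, shift, rng, n=15):
        return pd.DataFrame({
            "group": ["patient"] * n + ["control"] * n,
            "age_years": np.concatenate([rng.normal(50, 10, n), rng.normal(50, 10, n)]),
            "sara": np.concatenate([rng.normal(14 + shift, 1, n), rng.normal(14, 1, n)]),
        })

    def test_identical_groups_not_significant(self, rng):
        df = self._table(0.0, rng)
        df.loc[15:, "sara"] = df.loc[:14, "sara"].to_numpy()
        df.loc[15:, "age_years"] = df.loc[:14, "age_years"].to_numpy()
        out = cohort_summary(df)
        assert out[out.variable == "sara"].p.iloc[0] == pytest.approx(1.0)

    def test_large_shift_detected(self, rng):
        out = cohort_summary(self._table(5.0, rng))
        assert out[out.variable == "sara"].p.iloc[0] < 0.001

    def test_null_p_uniform(self, rng):
        """Matched draws from one distribution give uniform p-values."""
        ps = [cohort_summary(self._table(0.0, rng)).p.iloc[1] for _ in range(150)]
        assert sps.kstest(ps, "uniform").pvalue > 0.01
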