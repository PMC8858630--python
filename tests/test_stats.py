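import numpy as np
import pandas as pd
import pytest
from scipy import stats as ss

from psnpipe.stats import (bh_adjust, compare_composition_groups,
                           composition_table, fit_lmm, wilcoxon_test)


class TestComposition:
    meta = pd.DataFrame({"sample_id": ["s1"], "patient_id": ["p1"],
                         "clinical_group": ["GG"]})

    def test_fraction_arithmetic(self):
        labels = pd.DataFrame({"sample": ["s1"] * 4,
                               "cell_type": ["T", "T", "T", "B"]})
        comp = composition_table(labels, self.meta, ["T", "B"])
        assert comp.loc["s1", "T"] == pytest.approx(0.75)
        assert comp.loc["s1", "B"] == pytest.approx(0.25)

    def test_rows_sum_to_one_over_denominator(self, small_cohort):
        _, _, truth = small_cohort
        labels = truth.cells[["sample", "cell_type"]]
        meta = (truth.cells[["sample", "patient", "group"]].drop_duplicates()
                .rename(columns={"sample": "sample_id", "patient": "patient_id",
                                 "group": "clinical_group"}))
        types = sorted(truth.cells["cell_type"].unique())
        comp = composition_table(labels, meta, types)
        np.testing.assert_allclose(comp[types].sum(axis=1), 1.0, atol=1e-9)

    def test_types_outside_denominator_excluded(self):
        labels = pd.DataFrame({"sample": ["s1"] * 3,
                               "cell_type": ["T", "B", "epithelial"]})
        comp = composition_table(labels, self.meta, ["T", "B"])
        assert "epithelial" not in comp.columns
        assert comp.loc["s1", "T"] == pytest.approx(0.5)

    def test_planted_group_ordering_recovered(self, small_cohort):
        cfg, _, truth = small_cohort
        labels = truth.cells[["sample", "cell_type"]]
        meta = (truth.cells[["sample", "patient", "group"]].drop_duplicates()
                .rename(columns={"sample": "sample_id", "patient": "patient_id",
                                 "group": "clinical_group"}))
        comp = composition_table(labels, meta, ["T", "B", "NK", "myeloid"])
        by_group = comp.groupby("clinical_group")["myeloid"].mean()
        assert by_group["nLung"] > by_group["GG"] > by_group["solid"]


class TestWilcoxon:
    def test_unpaired_exact_enumeration(self):
        stat, p, method = wilcoxon_test([1, 2], [3, 4])
        assert method == "exact"
        assert p == pytest.approx(1 / 3)

    def test_paired_all_zero_differences(self):
        x = [1.0, 2.0, 3.0]
        stat, p, method = wilcoxon_test(x, x, paired=True)
        assert p == 1.0 and method == "degenerate"

    def test_paired_n5_all_positive(self):
        # all five differences positive and distinct: p = 2 / 2^5
        stat, p, method = wilcoxon_test([5, 6, 7, 8, 9], [4, 4, 4, 4, 4],
                                        paired=True)
        assert method == "exact"
        assert p == pytest.approx(0.0625)

    def test_ties_force_asymptotic(self):
        _, _, method = wilcoxon_test([1, 1, 2], [2, 3, 4])
        assert method == "asymptotic"

    def test_exact_vs_approx_within_band_at_boundary(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(0, 1, 6)
            y = rng.normal(0.5, 1, 6)
            _, p_exact, m = wilcoxon_test(x, y)
            assert m == "exact"
            res = ss.mannwhitneyu(x, y, alternative="two-sided",
                                  method="asymptotic", use_continuity=True)
            assert abs(p_exact - res.pvalue) < 0.02


class TestBH:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_step_up_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.04]),
                                   [0.03, 0.03, 0.04])

    def test_adjusted_at_least_raw_and_capped(self):
        rng = np.random.default_rng(1)
        p = rng.random(50)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= 1.0)

    def test_matches_brute_force_step_up(self):
        def brute(p):
            p = np.asarray(p, float)
            n = len(p)
            order = np.argsort(p)
            adj = np.empty(n)
            running = 1.0
            for rank in range(n, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * n / rank)
                adj[i] = running
            return adj

        rng = np.random.default_rng(2)
        p = rng.random(30)
        np.testing.assert_allclose(bh_adjust(p), brute(p), rtol=1e-12)


def balanced_boundary_data(seed=7, n_pat=10, per=40, delta=1.0):
    """Two-group data with patient effects removed exactly: the REML estimate
    of the patient variance sits at the boundary 0."""
    rng = np.random.default_rng(seed)
    pats = np.repeat([f"p{i}" for i in range(n_pat)], per)
    grp = np.where(np.isin(pats, [f"p{i}" for i in range(n_pat // 2)]),
                   "GG", "solid")
    y = rng.normal(0, 1, n_pat * per)
    for p in np.unique(pats):
        m = pats == p
        y[m] -= y[m].mean()
    return y + delta * (grp == "solid"), grp, pats


class TestLmm:
    def test_boundary_case_matches_t_test(self):
        y, grp, pats = balanced_boundary_data()
        res = fit_lmm(y, grp, pats)[0]
        a, b = y[grp == "solid"], y[grp == "GG"]
        t, p = ss.ttest_ind(a, b)
        est = a.mean() - b.mean()
        assert res.boundary
        assert res.estimate == pytest.approx(est, abs=1e-6)
        assert res.se == pytest.approx(est / t, abs=1e-6)
        assert res.pvalue == pytest.approx(p, abs=1e-6)
        assert abs(res.df - (len(y) - 2)) <= 0.5

    def test_matches_reference_mixed_model_fit(self):
        """Frozen oracle: the identical dataset fitted with lmerTest (R) gives
        estimate 0.43207279, SE 0.3365706, df 8, p 0.2351608, variance
        components 0.2619191 (patient) and 0.8512126 (residual)."""
        rng = np.random.default_rng(7)
        pats = np.repeat([f"p{i}" for i in range(10)], 40)
        grp = np.where(np.isin(pats, [f"p{i}" for i in range(5)]), "GG", "solid")
        y = rng.normal(0, 1, 400) + 0.8 * (grp == "solid") + \
            np.repeat(rng.normal(0, 0.5, 10), 40)
        res = fit_lmm(y, grp, pats)[0]
        assert res.estimate == pytest.approx(0.43207279, abs=1e-5)
        assert res.se == pytest.approx(0.3365706, abs=1e-5)
        assert res.df == pytest.approx(8.0, abs=0.01)
        assert res.pvalue == pytest.approx(0.2351608, abs=1e-5)
        assert res.var_patient == pytest.approx(0.2619191, abs=1e-5)
        assert res.var_residual == pytest.approx(0.8512126, abs=1e-5)

    def test_agrees_with_statsmodels_mixedlm(self):
        import statsmodels.formula.api as smf
        rng = np.random.default_rng(12)
        pats = np.repeat([f"p{i}" for i in range(8)], 30)
        grp = np.where(np.isin(pats, [f"p{i}" for i in range(4)]), "GG", "solid")
        y = rng.normal(0, 1, 240) + 0.5 * (grp == "solid") + \
            np.repeat(rng.normal(0, 0.7, 8), 30)
        df = pd.DataFrame({"y": y, "grp": grp, "pat": pats})
        sm_fit = smf.mixedlm("y ~ grp", df, groups=df["pat"]).fit(reml=True)
        res = fit_lmm(y, grp, pats)[0]
        assert res.estimate == pytest.approx(sm_fit.params["grp[T.solid]"], abs=1e-4)
        assert res.se == pytest.approx(sm_fit.bse["grp[T.solid]"], abs=1e-4)

    def test_reml_objective_no_worse_than_ols(self):
        from psnpipe.stats import _RandomInterceptREML
        rng = np.random.default_rng(3)
        pats = np.repeat([f"p{i}" for i in range(6)], 20)
        grp = np.where(np.isin(pats, ["p0", "p1", "p2"]), "GG", "solid")
        y = rng.normal(0, 1, 120) + np.repeat(rng.normal(0, 1.0, 6), 20)
        X = np.column_stack([np.ones(120), (grp == "solid").astype(float)])
        reml = _RandomInterceptREML(y, X, pats)
        va, ve = reml.fit()
        assert reml.neg2_reml(max(va, 1e-12), ve) <= \
            reml.neg2_reml(1e-12, reml.profile_sigma2(0.0)) + 1e-6

    def test_reference_level_preference(self):
        y, grp, pats = balanced_boundary_data()
        grp = np.where(grp == "GG", "nLung", "solid")
        res = fit_lmm(y, grp, pats)[0]
        assert res.reference == "nLung"
        assert res.contrast == "solid_vs_nLung"

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_lmm([1.0, 2.0], ["a", "a"], ["p1", "p2"])
        with pytest.raises(ValueError):
            fit_lmm([1.0, 2.0], ["a", "b"], ["p1", "p1"])


class TestCompareCompositionGroups:
    def test_paired_matching_by_patient(self):
        comp = pd.DataFrame({
            "T": [0.5, 0.6, 0.55, 0.7, 0.3],
            "B": [0.5, 0.4, 0.45, 0.3, 0.7],
            "patient_id": ["p1", "p1", "p2", "p2", "p3"],
            "clinical_group": ["GG", "solid", "GG", "solid", "GG"],
        }, index=["a", "b", "c", "d", "e"])
        out = compare_composition_groups(comp, "GG", "solid", paired=True)
        assert set(out["cell_type"]) == {"T", "B"}
        assert (out["comparison"] == "GG_vs_solid").all()
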