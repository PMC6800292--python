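"""Statistical layer: Dunnett, Tukey, t-tests, ΔΔCt, fold-change screens."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats as sps

from neurophenotyper.stats import (
    ddct,
    deg_filter_and_venn,
    dunnett_critical,
    dunnett_max_abs_cdf,
    dunnett_test,
    t_tests,
    tukey_hsd,
)


def mc_dunnett_pvalue(t_obs, ns, control_index, df, n_draws, rng):
    """Monte-Carlo null of max|T| for many-to-one comparisons.

    Simulates the sufficient statistics directly: independent group means
    and a pooled chi-square variance, nothing shared with the quadrature
    implementation.
    """
    ns = np.asarray(ns, dtype=float)
    idx = [i for i in range(len(ns)) if i != control_index]
    out = np.empty(n_draws)
    chunk = 200_000
    done = 0
    while done < n_draws:
        m = min(chunk, n_draws - done)
        means = rng.normal(0, 1, size=(m, len(ns))) / np.sqrt(ns)
        s2 = rng.chisquare(df, size=m) / df
        t = (means[:, idx] - means[:, [control_index]]) / np.sqrt(
            s2[:, None] * (1 / ns[idx] + 1 / ns[control_index])
        )
        out[done : done + m] = np.abs(t).max(axis=1)
        done += m
    return (out >= abs(t_obs)).mean()


def mc_tukey_pvalue(q_obs, k, n, df, n_draws, rng):
    """Monte-Carlo null of the studentized range for k equal-size groups."""
    out = np.empty(n_draws)
    chunk = 200_000
    done = 0
    while done < n_draws:
        m = min(chunk, n_draws - done)
        means = rng.normal(0, 1, size=(m, k))
        s = np.sqrt(rng.chisquare(df, size=m) / df)
        out[done : done + m] = (means.max(axis=1) - means.min(axis=1)) / s
        done += m
    return (out >= q_obs).mean()


class TestDunnett:
    def test_two_groups_reduce_to_pooled_t(self, rng):
        a, b = rng.normal(0, 1, 9), rng.normal(0.7, 1, 7)
        p_d = dunnett_test([a, b]).comparisons[0].p_adjusted
        p_t = sps.ttest_ind(a, b, equal_var=True).pvalue
        assert p_d == pytest.approx(p_t, abs=1e-6)

    def test_agrees_with_monte_carlo_oracle(self, rng):
        groups = [rng.normal(0, 1, 6), rng.normal(0.8, 1, 6), rng.normal(0.3, 1, 6)]
        res = dunnett_test(groups)
        ns = [len(g) for g in groups]
        for c in res.comparisons:
            p_mc = mc_dunnett_pvalue(c.statistic, ns, 0, res.df, 200_000, rng)
            assert c.p_adjusted == pytest.approx(p_mc, abs=0.01)

    def test_bounded_by_unadjusted_and_bonferroni(self, rng):
        for _ in range(5):
            k = int(rng.integers(2, 5))
            groups = [rng.normal(rng.normal(0, 0.4), 1, int(rng.integers(4, 9)))
                      for _ in range(k + 1)]
            res = dunnett_test(groups)
            for c in res.comparisons:
                p_raw = 2 * sps.t.sf(abs(c.statistic), res.df)
                assert c.p_adjusted >= p_raw - 1e-9
                assert c.p_adjusted <= min(1.0, k * p_raw) + 1e-9

    def test_unbalanced_matches_reference_implementation(self, rng):
        groups = [rng.normal(0, 1, 12), rng.normal(0.5, 1, 5), rng.normal(-0.4, 1, 8)]
        mine = [c.p_adjusted for c in dunnett_test(groups).comparisons]
        ref = sps.dunnett(*groups[1:], control=groups[0]).pvalue
        np.testing.assert_allclose(mine, ref, atol=5e-4)

    def test_critical_value_calibration(self):
        lam = np.sqrt(np.full(2, 6.0) / 12.0)    # k=2 comparisons, n=6 each
        crit = dunnett_critical(0.05, lam, df=15)
        assert dunnett_max_abs_cdf(crit, lam, 15)[0] == pytest.approx(0.95, abs=1e-6)
        # classical two-sided Dunnett table value for k=2, df=15
        assert crit == pytest.approx(2.44, abs=0.01)

    def test_zero_variance_everywhere_errors(self):
        with pytest.raises(ValueError):
            dunnett_test([np.ones(4), np.ones(4)])


class TestTukey:
    def test_equal_groups_p_near_one(self, rng):
        a = rng.normal(5, 1, 8)
        res = tukey_hsd([a, a + rng.normal(0, 1e-3, 8)])
        assert res.comparisons[0].p_adjusted > 0.9

    def test_two_groups_reduce_to_pooled_t(self, rng):
        a, b = rng.normal(0, 1, 6), rng.normal(1, 1, 10)
        p_q = tukey_hsd([a, b]).comparisons[0].p_adjusted
        p_t = sps.ttest_ind(a, b, equal_var=True).pvalue
        assert p_q == pytest.approx(p_t, abs=1e-6)

    def test_agrees_with_monte_carlo_oracle(self, rng):
        groups = [rng.normal(0, 1, 6), rng.normal(1.0, 1, 6), rng.normal(0.2, 1, 6)]
        res = tukey_hsd(groups)
        for c in res.comparisons:
            p_mc = mc_tukey_pvalue(c.statistic, 3, 6, res.df, 200_000, rng)
            assert c.p_adjusted == pytest.approx(p_mc, abs=0.01)

    def test_agrees_with_reference_implementation(self, rng):
        groups = [rng.normal(0, 1, 7), rng.normal(0.6, 1, 7), rng.normal(-0.2, 1, 7)]
        mine = tukey_hsd(groups).to_frame()["p_adjusted"].to_numpy()
        ref = sps.tukey_hsd(*groups)
        theirs = [ref.pvalue[0, 1], ref.pvalue[0, 2], ref.pvalue[1, 2]]
        np.testing.assert_allclose(np.sort(mine), np.sort(theirs), atol=1e-6)


class TestTTests:
    def test_identical_paired_degenerate(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        with pytest.warns(UserWarning):
            res = t_tests(a, a.copy(), paired=True)
        assert res.comparisons[0].statistic == 0.0
        assert res.comparisons[0].p_adjusted == 1.0

    def test_p_matches_cdf_integration_oracle(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(0.9, 1, 11)
        res = t_tests(a, b)
        t_obs, df = res.comparisons[0].statistic, res.df
        pdf = lambda x: sps.t.pdf(x, df)
        tail, _ = integrate.quad(pdf, abs(t_obs), np.inf)
        assert res.comparisons[0].p_adjusted == pytest.approx(2 * tail, abs=1e-10)

    def test_swap_symmetry(self, rng):
        a, b = rng.normal(0, 1, 6), rng.normal(1, 1, 6)
        r1 = t_tests(a, b).comparisons[0]
        r2 = t_tests(b, a).comparisons[0]
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_adjusted == pytest.approx(r2.p_adjusted)

    def test_paired_length_mismatch(self):
        with pytest.raises(ValueError):
            t_tests(np.ones(3), np.ones(4), paired=True)


class TestDdct:
    @staticmethod
    def table(rows):
        return pd.DataFrame(rows, columns=["sample", "group", "gene", "ct"])

    def test_closed_forms(self):
        # calibrator ddct=0 -> RQ 1; one-cycle lower Ct -> RQ 2
        rows = [
            ("c1", "control", "GAPDH", 18.0), ("c1", "control", "X", 24.0),
            ("c2", "control", "GAPDH", 18.0), ("c2", "control", "X", 24.0),
            ("p1", "case", "GAPDH", 18.0), ("p1", "case", "X", 23.0),
        ]
        res = ddct(self.table(rows), "GAPDH", "control", target_gene="X")
        rq = res.per_sample.set_index("sample")["rq"]
        assert rq["c1"] == pytest.approx(1.0)
        assert rq["p1"] == pytest.approx(2.0)

    def test_geometric_summaries(self):
        # case replicates with RQ = {1, 2, 4}: geometric mean 2, geometric SD 2
        rows = [
            ("cal1", "control", "GAPDH", 18.0), ("cal1", "control", "X", 24.0),
            ("cal2", "control", "GAPDH", 18.0), ("cal2", "control", "X", 24.0),
            ("a", "g", "GAPDH", 18.0), ("a", "g", "X", 24.0 - np.log2(1)),
            ("b", "g", "GAPDH", 18.0), ("b", "g", "X", 24.0 - np.log2(2)),
            ("c", "g", "GAPDH", 18.0), ("c", "g", "X", 24.0 - np.log2(4)),
        ]
        res = ddct(self.table(rows), "GAPDH", "control", target_gene="X")
        row = res.group_summary.set_index("group").loc["g"]
        assert row["geo_mean"] == pytest.approx(2.0, rel=1e-9)
        assert row["geo_sd"] == pytest.approx(2.0, rel=1e-9)

    def test_calibrator_geo_mean_is_one(self, rng):
        rows = []
        for grp, shift in [("control", 0.0), ("case", -1.3)]:
            for i in range(4):
                s = f"{grp}{i}"
                rows += [(s, grp, "GAPDH", 18 + rng.normal(0, 0.2)),
                         (s, grp, "X", 24 + shift + rng.normal(0, 0.2))]
        res = ddct(self.table(rows), "GAPDH", "control", target_gene="X")
        summary = res.group_summary.set_index("group")
        assert summary.loc["control", "geo_mean"] == pytest.approx(1.0, rel=1e-9)
        assert summary.loc["case", "geo_mean"] > 1.0

    def test_global_ct_shift_invariance(self, rng):
        rows = [("s%d" % i, "g" if i < 3 else "h", g, 18.0 + rng.normal(0, 1))
                for i in range(6) for g in ("GAPDH", "X")]
        tbl = self.table([(s, grp, g, c) for (s, grp, g, c) in rows])
        res1 = ddct(tbl, "GAPDH", "g", target_gene="X")
        tbl2 = tbl.copy()
        tbl2["ct"] += 3.7                  # instrument offset on every well
        res2 = ddct(tbl2, "GAPDH", "g", target_gene="X")
        np.testing.assert_allclose(
            res1.per_sample["rq"], res2.per_sample["rq"], rtol=1e-9
        )

    def test_below_detection_sample_removed(self):
        rows = [
            ("c1", "control", "GAPDH", 18.0), ("c1", "control", "X", 24.0),
            ("c2", "control", "GAPDH", 18.0), ("c2", "control", "X", np.nan),
        ]
        with pytest.warns(UserWarning):
            res = ddct(self.table(rows), "GAPDH", "control", target_gene="X")
        assert res.excluded_samples == ["c2"]
        assert list(res.per_sample["sample"]) == ["c1"]


class TestDegFilter:
    def _matrix(self, folds_by_gene, n_rep=3):
        genes = list(folds_by_gene)
        cols, data = [], {}
        groups = {}
        for g in ("control", "case"):
            for r in range(n_rep):
                s = f"{g}{r}"
                cols.append(s)
                groups[s] = g
                data[s] = [
                    100.0 * (folds_by_gene[gene] if g == "case" else 1.0)
                    for gene in genes
                ]
        return pd.DataFrame(data, index=genes), pd.Series(groups)

    def test_identical_means_no_degs(self):
        mat, groups = self._matrix({"g1": 1.0, "g2": 1.0})
        res = deg_filter_and_venn(mat, groups, [("case", "control")])
        assert res.counts()["case_vs_control"] == 0

    def test_exact_twofold_excluded_strict(self):
        mat, groups = self._matrix({"g1": 2.0, "g2": 2.0001, "g3": 0.5, "g4": 0.4999})
        res = deg_filter_and_venn(mat, groups, [("case", "control")])
        assert res.genes("case_vs_control") == {"g2", "g4"}

    def test_planted_intersection_count(self):
        rng = np.random.default_rng(0)
        from neurophenotyper.synth import generate_expression_matrix

        both = {f"G{i:05d}": 3.0 for i in range(30)}
        only_bp = {f"G{i:05d}": 3.0 for i in range(30, 50)}
        mat, groups, _ = generate_expression_matrix(
            n_genes=200,
            groups={"control": 3, "BP": 3, "SCZ": 3},
            planted={"BP": {**both, **only_bp}, "SCZ": both},
            cv=0.02,
            seed=1,
        )
        res = deg_filter_and_venn(
            mat, groups, [("BP", "control"), ("SCZ", "control")]
        )
        assert len(res.intersection()) == 30
        assert res.counts()["BP_vs_control"] == 50

    def test_mismatched_samples_error(self):
        mat, groups = self._matrix({"g1": 1.0})
        groups.loc["extra"] = "case"
        with pytest.raises(ValueError):
            deg_filter_and_venn(mat, groups, [("case", "control")])
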