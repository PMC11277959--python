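"""Statistics ladder: gate, omnibus tests, corrections, two-way layout.

Oracle strategy: closed-form sums-of-squares / rank formulas computed
inline for small fixtures, plus an independent R (stats package)
cross-check of Shapiro-Wilk, one-way ANOVA and Kruskal-Wallis on random
fixtures.
"""

import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vesquant import groupstats
from vesquant.groupstats import (compare_oneway, compare_twoway, dunn_test,
                                 holm_sidak_adjust, normality_gate,
                                 oneway_ladder, run_cohort_analysis)

R_ORACLE = r"""
library(jsonlite)
fx <- fromJSON(commandArgs(trailingOnly = TRUE)[1], simplifyVector = FALSE)
out <- list()
for (i in seq_along(fx)) {
  gs <- lapply(fx[[i]], unlist)
  sw <- sapply(gs, function(v) shapiro.test(v)$p.value)
  vals <- unlist(gs); grp <- factor(rep(seq_along(gs), sapply(gs, length)))
  av <- anova(lm(vals ~ grp))
  kw <- kruskal.test(gs)
  out[[i]] <- list(shapiro_p = sw, anova_F = av$`F value`[1],
                   anova_p = av$`Pr(>F)`[1],
                   kw_H = unname(kw$statistic), kw_p = kw$p.value)
}
cat(toJSON(out, digits = I(15), auto_unbox = TRUE))
"""


class TestNormalityGate:
    def test_gaussian_groups_pass(self):
        rng = np.random.default_rng(12)
        groups = {f"g{i}": rng.normal(0, 1, 20) for i in range(3)}
        parametric, pvals = normality_gate(groups)
        assert parametric and all(p >= 0.05 for p in pvals.values())

    def test_heavy_tail_fails(self):
        rng = np.random.default_rng(1)
        groups = {"normal": rng.normal(0, 1, 20),
                  "lognormal": rng.lognormal(0, 1.5, 20)}
        parametric, pvals = normality_gate(groups)
        assert not parametric and pvals["lognormal"] < 0.05

    def test_constant_group_degenerate(self):
        with pytest.warns(UserWarning, match="constant"):
            parametric, pvals = normality_gate(
                {"c": np.full(10, 3.0), "n": np.random.default_rng(0).normal(size=10)})
        assert not parametric and pvals["c"] == 0.0

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="tiny"):
            normality_gate({"tiny": np.array([1.0, 2.0]),
                            "ok": np.arange(5.0)})


class TestOnewayLadder:
    def test_identical_values_degenerate(self):
        groups = {k: np.full(5, 7.0) for k in "abc"}
        rep = oneway_ladder(groups)
        assert rep.statistic == 0.0 and rep.pvalue == 1.0
        assert rep.significant_pairs() == []

    def test_anova_against_closed_form(self):
        # hand-computable fixture: groups {1,2,3,4}, {2,3,4,5}, {20,21,22,23}
        g = {"a": np.array([1., 2, 3, 4]), "b": np.array([2., 3, 4, 5]),
             "c": np.array([20., 21, 22, 23])}
        allv = np.concatenate(list(g.values()))
        grand = allv.mean()
        ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in g.values())
        ss_within = sum(((v - v.mean()) ** 2).sum() for v in g.values())
        f_oracle = (ss_between / 2) / (ss_within / 9)
        rep = oneway_ladder(g)
        assert rep.test_used == "oneway_anova_holm_sidak"
        assert rep.statistic == pytest.approx(f_oracle, rel=1e-12)
        # only pairs against the far group are significant
        sig = set(map(frozenset, rep.significant_pairs()))
        assert sig == {frozenset({"a", "c"}), frozenset({"b", "c"})}

    def test_kruskal_tie_corrected_closed_form(self):
        # heavy ties; H = (12/(N(N+1)) * sum n_i rbar_i^2 - 3(N+1)) / C
        g = {"a": np.array([1., 1, 2]), "b": np.array([2., 2, 3]),
             "c": np.array([3., 3, 1])}
        allv = np.concatenate(list(g.values()))
        from scipy.stats import rankdata
        ranks = rankdata(allv)
        n = len(allv)
        start, h = 0, 0.0
        for v in g.values():
            r = ranks[start:start + len(v)]
            h += len(v) * (r.mean() - (n + 1) / 2) ** 2
            start += len(v)
        h *= 12 / (n * (n + 1))
        _, counts = np.unique(allv, return_counts=True)
        h /= 1 - ((counts ** 3 - counts).sum() / (n ** 3 - n))
        rep = oneway_ladder(g)
        assert rep.test_used == "kruskal_wallis_dunn"
        assert rep.statistic == pytest.approx(h, rel=1e-12)

    def test_r_oracle_equivalence(self, tmp_path):
        """Shapiro-Wilk, one-way ANOVA and Kruskal-Wallis agree with R's
        stats package to <= 1e-6 relative on 50 random fixtures."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable; oracle equivalence cannot run")
        rng = np.random.default_rng(2024)
        fixtures = []
        for _ in range(50):
            k = int(rng.integers(2, 5))
            groups = []
            for _ in range(k):
                n = int(rng.integers(5, 25))
                kind = rng.integers(3)
                if kind == 0:
                    v = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 2), n)
                elif kind == 1:
                    v = rng.lognormal(0, rng.uniform(0.3, 1), n)
                else:
                    v = rng.uniform(-5, 5, n)
                groups.append(np.round(v, 6).tolist())
            fixtures.append(groups)
        fx = tmp_path / "fixtures.json"
        fx.write_text(json.dumps(fixtures))
        rfile = tmp_path / "oracle.R"
        rfile.write_text(R_ORACLE)
        res = subprocess.run(["Rscript", str(rfile), str(fx)],
                             capture_output=True, text=True, check=True)
        refs = json.loads(res.stdout)
        from scipy import stats
        for groups, ref in zip(fixtures, refs):
            arrays = [np.array(g) for g in groups]
            for v, sw_ref in zip(arrays, np.atleast_1d(ref["shapiro_p"])):
                assert stats.shapiro(v).pvalue == pytest.approx(sw_ref, rel=1e-6)
            f, p = stats.f_oneway(*arrays)
            assert f == pytest.approx(ref["anova_F"], rel=1e-6)
            assert p == pytest.approx(ref["anova_p"], rel=1e-6)
            h, hp = stats.kruskal(*arrays)
            assert h == pytest.approx(ref["kw_H"], rel=1e-6)
            assert hp == pytest.approx(ref["kw_p"], rel=1e-6)


class TestCorrections:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=12))
    def test_holm_sidak_dominates_raw(self, pvals):
        p = np.array(pvals)
        adj = holm_sidak_adjust(p)
        assert np.all(adj >= p - 1e-12)
        assert np.all((0 <= adj) & (adj <= 1))

    def test_holm_sidak_monotone_in_rank(self):
        p = np.array([0.001, 0.02, 0.5, 0.04])
        adj = holm_sidak_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_dunn_corrected_at_least_raw(self):
        rng = np.random.default_rng(5)
        groups = {k: rng.normal(i, 1, 12) for i, k in enumerate("abcd")}
        for family in ("holm", "bonferroni"):
            for pr in dunn_test(groups, family):
                assert pr.corrected_p >= pr.raw_p - 1e-12


class TestTwoWay:
    def _table(self, effect=0.0, interaction=0.0, seed=0, n=10):
        rng = np.random.default_rng(seed)
        rows = []
        for scope in ("large", "medium"):
            for grp in ("control", "case"):
                shift = effect * (grp == "case") + \
                    interaction * (grp == "case") * (scope == "medium")
                for i in range(n):
                    rows.append({"eye_id": f"{scope}{grp}{i}",
                                 "subject_id": f"s{i}", "group": grp,
                                 "metric": "Tv", "scope": scope,
                                 "value": 1.0 + shift + rng.normal(0, 0.05)})
        return pd.DataFrame(rows)

    def test_null_fixture_no_significant_pairs(self):
        rep = compare_twoway(self._table(effect=0.0, seed=3), "Tv")
        assert rep.test_used == "twoway_anova_tukey"
        assert rep.significant_pairs() == []

    def test_additive_shift_detected_without_interaction(self):
        rep = compare_twoway(self._table(effect=0.5, seed=4), "Tv")
        assert rep.effects["group"] < 0.05
        assert rep.effects["interaction"] > 0.05
        assert len(rep.significant_pairs()) == 2  # both generation levels

    def test_single_level_factor_falls_back(self):
        tab = self._table(effect=0.5, seed=5)
        tab = tab[tab.scope == "large"]
        with pytest.warns(UserWarning, match="single-level"):
            rep = compare_twoway(tab, "Tv")
        assert rep.test_used in ("oneway_anova_holm_sidak",
                                 "kruskal_wallis_dunn")


class TestRunCohortAnalysis:
    def test_reports_per_metric_scope(self):
        rng = np.random.default_rng(8)
        rows = []
        for grp, mu in (("control", 1.0), ("DM_DR", 1.2)):
            for i in range(10):
                for metric in ("Tv", "Lv"):
                    for scope in ("total", "large"):
                        rows.append({"eye_id": f"{grp}{i}", "subject_id": f"{grp}{i}",
                                     "group": grp, "metric": metric,
                                     "scope": scope,
                                     "value": mu + rng.normal(0, 0.05)})
        reports, summary = run_cohort_analysis(pd.DataFrame(rows))
        oneway = [r for r in reports if r.scope != "twoway"]
        assert {(r.metric, r.scope) for r in oneway} == \
            {("Tv", "total"), ("Tv", "large"), ("Lv", "total"), ("Lv", "large")}
        assert not summary.empty

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            run_cohort_analysis(pd.DataFrame({"eye_id": [], "value": []}))

    def test_all_nan_metric_skipped(self):
        rng = np.random.default_rng(0)
        rows = [{"eye_id": f"e{i}{g}", "subject_id": f"e{i}", "group": g,
                 "metric": "Tv", "scope": "total", "value": rng.normal()}
                for g in ("a", "b") for i in range(5)]
        rows += [{"eye_id": f"x{i}{g}", "subject_id": f"x{i}", "group": g,
                  "metric": "Av", "scope": "micro", "value": float("nan")}
                 for g in ("a", "b") for i in range(5)]
        reports, _ = run_cohort_analysis(pd.DataFrame(rows))
        assert {(r.metric, r.scope) for r in reports if r.scope != "twoway"} \
            == {("Tv", "total")}

    def test_label_permutation_keeps_null_rate(self):
        """Permuting group labels of a null cohort leaves the rejection
        rate statistically unchanged."""
        rng = np.random.default_rng(77)
        base_rate, perm_rate = 0, 0
        n_rep = 300
        for _ in range(n_rep):
            vals = rng.normal(0, 1, 30)
            labels = np.repeat(["a", "b"], 15)
            rep1 = oneway_ladder({"a": vals[:15], "b": vals[15:]})
            perm = rng.permutation(labels)
            rep2 = oneway_ladder({"a": vals[perm == "a"], "b": vals[perm == "b"]})
            base_rate += rep1.pvalue < 0.05
            perm_rate += rep2.pvalue < 0.05
        assert abs(base_rate - perm_rate) / n_rep < 0.05
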