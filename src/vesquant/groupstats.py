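"""Cohort-comparison statistics for morphometry tables.

The analysis ladder mirrors common ophthalmology practice: per metric, a
Shapiro-Wilk normality gate across all groups decides between

* ordinary one-way ANOVA with Holm-Sidak all-pairs comparisons
  (every group normal at alpha = 0.05), or
* Kruskal-Wallis with Dunn all-pairs comparisons (any group non-normal).

Two-way layouts (generation group x cohort group) use ordinary two-way
ANOVA with Type II sums of squares and Tukey HSD pairwise comparisons
within each generation level using the single pooled error variance.

Eyes are the analysis unit; outliers are never removed.  Significance is
assessed at alpha = 0.05 on corrected p-values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "StatsReport",
    "PairwiseResult",
    "normality_gate",
    "oneway_ladder",
    "compare_oneway",
    "compare_twoway",
    "run_cohort_analysis",
    "holm_sidak_adjust",
    "dunn_test",
]

ALPHA = 0.05


@dataclass
class PairwiseResult:
    pair: tuple[str, str]
    raw_p: float
    corrected_p: float
    significant: bool
    statistic: float = float("nan")
    level: str | None = None    # generation level for two-way layouts


@dataclass
class StatsReport:
    metric: str
    scope: str
    test_used: str
    statistic: float
    pvalue: float
    pairwise: list[PairwiseResult] = field(default_factory=list)
    normality_p: dict[str, float] = field(default_factory=dict)
    alpha: float = ALPHA
    effects: dict[str, float] = field(default_factory=dict)  # two-way p-values

    def significant_pairs(self) -> list[tuple[str, str]]:
        return [p.pair for p in self.pairwise if p.significant]

    def to_rows(self) -> list[dict]:
        rows = []
        for p in self.pairwise:
            rows.append({
                "metric": self.metric, "scope": self.scope,
                "test": self.test_used, "omnibus_stat": self.statistic,
                "omnibus_p": self.pvalue,
                "pair": " vs ".join(p.pair), "level": p.level,
                "raw_p": p.raw_p, "corrected_p": p.corrected_p,
                "significant": p.significant,
            })
        if not rows:
            rows.append({"metric": self.metric, "scope": self.scope,
                         "test": self.test_used,
                         "omnibus_stat": self.statistic,
                         "omnibus_p": self.pvalue, "pair": None,
                         "level": None, "raw_p": None, "corrected_p": None,
                         "significant": self.pvalue < self.alpha})
        return rows


# ---------------------------------------------------------------------------
# normality gate


def normality_gate(groups: dict[str, np.ndarray], alpha: float = ALPHA
                   ) -> tuple[bool, dict[str, float]]:
    """Shapiro-Wilk per group; the whole metric goes parametric only when
    every group is compatible with normality (p >= alpha).

    Zero-variance groups are degenerate and treated as non-normal with a
    warning.  Raises for any group with n < 3.
    """
    pvals: dict[str, float] = {}
    for label, vals in groups.items():
        vals = np.asarray(vals, dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) < 3:
            raise ValueError(
                f"group '{label}' has n={len(vals)} < 3; Shapiro-Wilk needs >= 3")
        if np.ptp(vals) == 0:
            warnings.warn(f"group '{label}' is constant; treated as "
                          "non-normal", stacklevel=2)
            pvals[label] = 0.0
            continue
        pvals[label] = float(stats.shapiro(vals).pvalue)
    parametric = all(p >= alpha for p in pvals.values())
    return parametric, pvals


# ---------------------------------------------------------------------------
# corrections and post hocs


def holm_sidak_adjust(pvals: np.ndarray) -> np.ndarray:
    """Holm-Sidak step-down adjusted p-values (monotone, in [0, 1])."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        val = 1.0 - (1.0 - p[idx]) ** (m - rank)
        running = max(running, val)
        adj[idx] = min(1.0, running)
    return adj


def _holm_adjust(pvals: np.ndarray) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def _pairwise_t_pooled(groups: dict[str, np.ndarray]) -> list[tuple[tuple[str, str], float, float]]:
    """All-pairs t statistics sharing the one-way ANOVA pooled variance."""
    labels = list(groups)
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    n_tot = sum(len(v) for v in arrays.values())
    k = len(labels)
    df = n_tot - k
    sse = sum(((v - v.mean()) ** 2).sum() for v in arrays.values())
    mse = sse / df if df > 0 else float("nan")
    out = []
    for a, b in combinations(labels, 2):
        va, vb = arrays[a], arrays[b]
        se = np.sqrt(mse * (1 / len(va) + 1 / len(vb)))
        if se == 0:
            t, p = 0.0, 1.0
        else:
            t = (va.mean() - vb.mean()) / se
            p = 2 * stats.t.sf(abs(t), df)
        out.append(((a, b), float(t), float(p)))
    return out


def dunn_test(groups: dict[str, np.ndarray], correction: str = "holm"
              ) -> list[PairwiseResult]:
    """Dunn's all-pairs rank comparison after Kruskal-Wallis.

    Mean-rank z statistics with the tie correction
    ``(N(N+1)/12 - sum(t^3 - t)/(12(N-1)))``; family-wise correction is
    Holm by default, switchable to ``"bonferroni"`` or ``"none"``.
    """
    labels = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    alldata = np.concatenate(arrays)
    n = len(alldata)
    ranks = stats.rankdata(alldata)
    _, counts = np.unique(alldata, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / (12 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term
    mean_ranks, sizes = {}, {}
    start = 0
    for k, v in zip(labels, arrays):
        mean_ranks[k] = ranks[start:start + len(v)].mean()
        sizes[k] = len(v)
        start += len(v)
    zs, raws, pairs = [], [], []
    for a, b in combinations(labels, 2):
        se = np.sqrt(var_base * (1 / sizes[a] + 1 / sizes[b]))
        z = 0.0 if se == 0 else (mean_ranks[a] - mean_ranks[b]) / se
        p = 2 * stats.norm.sf(abs(z))
        pairs.append((a, b))
        zs.append(float(z))
        raws.append(float(p))
    raws = np.array(raws)
    if correction == "holm":
        adj = _holm_adjust(raws)
    elif correction == "bonferroni":
        adj = np.minimum(1.0, raws * len(raws))
    elif correction == "none":
        adj = raws
    else:
        raise ValueError(f"unknown Dunn correction '{correction}'")
    return [PairwiseResult(pair, float(r), float(c), bool(c < ALPHA), z)
            for pair, r, c, z in zip(pairs, raws, adj, zs)]


# ---------------------------------------------------------------------------
# one-way ladder


def oneway_ladder(groups: dict[str, np.ndarray], alpha: float = ALPHA,
                  dunn_correction: str = "holm",
                  metric: str = "", scope: str = "total") -> StatsReport:
    """Normality gate, then one-way ANOVA + Holm-Sidak or Kruskal-Wallis +
    Dunn, on raw value arrays (the fast path used by simulations)."""
    clean = {k: np.asarray(v, dtype=float)[np.isfinite(np.asarray(v, dtype=float))]
             for k, v in groups.items()}
    if len(clean) < 2:
        raise ValueError("need >= 2 groups")
    arrays = list(clean.values())
    if np.ptp(np.concatenate(arrays)) == 0:
        # all values identical across every group: F = H = 0, p = 1
        report = StatsReport(metric, scope, "degenerate_identical", 0.0, 1.0)
        report.pairwise = [PairwiseResult((a, b), 1.0, 1.0, False)
                           for a, b in combinations(clean, 2)]
        return report
    parametric, norm_p = normality_gate(clean, alpha)
    if parametric:
        f, p = stats.f_oneway(*arrays)
        pt = _pairwise_t_pooled(clean)
        adj = holm_sidak_adjust(np.array([x[2] for x in pt]))
        pairwise = [PairwiseResult(pair, raw, float(c), bool(c < alpha), t)
                    for (pair, t, raw), c in zip(pt, adj)]
        report = StatsReport(metric, scope, "oneway_anova_holm_sidak",
                             float(f), float(p), pairwise, norm_p, alpha)
    else:
        h, p = stats.kruskal(*arrays)
        pairwise = dunn_test(clean, dunn_correction)
        report = StatsReport(metric, scope, "kruskal_wallis_dunn",
                             float(h), float(p), pairwise, norm_p, alpha)
    return report


def _table_groups(table: pd.DataFrame, metric: str, scope: str
                  ) -> dict[str, np.ndarray]:
    sub = table[(table.metric == metric) & (table.scope == scope)]
    groups = {}
    for label, chunk in sub.groupby("group", sort=True):
        vals = chunk.value.to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) < 3:
            warnings.warn(f"group '{label}' has < 3 finite values for "
                          f"{metric}/{scope}; skipped", stacklevel=2)
            continue
        groups[label] = vals
    return groups


def compare_oneway(table: pd.DataFrame, metric: str, scope: str = "total",
                   alpha: float = ALPHA,
                   dunn_correction: str = "holm") -> StatsReport:
    """One-way ladder on a tidy cohort table
    (eye_id, subject_id, group, metric, scope, value)."""
    groups = _table_groups(table, metric, scope)
    if len(groups) < 2:
        raise ValueError(f"metric {metric}/{scope}: fewer than 2 usable groups")
    return oneway_ladder(groups, alpha, dunn_correction, metric, scope)


# ---------------------------------------------------------------------------
# two-way layout


def compare_twoway(table: pd.DataFrame, metric: str,
                   factors: tuple[str, str] = ("scope", "group"),
                   alpha: float = ALPHA) -> StatsReport:
    """Two-way ANOVA (Type II) over e.g. generation group x cohort group,
    with Tukey HSD pairwise comparisons of cohort groups within each
    generation level using the single pooled error variance.

    A factor with a single observed level degrades to the one-way ladder
    with a warning.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    fa, fb = factors
    sub = table[table.metric == metric].dropna(subset=["value"]).copy()
    sub = sub[np.isfinite(sub.value)]
    if fa == "scope":
        sub = sub[sub.scope != "total"]
    if sub[fa].nunique() < 2 or sub[fb].nunique() < 2:
        warnings.warn(f"two-way layout for {metric} has a single-level "
                      "factor; falling back to one-way", stacklevel=2)
        level = sub[fa].unique()[0] if sub[fa].nunique() == 1 else "total"
        return compare_oneway(table, metric,
                              scope=level if fa == "scope" else "total",
                              alpha=alpha)
    data = sub.rename(columns={fa: "A", fb: "B"})[["A", "B", "value"]]
    model = smf.ols("value ~ C(A) * C(B)", data=data).fit()
    try:
        anova = sm.stats.anova_lm(model, typ=2)
    except ValueError:
        # unbalanced layouts with empty cells: drop the interaction
        model = smf.ols("value ~ C(A) + C(B)", data=data).fit()
        anova = sm.stats.anova_lm(model, typ=2)
    effects = {}
    for name, row in anova.iterrows():
        key = {"C(A)": fa, "C(B)": fb, "C(A):C(B)": "interaction"}.get(
            name.strip(), name.strip())
        if key != "Residual":
            effects[key] = float(row["PR(>F)"])
    mse = float(anova.loc["Residual", "sum_sq"] / anova.loc["Residual", "df"])
    df_err = float(anova.loc["Residual", "df"])

    # Tukey HSD within each level of factor A, pooled variance from the model
    pairwise: list[PairwiseResult] = []
    k = data["B"].nunique()
    for level, chunk in data.groupby("A", sort=True):
        cells = {b: v.value.to_numpy(dtype=float)
                 for b, v in chunk.groupby("B", sort=True) if len(v) >= 2}
        for a, b in combinations(sorted(cells), 2):
            va, vb = cells[a], cells[b]
            se = np.sqrt(mse / 2 * (1 / len(va) + 1 / len(vb)))
            q = abs(va.mean() - vb.mean()) / se if se > 0 else 0.0
            p = float(stats.studentized_range.sf(q, k, df_err)) if se > 0 else 1.0
            pairwise.append(PairwiseResult((a, b), p, p, bool(p < alpha),
                                           float(q), level=str(level)))

    fstat = float(model.fvalue)
    fp = float(model.f_pvalue)
    omnibus = effects.get(fb, fp)
    report = StatsReport(metric, "twoway", "twoway_anova_tukey", fstat,
                         omnibus, pairwise, {}, alpha, effects)
    return report


# ---------------------------------------------------------------------------
# whole-cohort driver


def run_cohort_analysis(table: pd.DataFrame, alpha: float = ALPHA,
                        dunn_correction: str = "holm",
                        twoway_metrics: tuple[str, ...] = ("Tv",)
                        ) -> tuple[list[StatsReport], pd.DataFrame]:
    """One report per metric x scope plus two-way generation x cohort
    layouts; outliers are never removed.  Returns (reports, summary frame).
    """
    required = {"eye_id", "group", "metric", "scope", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    reports: list[StatsReport] = []
    for (metric, scope), chunk in table.groupby(["metric", "scope"], sort=True):
        if not np.isfinite(chunk.value.to_numpy(dtype=float)).any():
            logger.info("metric %s/%s has no finite values; skipped",
                        metric, scope)
            continue
        try:
            reports.append(compare_oneway(table, metric, scope, alpha,
                                          dunn_correction))
        except ValueError as exc:
            logger.info("metric %s/%s skipped: %s", metric, scope, exc)
    for metric in twoway_metrics:
        sub = table[(table.metric == metric) & (table.scope != "total")]
        if sub.dropna(subset=["value"]).scope.nunique() >= 2:
            reports.append(compare_twoway(table, metric, alpha=alpha))
    summary = pd.DataFrame([row for r in reports for row in r.to_rows()])
    return reports, summary


def report_markdown(reports: list[StatsReport]) -> str:
    """Human-readable markdown digest of a cohort analysis."""
    lines = ["# Cohort comparison report", ""]
    for r in reports:
        lines.append(f"## {r.metric} ({r.scope})")
        lines.append(f"- test: {r.test_used}; omnibus statistic "
                     f"{r.statistic:.4g}, p = {r.pvalue:.4g}")
        if r.effects:
            eff = ", ".join(f"{k}: p={v:.4g}" for k, v in r.effects.items())
            lines.append(f"- effects: {eff}")
        for p in r.pairwise:
            star = " *" if p.significant else ""
            lvl = f" [{p.level}]" if p.level else ""
            lines.append(f"- {p.pair[0]} vs {p.pair[1]}{lvl}: corrected "
                         f"p = {p.corrected_p:.4g}{star}")
        lines.append("")
    return "\n".join(lines)
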