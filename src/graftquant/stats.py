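"""Association statistics: group comparisons, lesion-score associations,
tertile grouping, hierarchical clustering and correlation matrices.

Conventions
-----------
* Contingency tests are Pearson chi-square without continuity correction;
  rows/columns with zero margin are dropped (with a warning) before testing.
* Rank tests use midranks for ties. The two-sample Wilcoxon rank-sum test is
  exact (full null enumeration) for combined n <= 12 without ties and a
  normal approximation with tie correction otherwise.
* Post-hoc p-values are reported raw; Holm adjustment is available behind a
  flag because the study design reports unadjusted pairwise tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy

__all__ = [
    "ContingencyTable",
    "TestResult",
    "ClusteringResult",
    "chi_square_test",
    "one_way_anova",
    "kruskal_wallis",
    "wilcoxon_rank_sum",
    "group_compare_ddcfdna",
    "lesion_score_association",
    "tertile_split",
    "cluster_heatmap",
    "correlation_matrix",
]


@dataclass
class ContingencyTable:
    row_labels: list
    col_labels: list
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    def drop_zero_margins(self) -> "ContingencyTable":
        rows = self.counts.sum(axis=1) > 0
        cols = self.counts.sum(axis=0) > 0
        if not rows.all() or not cols.all():
            warnings.warn("dropping zero-margin rows/columns before testing")
        return ContingencyTable(
            [l for l, k in zip(self.row_labels, rows) if k],
            [l for l, k in zip(self.col_labels, cols) if k],
            self.counts[np.ix_(rows, cols)],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_labels, columns=self.col_labels)


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    df: Optional[float] = None
    group_sizes: tuple = ()

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


@dataclass
class ClusteringResult:
    linkage: np.ndarray          # scipy condensed linkage matrix (average)
    row_order: np.ndarray        # leaf order from dendrogram traversal
    standardized: pd.DataFrame   # z-scored matrix actually clustered
    dropped_columns: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Elementary tests

def chi_square_test(table: ContingencyTable) -> TestResult:
    """Pearson chi-square test of independence (no continuity correction)."""
    reduced = table.drop_zero_margins()
    r, c = reduced.counts.shape
    if r < 2 or c < 2:
        raise ValueError("contingency table degenerate after dropping zero margins")
    res = sps.chi2_contingency(reduced.counts, correction=False)
    return TestResult(
        statistic=float(res.statistic), p_value=float(res.pvalue),
        method="pearson-chi-square", df=float((r - 1) * (c - 1)),
        group_sizes=tuple(reduced.counts.sum(axis=0)),
    )


def one_way_anova(groups: Sequence[np.ndarray]) -> TestResult:
    """Classical one-way fixed-effects F test.

    When every group is constant and all means coincide (zero between- and
    within-group variance) the statistic is reported as 0 with p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("one_way_anova needs >= 2 groups with >= 2 values each")
    grand = np.concatenate(groups)
    ss_between = sum(len(g) * (g.mean() - grand.mean()) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ss_within == 0.0 and ss_between == 0.0:
        warnings.warn("all groups constant and equal; F reported as 0, p = 1")
        return TestResult(0.0, 1.0, "one-way-anova",
                          df=float(len(groups) - 1),
                          group_sizes=tuple(len(g) for g in groups))
    res = sps.f_oneway(*groups)
    return TestResult(float(res.statistic), float(res.pvalue), "one-way-anova",
                      df=float(len(groups) - 1),
                      group_sizes=tuple(len(g) for g in groups))


def kruskal_wallis(groups: Sequence[np.ndarray]) -> TestResult:
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in groups):
        raise ValueError("kruskal_wallis: empty group")
    if all(np.array_equal(g, groups[0]) for g in groups):
        # identical groups: H = 0 by construction, scipy raises on all-ties
        return TestResult(0.0, 1.0, "kruskal-wallis", df=float(len(groups) - 1),
                          group_sizes=tuple(len(g) for g in groups))
    res = sps.kruskal(*groups)
    return TestResult(float(res.statistic), float(res.pvalue), "kruskal-wallis",
                      df=float(len(groups) - 1),
                      group_sizes=tuple(len(g) for g in groups))


def wilcoxon_rank_sum(a: np.ndarray, b: np.ndarray, exact_max_n: int = 12) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null distribution when the combined sample size is <= ``exact_max_n``
    and there are no ties; normal approximation with tie correction otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("wilcoxon_rank_sum: empty group")
    combined = np.concatenate([a, b])
    has_ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (len(combined) <= exact_max_n and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(float(res.statistic), float(min(res.pvalue, 1.0)),
                      f"wilcoxon-rank-sum-{method}",
                      group_sizes=(len(a), len(b)))


# ---------------------------------------------------------------------------
# Cohort-level analyses

def _holm(pvals: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    return multipletests(pvals, method="holm")[1]


def group_compare_ddcfdna(cohort, adjust: bool = False):
    """Omnibus Kruskal-Wallis across diagnosis groups plus all pairwise
    Wilcoxon rank-sum post-tests on the plasma ddcfDNA fraction.

    Returns ``(omnibus: TestResult, pairwise: DataFrame)``; pairwise rows with
    a group of size < 2 are skipped with a warning. Raw p-values are primary;
    ``adjust=True`` adds a Holm-adjusted column.
    """
    from .cohort import DIAGNOSIS_GROUPS

    values = {g: np.array([r.ddcfdna_fraction for r in cohort if r.diagnosis == g])
              for g in DIAGNOSIS_GROUPS}
    values = {g: v for g, v in values.items() if len(v) > 0}
    if len(values) < 2:
        raise ValueError("need at least two diagnosis groups")
    omnibus = kruskal_wallis(list(values.values()))
    rows = []
    names = list(values)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            ga, gb = names[i], names[j]
            if len(values[ga]) < 2 or len(values[gb]) < 2:
                warnings.warn(f"post-test {ga} vs {gb} skipped (group of size < 2)")
                continue
            res = wilcoxon_rank_sum(values[ga], values[gb])
            rows.append({"group_a": ga, "group_b": gb, "n_a": len(values[ga]),
                         "n_b": len(values[gb]), "statistic": res.statistic,
                         "p_value": res.p_value, "method": res.method})
    pairwise = pd.DataFrame(rows)
    if adjust and len(pairwise):
        pairwise["p_holm"] = _holm(pairwise["p_value"].to_numpy())
    return omnibus, pairwise


#: Named contrasts from the lesion-association analysis: severe interstitial
#: inflammation vs score <= 1; moderate-severe microvascular inflammation;
#: presence/absence for lesions too sparse for level-wise testing.
SPECIAL_CONTRASTS = {
    "i": ("i3_vs_i<=1", lambda s: s == 3, lambda s: s <= 1),
    "mvi": ("mvi>=2_vs_mvi<2", lambda s: s >= 2, lambda s: s < 2),
    "ah": ("ah>0_vs_ah=0", lambda s: s > 0, lambda s: s == 0),
    "c4d": ("c4d>0_vs_c4d=0", lambda s: s > 0, lambda s: s == 0),
}


def lesion_score_association(cohort, lesion: str, adjust: bool = False) -> dict:
    """ddcfDNA fraction vs one Banff lesion's score levels.

    Returns a dict with a per-level summary frame, the omnibus Kruskal-Wallis
    across populated levels, all pairwise level contrasts, and (for i, mvi,
    ah, c4d) the named special contrast.
    """
    scores = np.array([r.banff.score(lesion) for r in cohort])
    dd = np.array([r.ddcfdna_fraction for r in cohort])
    levels = sorted(set(scores.tolist()))
    summary = pd.DataFrame([
        {"level": lvl, "n": int((scores == lvl).sum()),
         "median": float(np.median(dd[scores == lvl])),
         "q25": float(np.percentile(dd[scores == lvl], 25)),
         "q75": float(np.percentile(dd[scores == lvl], 75))}
        for lvl in levels
    ])
    groups = [dd[scores == lvl] for lvl in levels if (scores == lvl).sum() > 0]
    omnibus = kruskal_wallis(groups) if len(groups) >= 2 else None
    rows = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            a, b = dd[scores == levels[i]], dd[scores == levels[j]]
            if len(a) < 2 or len(b) < 2:
                continue
            res = wilcoxon_rank_sum(a, b)
            rows.append({"level_a": levels[i], "level_b": levels[j],
                         "statistic": res.statistic, "p_value": res.p_value,
                         "method": res.method})
    pairwise = pd.DataFrame(rows)
    if adjust and len(pairwise):
        pairwise["p_holm"] = _holm(pairwise["p_value"].to_numpy())
    special = None
    if lesion in SPECIAL_CONTRASTS:
        name, in_a, in_b = SPECIAL_CONTRASTS[lesion]
        a, b = dd[in_a(scores)], dd[in_b(scores)]
        if len(a) >= 2 and len(b) >= 2:
            special = (name, wilcoxon_rank_sum(a, b))
    return {"lesion": lesion, "summary": summary, "omnibus": omnibus,
            "pairwise": pairwise, "special": special}


def tertile_split(cohort_or_values, recipient_ids: Optional[Sequence[str]] = None) -> pd.Series:
    """Split recipients into low / medium / high thirds of ddcfDNA fraction.

    After sorting ascending (stable tie-break on recipient_id), the lowest
    floor(n/3) recipients are 'low', the highest floor(n/3) are 'high', and
    the remainder 'medium' — so n = 106 gives 35/36/35.
    """
    if recipient_ids is None:
        values = np.array([r.ddcfdna_fraction for r in cohort_or_values])
        ids = [r.recipient_id for r in cohort_or_values]
    else:
        values = np.asarray(cohort_or_values, dtype=float)
        ids = list(recipient_ids)
    n = len(values)
    if n < 3:
        raise ValueError("tertile_split needs n >= 3")
    order = sorted(range(n), key=lambda k: (values[k], ids[k]))
    third = n // 3
    labels = [""] * n
    for rank, k in enumerate(order):
        labels[k] = "low" if rank < third else ("high" if rank >= n - third else "medium")
    return pd.Series(labels, index=ids, name="ddcfdna_tertile")


def cluster_heatmap(matrix: pd.DataFrame) -> ClusteringResult:
    """Hierarchical clustering of recipients on z-scored density columns.

    Missing entries are imputed with the column median (warned); constant
    columns cannot be standardized and are excluded (warned). Distances are
    Euclidean, linkage is average (UPGMA); the returned row order is the
    dendrogram leaf order.
    """
    if len(matrix) < 2:
        raise ValueError("need >= 2 rows to cluster")
    mat = matrix.astype(float).copy()
    if mat.isna().any().any():
        warnings.warn("imputing missing values with column medians")
        mat = mat.fillna(mat.median())
    dropped = [c for c in mat.columns if mat[c].std(ddof=0) == 0]
    if dropped:
        warnings.warn(f"excluding constant columns from standardization: {dropped}")
        mat = mat.drop(columns=dropped)
    if mat.shape[1] == 0:
        raise ValueError("no non-constant columns to cluster on")
    z = (mat - mat.mean()) / mat.std(ddof=0)
    linkage = hierarchy.linkage(z.to_numpy(), method="average", metric="euclidean")
    if (np.diff(linkage[:, 2]) < -1e-9).any():
        warnings.warn("non-monotone merge heights in average linkage")
    order = hierarchy.leaves_list(linkage)
    return ClusteringResult(linkage=linkage, row_order=order,
                            standardized=z, dropped_columns=dropped)


def correlation_matrix(matrix: pd.DataFrame, min_pairs: int = 3):
    """Pairwise-complete Pearson correlations with two-sided t-based p-values.

    Returns ``(r, p, n)`` DataFrames over the input columns. Pairs with fewer
    than ``min_pairs`` complete observations, or zero variance in either
    variable, are reported as missing.
    """
    cols = list(matrix.columns)
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i, k):
            pair = matrix[[cols[i], cols[j]]].dropna() if i != j else matrix[[cols[i]]].dropna()
            if i == j:
                n[i, i] = len(pair)
                if len(pair) >= min_pairs and pair[cols[i]].std(ddof=0) > 0:
                    r[i, i], p[i, i] = 1.0, 0.0
                continue
            x, y = pair[cols[i]].to_numpy(), pair[cols[j]].to_numpy()
            n[i, j] = n[j, i] = len(pair)
            if len(pair) < min_pairs or x.std(ddof=0) == 0 or y.std(ddof=0) == 0:
                continue
            res = sps.pearsonr(x, y)
            r[i, j] = r[j, i] = float(res.statistic)
            p[i, j] = p[j, i] = float(res.pvalue)
    return (pd.DataFrame(r, index=cols, columns=cols),
            pd.DataFrame(p, index=cols, columns=cols),
            pd.DataFrame(n, index=cols, columns=cols))
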