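import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from graftquant.stats import (ClusteringResult, ContingencyTable, TestResult,
                              chi_square_test, cluster_heatmap,
                              correlation_matrix, group_compare_ddcfdna,
                              kruskal_wallis, lesion_score_association,
                              one_way_anova, tertile_split, wilcoxon_rank_sum)
from tests.conftest import table2_counts


# ---------------------------------------------------------------------------
# Independent oracles

def chi_square_oracle(counts: np.ndarray) -> tuple[float, float]:
    """Textbook sum((O-E)^2 / E) with chi-square tail probability."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / total
    stat = ((counts - expected) ** 2 / expected).sum()
    df = (counts.shape[0] - 1) * (counts.shape[1] - 1)
    return stat, float(sps.chi2.sf(stat, df))


def wilcoxon_enumeration_oracle(a, b) -> float:
    """Exact two-sided p by enumerating every group assignment of the ranks."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n_a = len(a)
    w_obs = ranks[:n_a].sum()
    mean_w = n_a * (len(pooled) + 1) / 2
    count = more_extreme = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        w = ranks[list(combo)].sum()
        count += 1
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            more_extreme += 1
    return more_extreme / count


class TestChiSquare:
    @pytest.mark.parametrize("lesion", ["g", "ct", "t", "v", "i", "ci", "ptc"])
    def test_matches_textbook_oracle(self, lesion):
        counts = table2_counts()[lesion]
        table = ContingencyTable([f"{lesion}{k}" for k in range(4)],
                                 ["NR", "Borderline", "TCMR", "ABMR"], counts)
        stat_o, p_o = chi_square_oracle(counts[counts.sum(axis=1) > 0])
        res = chi_square_test(table)
        assert res.statistic == pytest.approx(stat_o)
        assert res.p_value == pytest.approx(p_o)

    def test_perfect_independence(self):
        table = ContingencyTable(["a", "b"], ["x", "y"], [[10, 10], [10, 10]])
        res = chi_square_test(table)
        assert res.statistic == 0 and res.p_value == 1

    def test_zero_margin_rows_dropped(self):
        table = ContingencyTable(["a", "b", "c"], ["x", "y"],
                                 [[5, 1], [0, 0], [1, 5]])
        with pytest.warns(UserWarning, match="zero-margin"):
            res = chi_square_test(table)
        assert res.df == 1

    def test_degenerate_raises(self):
        table = ContingencyTable(["a", "b"], ["x", "y"], [[3, 4], [0, 0]])
        with pytest.warns(UserWarning), pytest.raises(ValueError, match="degenerate"):
            chi_square_test(table)


class TestAnova:
    def test_zero_between_variance(self):
        res = one_way_anova([[1, 2, 3], [1, 2, 3]])
        assert res.statistic == 0 and res.p_value == 1

    def test_all_constant_convention(self):
        with pytest.warns(UserWarning, match="constant"):
            res = one_way_anova([[2, 2, 2], [2, 2]])
        assert res.p_value == 1

    def test_textbook_two_by_three_example(self):
        """Hand computation: groups (1,2,3) and (2,4,6).
        Grand mean 3; SSB = 3*(2-3)^2 + 3*(4-3)^2 = 6 (df 1);
        SSW = 2 + 8 = 10 (df 4); F = 6 / (10/4) = 2.4."""
        res = one_way_anova([[1, 2, 3], [2, 4, 6]])
        assert res.statistic == pytest.approx(2.4)
        assert res.p_value == pytest.approx(float(sps.f.sf(2.4, 1, 4)))

    def test_planted_shift_power(self):
        rng = np.random.default_rng(0)
        groups = [rng.normal(3 * k, 1.0, size=20) for k in range(3)]
        assert one_way_anova(groups).p_value < 0.01


class TestRankTests:
    def test_extreme_separation_exact_p(self):
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert res.method == "wilcoxon-rank-sum-exact"
        assert res.p_value == pytest.approx(0.1)  # 2/20 arrangements

    def test_exact_equals_enumeration_all_small_sizes(self):
        rng = np.random.default_rng(1)
        for n_a in range(1, 6):
            for n_b in range(n_a, 11 - n_a):
                if n_a + n_b > 10:
                    continue
                a = rng.normal(size=n_a)
                b = rng.normal(size=n_b)
                res = wilcoxon_rank_sum(a, b)
                assert res.p_value == pytest.approx(
                    wilcoxon_enumeration_oracle(a, b)), (n_a, n_b)

    def test_identical_groups_kw_zero(self):
        res = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert res.statistic == 0

    def test_kw_two_groups_agrees_with_wilcoxon(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=30), rng.normal(0.5, 1, size=25)
        p_kw = kruskal_wallis([a, b]).p_value
        p_w = wilcoxon_rank_sum(a, b).p_value
        assert p_kw == pytest.approx(p_w, rel=0.05)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0], []])
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestGroupCompare:
    def test_power_under_generator_defaults(self):
        """ABMR vs NR separates (p < 0.05) in >= 90% of seeds at the default
        group medians and log-sd 0.6."""
        from graftquant.synthetic import SimCohortParams, simulate_cohort

        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            records, _ = simulate_cohort(SimCohortParams(seed=seed))
            _, pairwise = group_compare_ddcfdna(records)
            row = pairwise[(pairwise.group_a == "NR") & (pairwise.group_b == "ABMR")]
            hits += float(row.p_value.iloc[0]) < 0.05
        assert hits / n_seeds >= 0.90

    def test_degenerate_groups_skipped(self):
        from graftquant.cohort import CohortRecord

        records = [CohortRecord("a", 1.0, "NR"), CohortRecord("b", 2.0, "TCMR"),
                   CohortRecord("c", 2.5, "TCMR")]
        with pytest.warns(UserWarning, match="skipped"):
            _, pairwise = group_compare_ddcfdna(records)
        assert len(pairwise) == 0


class TestLesionAssociation:
    def test_mvi_grouping_uses_g_plus_ptc(self):
        from graftquant.cohort import BanffScores, CohortRecord

        records = [CohortRecord(f"r{i}", 1.0 + i, "TCMR",
                                BanffScores(g=2, ptc=1)) for i in range(4)]
        res = lesion_score_association(records, "mvi")
        assert list(res["summary"]["level"]) == [3]

    def test_planted_monotone_shift_detected(self):
        from graftquant.cohort import BanffScores, CohortRecord

        rng = np.random.default_rng(3)
        records = []
        for i in range(106):
            v = int(rng.integers(0, 3))
            dd = float(np.exp(rng.normal(0.0 + 0.6 * v, 0.6)))
            records.append(CohortRecord(f"r{i}", dd, "TCMR", BanffScores(v=v)))
        res = lesion_score_association(records, "v")
        assert res["omnibus"].p_value < 0.05

    def test_special_contrast_i3_vs_le1(self):
        from graftquant.cohort import BanffScores, CohortRecord

        rng = np.random.default_rng(4)
        records = []
        for i in range(60):
            score = int(rng.integers(0, 4))
            dd = float(np.exp(rng.normal(1.5 if score == 3 else 0.0, 0.3)))
            records.append(CohortRecord(f"r{i}", dd, "TCMR", BanffScores(i=score)))
        res = lesion_score_association(records, "i")
        name, contrast = res["special"]
        assert name == "i3_vs_i<=1"
        assert contrast.p_value < 0.01


class TestTertiles:
    def test_106_gives_35_36_35(self):
        rng = np.random.default_rng(0)
        labels = tertile_split(rng.random(106), [f"r{i:03d}" for i in range(106)])
        assert labels.value_counts().to_dict() == {"medium": 36, "low": 35, "high": 35}

    def test_all_equal_values_stable_tie_break(self):
        labels = tertile_split(np.ones(106), [f"r{i:03d}" for i in range(106)])
        counts = labels.value_counts().to_dict()
        assert counts == {"medium": 36, "low": 35, "high": 35}
        # stable: lexicographically smallest ids are 'low'
        assert all(labels[f"r{i:03d}"] == "low" for i in range(35))

    @given(st.integers(min_value=3, max_value=300))
    @settings(max_examples=60, deadline=None)
    def test_sizes_for_all_n(self, n):
        labels = tertile_split(np.arange(n, dtype=float),
                               [f"r{i:04d}" for i in range(n)])
        counts = labels.value_counts()
        assert counts.get("low", 0) == n // 3
        assert counts.get("high", 0) == n // 3
        assert counts.get("medium", 0) == n - 2 * (n // 3)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            tertile_split(np.array([1.0, 2.0]), ["a", "b"])


def average_linkage_oracle(X: np.ndarray) -> np.ndarray:
    """Brute-force O(n^3) UPGMA on Euclidean distances; returns merge heights."""
    clusters = {i: [i] for i in range(len(X))}
    dists = {}

    def cdist(a, b):
        return np.mean([np.linalg.norm(X[i] - X[j]) for i in clusters[a] for j in clusters[b]])

    heights = []
    next_id = len(X)
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = min(((cdist(a, b), a, b) for i, a in enumerate(keys)
                    for b in keys[i + 1:]))
        d, a, b = best
        heights.append(d)
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return np.array(heights)


class TestClustering:
    def test_identical_rows_merge_first_at_zero(self):
        df = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [9.0, 9.0]],
                          columns=["a", "b"])
        res = cluster_heatmap(df)
        assert res.linkage[0, 2] == 0.0
        assert {int(res.linkage[0, 0]), int(res.linkage[0, 1])} == {0, 1}

    def test_planted_two_blob_partition(self):
        rng = np.random.default_rng(5)
        blob1 = rng.normal(0, 0.1, size=(2, 3))
        blob2 = rng.normal(5, 0.1, size=(2, 3))
        df = pd.DataFrame(np.vstack([blob1, blob2]))
        res = cluster_heatmap(df)
        # top split separates rows {0,1} from {2,3}
        from scipy.cluster.hierarchy import fcluster

        assignments = fcluster(res.linkage, t=2, criterion="maxclust")
        assert assignments[0] == assignments[1] != assignments[2] == assignments[3]

    def test_matches_bruteforce_upgma(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.normal(size=(8, 4)))
        res = cluster_heatmap(df)
        z = res.standardized.to_numpy()
        assert np.allclose(np.sort(res.linkage[:, 2]),
                           np.sort(average_linkage_oracle(z)))

    def test_constant_column_excluded_with_warning(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="constant"):
            res = cluster_heatmap(df)
        assert res.dropped_columns == ["b"]

    def test_missing_values_imputed_with_warning(self):
        df = pd.DataFrame({"a": [1.0, np.nan, 3.0], "b": [2.0, 1.0, 0.0]})
        with pytest.warns(UserWarning, match="imput"):
            cluster_heatmap(df)


class TestCorrelationMatrix:
    def test_perfect_linear(self):
        x = np.arange(10, dtype=float)
        df = pd.DataFrame({"x": x, "y": 2 * x})
        r, p, n = correlation_matrix(df)
        assert r.loc["x", "y"] == pytest.approx(1.0)
        assert n.loc["x", "y"] == 10

    def test_hand_formula_three_points(self):
        """(1,2),(2,4),(3,5): cov = 3/2 (n-1 denom), sx = 1, sy = sqrt(7/3),
        r = 1.5 / sqrt(7/3) = 0.9819805061..."""
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [2.0, 4.0, 5.0]})
        r, _, _ = correlation_matrix(df)
        assert r.loc["x", "y"] == pytest.approx(1.5 / np.sqrt(7 / 3))

    def test_zero_variance_reported_missing(self):
        df = pd.DataFrame({"x": [1.0, 1.0, 1.0], "y": [1.0, 2.0, 3.0]})
        r, p, _ = correlation_matrix(df)
        assert np.isnan(r.loc["x", "y"]) and np.isnan(p.loc["x", "y"])

    def test_pairwise_complete(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, np.nan, 5.0],
                           "y": [2.0, 4.0, 6.0, 8.0, np.nan]})
        r, _, n = correlation_matrix(df)
        assert n.loc["x", "y"] == 3
        assert r.loc["x", "y"] == pytest.approx(1.0)

    def test_planted_r_recovery(self):
        rng = np.random.default_rng(7)
        estimates = []
        for _ in range(200):
            x = rng.normal(size=106)
            y = 0.6 * x + np.sqrt(1 - 0.36) * rng.normal(size=106)
            r, _, _ = correlation_matrix(pd.DataFrame({"x": x, "y": y}))
            estimates.append(r.loc["x", "y"])
        assert abs(np.mean(estimates) - 0.6) < 0.03
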