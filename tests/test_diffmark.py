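import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from markcord.diffmark import (
    DifferentialMark,
    classify_dhg,
    cluster_dhg,
    diff_test,
    group_ratio,
    welch_p,
)

GROUPS = {f"LN_{i}": "LN" for i in range(1, 5)} | \
         {f"HN_{i}": "HN" for i in range(1, 5)}
COLS = list(GROUPS)


def _frame(rows: dict[str, list[float]]) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index", columns=COLS)


def welch_oracle(a, b):
    """Closed-form Welch t-test on log2(x+1), written out long-hand."""
    xa = [math.log2(v + 1) for v in a]
    xb = [math.log2(v + 1) for v in b]
    na, nb = len(xa), len(xb)
    ma, mb = sum(xa) / na, sum(xb) / nb
    va = sum((v - ma) ** 2 for v in xa) / (na - 1)
    vb = sum((v - mb) ** 2 for v in xb) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return 2 * stats.t.sf(abs(t), df)


class TestDiffTest:
    def test_identical_groups_are_null(self):
        res = diff_test(_frame({"g": [4, 5, 6, 5, 4, 5, 6, 5]}), GROUPS)
        row = res.loc["g"]
        assert row["p_value"] == 1.0
        assert row["ln_hn_ratio"] == 1.0
        assert row["direction"] == "ns"

    def test_matches_hand_computed_welch(self):
        ln, hn = [4, 5, 6, 5], [1, 2, 1, 2]
        res = diff_test(_frame({"g": ln + hn}), GROUPS)
        row = res.loc["g"]
        assert row["direction"] == "up"
        assert row["p_value"] == pytest.approx(welch_oracle(ln, hn), rel=1e-12)
        assert row["ln_hn_ratio"] == pytest.approx(5.0 / 1.5)

    def test_matches_scipy_ttest(self):
        rng = np.random.default_rng(0)
        mat = pd.DataFrame(rng.gamma(3, 10, (50, 8)), columns=COLS,
                           index=[f"g{i}" for i in range(50)])
        res = diff_test(mat, GROUPS)
        x = np.log2(mat.to_numpy() + 1)
        _, p = stats.ttest_ind(x[:, :4], x[:, 4:], axis=1, equal_var=False)
        np.testing.assert_allclose(res["p_value"], p, rtol=1e-10)

    def test_zero_denominator_contract(self):
        res = diff_test(_frame({"g": [3, 4, 5, 4, 0, 0, 0, 0]}), GROUPS)
        row = res.loc["g"]
        assert row["ln_hn_ratio"] == np.inf
        assert np.isfinite(row["log2_ratio"]) and row["log2_ratio"] > 0

    def test_zero_variance_unequal_means_gets_floor_p(self, caplog):
        res = diff_test(_frame({"g": [4, 4, 4, 4, 2, 2, 2, 2]}), GROUPS)
        assert res.loc["g", "p_value"] == float(np.finfo(float).tiny)
        assert "zero within-group variance" in caplog.text

    def test_relabeling_within_group_is_invariant(self):
        rows = {"g": [4.0, 9.0, 6.0, 5.0, 1.0, 2.0, 1.5, 2.5]}
        res1 = diff_test(_frame(rows), GROUPS)
        shuffled = _frame(rows)[["LN_3", "LN_1", "LN_4", "LN_2",
                                 "HN_2", "HN_4", "HN_1", "HN_3"]]
        res2 = diff_test(shuffled, GROUPS)
        assert res1.loc["g", "p_value"] == pytest.approx(
            res2.loc["g", "p_value"], rel=1e-12)

    def test_swapping_groups_flips_sign_keeps_p(self):
        mat = _frame({"g": [4, 9, 6, 5, 1, 2, 1.5, 2.5]})
        fwd = diff_test(mat, GROUPS)
        swapped = {s: ("HN" if g == "LN" else "LN") for s, g in GROUPS.items()}
        rev = diff_test(mat, swapped)
        assert fwd.loc["g", "p_value"] == pytest.approx(
            rev.loc["g", "p_value"], rel=1e-12)
        assert fwd.loc["g", "log2_ratio"] == pytest.approx(
            -rev.loc["g", "log2_ratio"], rel=1e-12)

    def test_ratio_and_log2_ratio_agree_in_sign(self):
        rng = np.random.default_rng(3)
        mat = pd.DataFrame(rng.gamma(4, 20, (200, 8)) + 1.0, columns=COLS,
                           index=[f"g{i}" for i in range(200)])
        res = diff_test(mat, GROUPS)
        defined = np.isfinite(res["ln_hn_ratio"]) & (res["ln_hn_ratio"] != 1.0)
        assert (np.sign(np.log(res.loc[defined, "ln_hn_ratio"]))
                == np.sign(res.loc[defined, "log2_ratio"])).all()

    def test_requires_two_replicates(self):
        with pytest.raises(ValueError, match=">= 2 replicates"):
            diff_test(_frame({"g": [1] * 8})[["LN_1", "HN_1", "HN_2"]],
                      GROUPS)


class TestClassify:
    def test_all_null_gives_empty_lists(self):
        res = diff_test(_frame({"g": [4, 5, 6, 5, 4, 5, 6, 5]}), GROUPS)
        assert classify_dhg(res, 0.05) == ([], [])

    def test_alpha_one_classifies_everything(self):
        mat = _frame({"g1": [4, 5, 6, 5, 1, 2, 1, 2],
                      "g2": [1, 2, 1, 2, 4, 5, 6, 5]})
        res = diff_test(mat, GROUPS)
        hyper, hypo = classify_dhg(res, 1.0000001)
        assert set(hyper) | set(hypo) == {"g1", "g2"}
        assert hyper == ["g1"] and hypo == ["g2"]

    def test_recovers_planted_differential_genes(self, small_dataset):
        from conftest import mark_diff

        res = mark_diff(small_dataset, "H3K4me3")
        hyper, hypo = classify_dhg(res, 0.05)
        planted = set(small_dataset.truth.planted("H3K4me3"))
        recovered = (set(hyper) | set(hypo)) & planted
        assert len(recovered) >= 0.9 * len(planted)


def brute_force_average_linkage(dist: np.ndarray):
    """O(n^3) agglomeration: repeatedly merge the closest pair under
    unweighted average linkage; returns sorted merge heights."""
    clusters = [[i] for i in range(len(dist))]
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        heights.append(d)
        merged = clusters[a] + clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged)
    return sorted(heights)


class TestClustering:
    def test_identical_rows_merge_at_height_zero(self):
        mat = _frame({
            "g1": [5, 6, 7, 6, 1, 2, 1, 2],
            "g2": [5, 6, 7, 6, 1, 2, 1, 2],
            "g3": [1, 2, 1, 2, 5, 6, 7, 6],
        })
        res = diff_test(mat, GROUPS)
        res["p_value"] = 0.001  # force all three into the clustering
        clust = cluster_dhg(mat, res, alpha=0.01)
        assert clust.gene_linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_linkage_heights_match_brute_force(self):
        rng = np.random.default_rng(5)
        n = 6
        mat = pd.DataFrame(rng.gamma(3, 5, (n, 8)), columns=COLS,
                           index=[f"g{i}" for i in range(n)])
        res = diff_test(mat, GROUPS)
        res["p_value"] = 0.001
        clust = cluster_dhg(mat, res, alpha=0.01)
        x = np.log2(mat.to_numpy() + 1)
        c = np.corrcoef(x)
        dist = 1 - c
        np.fill_diagonal(dist, 0)
        expected = brute_force_average_linkage(dist)
        np.testing.assert_allclose(sorted(clust.gene_linkage[:, 2]), expected,
                                   rtol=1e-9)

    def test_sample_partition_separates_groups(self, small_dataset):
        from conftest import mark_diff, mark_matrix

        ds = small_dataset
        mat = mark_matrix(ds, "H3K4me3")
        res = mark_diff(ds, "H3K4me3")
        clust = cluster_dhg(mat, res, alpha=0.01)
        labels = {}
        for sample, cl in clust.sample_partition.items():
            labels.setdefault(cl, set()).add(ds.groups[sample])
        assert all(len(v) == 1 for v in labels.values())

    def test_zero_variance_row_gets_distance_one(self, caplog):
        mat = _frame({
            "flat": [3, 3, 3, 3, 3, 3, 3, 3],
            "g1": [5, 6, 7, 6, 1, 2, 1, 2],
            "g2": [5, 7, 6, 6, 1, 2, 2, 1],
        })
        res = diff_test(mat, GROUPS)
        res["p_value"] = 0.001
        clust = cluster_dhg(mat, res, alpha=0.01)
        assert "zero-variance" in caplog.text
        # the flat gene joins last, at height ~1
        assert clust.gene_linkage[-1, 2] == pytest.approx(1.0, abs=1e-6)

    def test_needs_two_significant_regions(self):
        mat = _frame({"g": [4, 5, 6, 5, 4, 5, 6, 5]})
        res = diff_test(mat, GROUPS)
        with pytest.raises(ValueError, match=">= 2 regions"):
            cluster_dhg(mat, res, alpha=0.01)


class TestSummaryStats:
    @pytest.mark.parametrize("a,b,expected", [
        (24.29, 32.91, 0.74),
        (508.12, 641.73, 0.79),
        (641.73, 329.1, 1.95),
        (2.10, 32.91, 0.06),
    ])
    def test_group_ratio_rounds_half_up(self, a, b, expected):
        assert group_ratio(a, b) == expected

    def test_group_ratio_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            group_ratio(1.0, 0.0)

    def test_equal_means_give_p_one(self):
        assert welch_p(5.0, 1.0, 4, 5.0, 2.0, 4) == 1.0

    def test_welch_p_matches_sample_level_test(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(3, 1, 6), rng.normal(4, 2, 8)
        expected = stats.ttest_ind(a, b, equal_var=False).pvalue
        got = welch_p(a.mean(), stats.sem(a), len(a),
                      b.mean(), stats.sem(b), len(b))
        assert got == pytest.approx(expected, rel=1e-10)

    def test_one_sided_welch_halves_p(self):
        p2 = welch_p(6.0, 0.5, 4, 5.0, 0.5, 4)
        p1 = welch_p(6.0, 0.5, 4, 5.0, 0.5, 4, alternative="greater")
        assert p1 == pytest.approx(p2 / 2)


class TestModelInterface:
    def test_fit_returns_results_with_summary(self, small_dataset):
        from conftest import mark_matrix

        ds = small_dataset
        mat = mark_matrix(ds, "H3K4me3")
        model = DifferentialMark(mat, ds.groups, mark="H3K4me3")
        res = model.fit(alpha=0.05)
        assert res.table.shape[0] == len(mat)
        text = res.summary()
        assert "H3K4me3" in text and "regions tested: 300" in text
        hyper, hypo = res.classify()
        assert set(hyper).isdisjoint(hypo)

    def test_bh_adjustment_is_monotone(self, small_dataset):
        from conftest import mark_matrix

        ds = small_dataset
        mat = mark_matrix(ds, "H3K4me3")
        res = DifferentialMark(mat, ds.groups).fit(adjust="bh")
        assert (res.table["p_adj"] >= res.table["p_value"] - 1e-15).all()
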