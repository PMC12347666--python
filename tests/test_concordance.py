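import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from markcord.concordance import (
    ConcordanceAnalysis,
    ModifierSpec,
    classify_concordance,
    compare_modifiers,
    select_top,
    summarize_records,
)

ACT = ModifierSpec("H3K4me3", "activating")
REP = ModifierSpec("H3K27me3", "repressive")


def _diff(p, lr, ids=None):
    ids = ids or [f"g{i}" for i in range(len(p))]
    return pd.DataFrame({"p_value": p, "log2_ratio": lr},
                        index=pd.Index(ids, name="region_id"))


class TestSelectTop:
    def test_takes_k_smallest_p(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.001, 1, 25)
        top = select_top(_diff(p, np.ones(25)), k=20)
        assert len(top) == 20
        assert set(top["p_value"]) == set(np.sort(p)[:20])

    def test_tie_break_by_effect_then_id(self):
        d = _diff([0.01, 0.01, 0.01], [0.5, -2.0, 2.0], ["b", "c", "a"])
        top = select_top(d, k=2)
        # |log2| descending first, then id: c (2.0) ties a (2.0) -> a < c
        assert list(top["gene_id"]) == ["a", "c"]

    def test_short_list_returns_all_with_warning(self, caplog):
        top = select_top(_diff([0.1, 0.2], [1, 1]), k=20)
        assert len(top) == 2
        assert "only 2 eligible" in caplog.text

    def test_skips_genes_missing_from_expression(self):
        d = _diff([0.01, 0.02, 0.03], [1, 1, 1], ["a", "b", "c"])
        top = select_top(d, k=2, eligible={"a", "c"})
        assert list(top["gene_id"]) == ["a", "c"]

    def test_cpg_best_site_per_gene(self):
        d = _diff([0.5, 0.001, 0.02], [0.1, -0.8, 0.3],
                  ["gA|s1", "gA|s2", "gB|s1"])
        gene_map = {"gA|s1": "gA", "gA|s2": "gA", "gB|s1": "gB"}
        top = select_top(d, k=2, gene_ids=gene_map)
        assert list(top["gene_id"]) == ["gA", "gB"]
        assert list(top["region_id"]) == ["gA|s2", "gB|s1"]  # best site wins


class TestClassify:
    def test_activating_consistent_high_fc(self):
        r = classify_concordance("g", ACT, 1.0, 0.8, 0.01)
        assert r.consistent and r.high_fc and r.significant

    def test_repressive_consistent_low_fc(self):
        r = classify_concordance("g", REP, 1.0, -0.3, 0.04)
        assert r.consistent and not r.high_fc

    def test_insignificant_is_never_consistent(self):
        r = classify_concordance("g", ACT, 1.0, 0.8, 0.2)
        assert not r.consistent and r.high_fc
        assert not r.trend

    def test_trend_recorded_but_not_consistent(self):
        r = classify_concordance("g", ACT, 1.0, 0.8, 0.07)
        assert r.trend and not r.consistent

    def test_zero_expression_change_is_inconsistent(self):
        r = classify_concordance("g", ACT, 1.0, 0.0, 0.001)
        assert not r.consistent

    def test_high_fc_boundary_is_log2_1_5(self):
        on = classify_concordance("g", ACT, 1.0, math.log2(1.5), 0.01)
        off = classify_concordance("g", ACT, 1.0, math.log2(1.5) - 1e-9, 0.01)
        assert on.high_fc and not off.high_fc

    def test_polarity_antisymmetry_exact(self):
        """Flipping polarity and negating the modification ratio leaves
        every consistency call unchanged."""
        rng = np.random.default_rng(1)
        for _ in range(200):
            mod = rng.normal()
            expr = rng.normal()
            p = rng.uniform(0, 0.2)
            a = classify_concordance("g", ACT, mod, expr, p)
            b = classify_concordance(
                "g", ModifierSpec("H3K4me3", "repressive"), -mod, expr, p)
            assert a.consistent == b.consistent
            assert a.high_fc == b.high_fc


class TestSummarize:
    def test_perfect_line(self):
        recs = [classify_concordance(f"g{i}", ACT, float(i), float(i), 0.01)
                for i in (1, 2, 3)]
        s = summarize_records(recs)
        assert s.r_squared == pytest.approx(1.0)
        assert s.slope == pytest.approx(1.0)
        assert s.n_consistent == 3

    def test_zero_response_variance_is_degenerate(self):
        recs = [classify_concordance(f"g{i}", ACT, float(i), 1.0, 0.01)
                for i in (1, 2, 3)]
        s = summarize_records(recs)
        assert s.degenerate and s.r_squared is None

    def test_fewer_than_three_consistent_drops_r2(self):
        recs = [classify_concordance("g1", ACT, 1.0, 1.0, 0.01),
                classify_concordance("g2", ACT, 2.0, 2.0, 0.01),
                classify_concordance("g3", ACT, 2.0, 2.0, 0.5)]
        s = summarize_records(recs)
        assert s.n_consistent == 2 and s.r_squared is None

    def test_counts_respect_invariants(self):
        rng = np.random.default_rng(2)
        recs = [classify_concordance(f"g{i}", REP, rng.normal(), rng.normal(),
                                     rng.uniform())
                for i in range(40)]
        s = summarize_records(recs)
        assert 0 <= s.n_high_fc_consistent <= s.n_consistent
        assert s.n_consistent <= s.n_significant <= s.k == 40

    def test_high_fc_count_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        args = [(rng.normal(), rng.normal(), rng.uniform(0, 0.1))
                for _ in range(50)]
        counts = []
        for fc in (1.2, 1.5, 2.0, 3.0):
            recs = [classify_concordance(f"g{i}", ACT, m, e, p, fc=fc)
                    for i, (m, e, p) in enumerate(args)]
            counts.append(summarize_records(recs).n_high_fc_consistent)
        assert counts == sorted(counts, reverse=True)


class TestCompare:
    def _summaries(self):
        mk = lambda name, sig, cons, hf, r2: dataclasses.replace(
            summarize_records([], modifier=name), k=20, n_significant=sig,
            n_consistent=cons, n_high_fc_consistent=hf, r_squared=r2)
        return [mk("H3K27me3", 0, 0, 0, None),
                mk("H3K4me3", 16, 16, 10, 0.5704),
                mk("CpG", 1, 1, 0, None)]

    def test_strong_activating_modifier_ranks_first(self):
        ranking = compare_modifiers(self._summaries())
        assert ranking["modifier"].iloc[0] == "H3K4me3"
        # CpG beats H3K27me3 on n_consistent
        assert list(ranking["modifier"]) == ["H3K4me3", "CpG", "H3K27me3"]

    def test_permutation_invariant(self):
        s = self._summaries()
        r1 = compare_modifiers(s)
        r2 = compare_modifiers(list(reversed(s)))
        pd.testing.assert_frame_equal(r1, r2)

    def test_all_zero_keeps_input_order(self):
        mk = lambda name: summarize_records([], modifier=name)
        ranking = compare_modifiers([mk("a"), mk("b"), mk("c")])
        assert list(ranking["modifier"]) == ["a", "b", "c"]


class TestAnalysis:
    def _fit(self, ds, **kw):
        from conftest import mark_diff
        from markcord.diffmark import diff_test

        tables = {m: mark_diff(ds, m) for m in ("H3K4me3", "H3K27me3")}
        tables["CpG"] = diff_test(ds.methylation, ds.groups, pseudocount=0.01)
        return ConcordanceAnalysis(ds.expression, ds.groups, tables).fit(**kw)

    def test_planted_activating_coupling_is_recovered(self, small_dataset):
        res = self._fit(small_dataset, k=20)
        s = {x.modifier: x for x in res.summaries}["H3K4me3"]
        assert s.n_consistent >= 14
        assert s.r_squared is not None and s.r_squared >= 0.5

    def test_summary_text_mentions_all_modifiers(self, small_dataset):
        res = self._fit(small_dataset)
        text = res.summary()
        for name in ("H3K4me3", "H3K27me3", "CpG"):
            assert name in text

    def test_slope_recovery_with_tiny_noise(self):
        """With near-zero noise the OLS slope over consistent genes recovers
        the planted coupling within 5%."""
        from markcord.synthio import SyntheticConfig, simulate_dataset

        cfg = SyntheticConfig(seed=3, n_genes=400, effect_log2=1.5,
                              expr_noise_sd=0.01, expr_rep_sd=0.01,
                              nb_dispersion=0.001, baseline_log_mean=8.0,
                              coupling_slope_repressive=0.0)
        res = self._fit(simulate_dataset(cfg), k=20)
        s = {x.modifier: x for x in res.summaries}["H3K4me3"]
        assert s.slope == pytest.approx(1.0, rel=0.05)
        assert s.r_squared >= 0.99

    def test_unknown_modifier_requires_spec(self, small_dataset):
        from conftest import mark_diff

        tables = {"H3K9me3": mark_diff(small_dataset, "H3K4me3")}
        with pytest.raises(ValueError, match="ModifierSpec"):
            ConcordanceAnalysis(small_dataset.expression, small_dataset.groups,
                                tables)
        # works once a spec is supplied
        ConcordanceAnalysis(
            small_dataset.expression, small_dataset.groups, tables,
            specs={"H3K9me3": ModifierSpec("H3K9me3", "repressive")})
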