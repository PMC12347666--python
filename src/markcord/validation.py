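"""Self-contained validation scenarios: calibration, parameter recovery and
qualitative checks of the whole pipeline on synthetic data.

Each function simulates its own data from a seed, runs the ordinary public
API, and returns plain numbers. They are used by the acceptance suite and
by ``scripts/acceptance.py``, and are handy for sanity-checking the
pipeline after changes.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats

from .concordance import ConcordanceAnalysis
from .diffmark import classify_dhg, cluster_dhg, diff_test, group_ratio
from .promoter_quant import SCALE, metagene, promoter_windows, quantify_samples
from .synthio import MARKS, SyntheticConfig, simulate_dataset

__all__ = [
    "EXAMPLE_PHENOTYPES",
    "phenotype_ratios",
    "null_calibration",
    "dhg_recovery",
    "coupling_recovery",
    "modifier_ranking",
    "hypergeometric_oracle",
    "clustering_recovery",
    "metagene_invariants",
]

#: Fetal phenotype group means for the worked example: body weight (kg) and
#: liver weight (g) of high- vs low-nutrition groups, n=4 fetuses each.
EXAMPLE_PHENOTYPES = {
    "BW_kg": {"HN": 32.91, "LN": 24.29},
    "liver_g": {"HN": 641.73, "LN": 508.12},
}


def phenotype_ratios() -> dict[str, float]:
    """LN/HN effect-size ratios and the HN liver-to-body-weight percentage,
    each rounded half-up to two decimals (report convention)."""
    bw = EXAMPLE_PHENOTYPES["BW_kg"]
    liver = EXAMPLE_PHENOTYPES["liver_g"]
    return {
        "bw_ratio_ln_hn": group_ratio(bw["LN"], bw["HN"]),
        "liver_ratio_ln_hn": group_ratio(liver["LN"], liver["HN"]),
        # liver (g) as % of body weight (g): liver_g / (BW_kg * 1000) * 100
        "hn_liver_pct_bw": group_ratio(liver["HN"], bw["HN"] * 10.0),
    }


def _mark_diff_tables(ds, window: int = 1000) -> dict[str, pd.DataFrame]:
    windows = promoter_windows(ds.genes, window, ds.chrom_sizes)
    tables = {
        mark: diff_test(quantify_samples(ds.tracks[mark], windows), ds.groups)
        for mark in MARKS
    }
    tables["CpG"] = diff_test(ds.methylation, ds.groups, pseudocount=0.01)
    return tables


def null_calibration(seed: int, n_genes: int = 2000,
                     n_replicates: int = 40) -> dict[str, float]:
    """Type-I error of the differential test on null datasets.

    Pools the empirical rejection rate at alpha=0.05 over ``n_replicates``
    independent null datasets (both marks) for a high-precision estimate,
    and reports the median per-dataset KS-uniformity p at the stated
    ``n_genes``.
    """
    rates, ks_ps = [], []
    for i in range(n_replicates):
        cfg = SyntheticConfig(seed=seed + i, n_genes=n_genes,
                              frac_dhg=0.0, frac_dmg=0.0)
        ds = simulate_dataset(cfg)
        windows = promoter_windows(ds.genes, 1000, ds.chrom_sizes)
        for mark in MARKS:
            m = quantify_samples(ds.tracks[mark], windows)
            p = diff_test(m, ds.groups)["p_value"].to_numpy()
            rates.append(float((p < 0.05).mean()))
            ks_ps.append(float(stats.kstest(p, "uniform").pvalue))
    return {
        "null_rejection_rate": float(np.mean(rates)),
        "null_ks_uniform_p_median": float(np.median(ks_ps)),
    }


def dhg_recovery(seed: int, n_genes: int = 1000) -> dict[str, float]:
    """Sensitivity/FDR of DHG calling against planted truth.

    Conditions: planted |log2 LN/HN| = 1.5 on 10% of promoters, small
    negative-binomial dispersion. Raw-p calls at 0.05 measure sensitivity;
    FDR control is assessed on the Benjamini-Hochberg call set (a raw
    p<0.05 cut cannot bound FDR at 10% when 90% of regions are null).
    """
    cfg = SyntheticConfig(seed=seed, n_genes=n_genes, frac_dhg=0.1,
                          effect_log2=1.5)
    ds = simulate_dataset(cfg)
    windows = promoter_windows(ds.genes, 1000, ds.chrom_sizes)
    m = quantify_samples(ds.tracks["H3K4me3"], windows)
    res = diff_test(m, ds.groups, adjust="bh")
    planted = set(ds.truth.planted("H3K4me3"))
    raw = set().union(*classify_dhg(res, 0.05))
    bh = set().union(*classify_dhg(res, 0.05, use_adjusted=True))
    return {
        "recovery_sensitivity_raw": len(raw & planted) / len(planted),
        "recovery_fdr_raw": len(raw - planted) / max(len(raw), 1),
        "recovery_sensitivity_bh": len(bh & planted) / len(planted),
        "recovery_fdr_bh": len(bh - planted) / max(len(bh), 1),
    }


def coupling_recovery(seed: int, n_genes: int = 400) -> dict[str, float]:
    """OLS recovery of the planted activating coupling slope (+1.0) in the
    near-noiseless regime."""
    cfg = SyntheticConfig(seed=seed, n_genes=n_genes, effect_log2=1.5,
                          expr_noise_sd=0.01, expr_rep_sd=0.01,
                          nb_dispersion=0.001, baseline_log_mean=8.0,
                          coupling_slope_repressive=0.0)
    ds = simulate_dataset(cfg)
    res = ConcordanceAnalysis(ds.expression, ds.groups,
                              _mark_diff_tables(ds)).fit(k=20)
    s = {x.modifier: x for x in res.summaries}["H3K4me3"]
    return {
        "coupling_slope": float(s.slope),
        "coupling_r_squared": float(s.r_squared),
        "coupling_n_consistent": float(s.n_consistent),
    }


def modifier_ranking(seed: int, n_genes: int = 500) -> dict[str, float]:
    """Default study conditions: which modifier best explains expression
    change, per the (n_high_fc_consistent, n_consistent, R^2) ranking."""
    ds = simulate_dataset(SyntheticConfig(seed=seed, n_genes=n_genes))
    res = ConcordanceAnalysis(ds.expression, ds.groups,
                              _mark_diff_tables(ds)).fit(k=20)
    by = {x.modifier: x for x in res.summaries}
    top = res.ranking["modifier"].iloc[0]
    return {
        "h3k4me3_ranked_first": float(top == "H3K4me3"),
        "h3k4me3_n_consistent": float(by["H3K4me3"].n_consistent),
        "h3k4me3_n_high_fc_consistent":
            float(by["H3K4me3"].n_high_fc_consistent),
        "h3k27me3_n_high_fc_consistent":
            float(by["H3K27me3"].n_high_fc_consistent),
        "cpg_n_high_fc_consistent": float(by["CpG"].n_high_fc_consistent),
    }


def _exhaustive_tail_p(N: int, K: int, n: int, k: int) -> Fraction:
    term = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(term.intersection(draw)) >= k:
            hits += 1
    return Fraction(hits, total)


def hypergeometric_oracle(max_n: int = 12) -> dict[str, float]:
    """Compare the closed-form upper-tail p to exhaustive enumeration over
    every (N <= max_n, K, n, k); also reports the textbook 5/210 case."""
    worst = 0.0
    for N in range(1, max_n + 1):
        for K in range(N + 1):
            for n in range(1, N + 1):
                for k in range(1, min(n, K) + 1):
                    exact = float(_exhaustive_tail_p(N, K, n, k))
                    closed = float(stats.hypergeom.sf(k - 1, N, K, n))
                    worst = max(worst, abs(exact - closed))
    return {
        "hypergeom_textbook_p": float(stats.hypergeom.sf(3, 10, 5, 4)),
        "hypergeom_max_abs_error_vs_enumeration": worst,
    }


def _brute_force_average_linkage_heights(dist: np.ndarray) -> list[float]:
    clusters = [[i] for i in range(len(dist))]
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = float(np.mean([dist[i, j]
                               for i in clusters[a] for j in clusters[b]]))
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        heights.append(d)
        merged = clusters[a] + clusters[b]
        clusters = [c for x, c in enumerate(clusters) if x not in (a, b)]
        clusters.append(merged)
    return sorted(heights)


def clustering_recovery(seed: int, n_genes: int = 300) -> dict[str, float]:
    """k=2 sample cut of the DHG heatmap vs the true group labels, plus the
    worst deviation of average-linkage heights from an O(n^3) re-derivation
    on a 6-gene subset."""
    ds = simulate_dataset(SyntheticConfig(seed=seed, n_genes=n_genes))
    windows = promoter_windows(ds.genes, 1000, ds.chrom_sizes)
    matrix = quantify_samples(ds.tracks["H3K4me3"], windows)
    res = diff_test(matrix, ds.groups)
    clust = cluster_dhg(matrix, res, alpha=0.01)
    sides = {}
    for sample, cl in clust.sample_partition.items():
        sides.setdefault(cl, set()).add(ds.groups[sample])
    pure = float(all(len(v) == 1 for v in sides.values()) and len(sides) == 2)

    six = sorted(res.index[res["p_value"] < 0.01])[:6]
    sub = matrix.loc[six]
    res6 = res.loc[six].copy()
    clust6 = cluster_dhg(sub, res6, alpha=0.01)
    x = np.log2(sub.to_numpy() + 1.0)
    dist = 1.0 - np.corrcoef(x)
    np.fill_diagonal(dist, 0.0)
    expected = _brute_force_average_linkage_heights(dist)
    got = sorted(clust6.gene_linkage[:, 2])
    height_err = float(np.max(np.abs(np.asarray(got) - np.asarray(expected))))
    return {
        "cluster_partition_pure": pure,
        "cluster_linkage_height_max_err": height_err,
    }


def metagene_invariants(seed: int, n_genes: int = 200) -> dict[str, float]:
    """Mass conservation, strand symmetry and TSS-peak shape of the
    metagene profile on synthetic promoter-mark tracks."""
    ds = simulate_dataset(SyntheticConfig(seed=seed, n_genes=n_genes))
    track = ds.tracks["H3K4me3"][0]

    # conservation on one awkward-length gene
    gene = ds.genes[3]
    prof1 = metagene([track], [gene])
    widths = np.concatenate([np.full(30, 100.0), np.full(60, gene.length / 60),
                             np.full(30, 100.0)])
    binned = float((prof1.iloc[:, 0].to_numpy() * widths).sum())
    span = track.integral(gene.chrom, gene.start - 3000, gene.end + 3000)
    expected = span * SCALE / track.library_size
    conservation_err = abs(binned - expected) / expected

    # strand symmetry: mirror the genome
    L = ds.chrom_sizes[gene.chrom]
    genes = ds.genes[:50]
    from .iolib import GeneModel, SignalTrack

    starts, ends, values = track.chroms[gene.chrom]
    mirrored = SignalTrack(track.sample_id, track.group, {
        gene.chrom: (L - ends[::-1], L - starts[::-1], values[::-1])})
    flipped = [GeneModel(g.gene_id, g.chrom, L - g.end, L - g.start,
                         "-" if g.strand == "+" else "+") for g in genes]
    p_fwd = metagene([track], genes)
    p_rev = metagene([mirrored], flipped)
    sym_err = float(np.max(np.abs(p_fwd.iloc[:, 0] - p_rev.iloc[:, 0]))
                    / p_fwd.iloc[:, 0].max())

    # TSS-proximal single peak on the group profile
    prof = metagene(ds.tracks["H3K4me3"], ds.genes, input_track=ds.input_track)
    col = prof["LN"].to_numpy()
    distal = float(np.concatenate([col[:10], col[-10:]]).mean())
    peak_in_zone = float(20 <= int(col.argmax()) < 60)
    return {
        "metagene_conservation_rel_err": float(conservation_err),
        "metagene_strand_symmetry_rel_err": sym_err,
        "metagene_peak_within_1kb_of_tss": peak_in_zone,
        "metagene_peak_to_distal_ratio": float(col.max() / distal),
    }
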