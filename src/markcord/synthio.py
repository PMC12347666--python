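"""Synthetic datasets with planted structure matching a 4-vs-4 two-condition
promoter ChIP design.

The generator emulates the study design the analysis modules are built for:
two replicate groups ("LN" low nutrition, "HN" high nutrition, 4 fetuses
each), two promoter histone marks (H3K4me3 activating, H3K27me3 repressive),
an already-normalized log2 expression matrix, a promoter CpG methylation
(beta) matrix, and a term->gene annotation table with a few terms enriched
among the planted differential genes.

Statistical structure
---------------------
* Per-gene promoter intensity: lognormal baseline; a planted fraction
  (``frac_dhg`` per mark, disjoint gene sets) gets a symmetric group effect
  of ``+/- effect_log2`` split evenly between the groups; replicate counts
  are negative binomial (``var = mu + dispersion * mu^2``).
* Coverage tracks: the window ``[tss - window, tss + window)`` carries the
  count spread uniformly, on top of a flat genomic background; a flat
  "input" track is emitted for profile-control parity.
* Expression: per-gene group-mean log2 difference =
  sum over marks (coupling_slope_mark * true_mod_log2_mark)
  + meth_coupling_slope * planted beta difference + N(0, expr_noise_sd);
  replicates add iid N(0, expr_rep_sd).
* Methylation: beta values with a planted LN-HN difference on a gene set
  disjoint from the histone DHGs.

Everything is a pure function of the config (seed included): the same
config yields byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .iolib import (
    GeneModel,
    SignalTrack,
    write_bedgraph,
    write_gene_models,
    write_groups,
    write_matrix,
)

__all__ = ["SyntheticConfig", "GroundTruth", "SyntheticDataset",
           "simulate_dataset", "plant_expression"]

MARKS = ("H3K4me3", "H3K27me3")


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticConfig:
    """Full provenance of one generated dataset.

    Defaults encode the emulated study conditions: 4 replicates per group,
    10% planted differential promoters per mark at |log2 LN/HN| = 1 (the
    scale of top-ranked promoter changes in this kind of design),
    negative-binomial dispersion 0.01 around lognormal baselines of a few
    hundred reads per promoter (so top-ranked differential promoters
    separate cleanly from the null floor, with rank-20 p-values around
    1e-4..1e-3), activating coupling +1.0 and weak repressive coupling
    -0.3, and tight expression noise (see docs/methods.md).
    """

    seed: int
    n_genes: int = 500
    n_reps_per_group: int = 4
    genome: tuple[tuple[str, int], ...] | None = None
    frac_dhg: float = 0.1
    frac_dmg: float = 0.1
    effect_log2: float = 1.0
    meth_effect_beta: float = 0.2
    nb_dispersion: float = 0.01
    baseline_log_mean: float = math.log(300.0)
    baseline_log_sd: float = 1.0
    background_density: float = 0.01
    window: int = 1000
    gene_spacing: int = 10_000
    gene_length_range: tuple[int, int] = (2000, 6000)
    coupling_slope_activating: float = 1.0
    coupling_slope_repressive: float = -0.3
    meth_coupling_slope: float = 0.0
    expr_noise_sd: float = 0.04
    expr_rep_sd: float = 0.07
    expr_baseline_mean: float = 8.0
    expr_baseline_sd: float = 2.0
    meth_rep_sd: float = 0.02
    n_terms: int = 20
    term_size: int = 25
    n_enriched_terms: int = 3
    enriched_frac: float = 0.5

    def __post_init__(self) -> None:
        if not (0 <= self.frac_dhg <= 1 and 0 <= self.frac_dmg <= 1):
            raise ConfigError("planted fractions must lie in [0, 1]")
        if 2 * self.frac_dhg + self.frac_dmg > 1 + 1e-12:
            raise ConfigError("planted sets (two marks + methylation) are "
                              "disjoint; fractions exceed the gene universe")
        if self.n_reps_per_group < 2:
            raise ConfigError("need >= 2 replicates per group")
        for name in ("nb_dispersion", "baseline_log_sd", "expr_noise_sd",
                     "expr_rep_sd", "meth_rep_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.gene_length_range[0] < 1:
            raise ConfigError("gene length must be >= 1 bp")


@dataclass
class GroundTruth:
    """Planted per-gene effects (the generator's sidecar).

    ``table`` is indexed by gene_id with, per histone mark, columns
    ``dhg_<mark>`` (bool) and ``mod_log2_<mark>``; plus ``dmg_CpG``,
    ``meth_delta`` (planted LN-HN beta difference) and ``true_expr_log2``.
    """

    table: pd.DataFrame

    def planted(self, mark: str) -> list[str]:
        col = f"dhg_{mark}" if mark in MARKS else "dmg_CpG"
        return self.table.index[self.table[col]].tolist()


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    genes: list[GeneModel]
    chrom_sizes: dict[str, int]
    tracks: dict[str, list[SignalTrack]]      # mark -> per-sample tracks
    input_track: SignalTrack
    expression: pd.DataFrame                   # log2 scale, genes x samples
    methylation: pd.DataFrame                  # beta values, genes x samples
    annotation: list[tuple[str, str]]          # (term_id, gene_id) pairs
    groups: dict[str, str]                     # sample -> LN/HN
    truth: GroundTruth

    def write(self, out_dir) -> dict[str, Path]:
        """Write the whole dataset as plain-text files; returns the paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        paths["genes"] = out / "genes.bed"
        write_gene_models(self.genes, paths["genes"])
        for mark, tracks in self.tracks.items():
            for t in tracks:
                key = f"track_{mark}_{t.sample_id}"
                paths[key] = out / f"{mark}_{t.sample_id}.bedgraph"
                write_bedgraph(t, paths[key])
        paths["input"] = out / "input.bedgraph"
        write_bedgraph(self.input_track, paths["input"])
        paths["expression"] = out / "expression.tsv"
        write_matrix(self.expression, paths["expression"])
        paths["methylation"] = out / "methylation.tsv"
        write_matrix(self.methylation, paths["methylation"])
        paths["groups"] = out / "groups.tsv"
        write_groups(self.groups, paths["groups"])
        paths["annotation"] = out / "annotation.tsv"
        with open(paths["annotation"], "w") as fh:
            fh.write("term_id\tgene_id\n")
            for term, gene in self.annotation:
                fh.write(f"{term}\t{gene}\n")
        paths["truth"] = out / "truth.tsv"
        self.truth.table.to_csv(paths["truth"], sep="\t",
                                float_format="%.10g", lineterminator="\n")
        paths["chrom_sizes"] = out / "chrom.sizes"
        with open(paths["chrom_sizes"], "w") as fh:
            for chrom, size in self.chrom_sizes.items():
                fh.write(f"{chrom}\t{size}\n")
        return paths


def _layout_genes(cfg: SyntheticConfig, rng: np.random.Generator
                  ) -> tuple[list[GeneModel], dict[str, int]]:
    margin = cfg.gene_spacing // 2
    if cfg.genome is None:
        length = 2 * margin + cfg.n_genes * cfg.gene_spacing
        genome = [("chr1", length)]
    else:
        genome = [(c, int(l)) for c, l in cfg.genome]
        capacity = sum(max(0, (l - 2 * margin) // cfg.gene_spacing)
                       for _, l in genome)
        if capacity < cfg.n_genes:
            raise ConfigError(
                f"genome too small: capacity {capacity} gene slot(s) for "
                f"{cfg.n_genes} genes at {cfg.gene_spacing} bp spacing"
            )
    lo, hi = cfg.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=cfg.n_genes)
    strands = rng.choice(np.array(["+", "-"]), size=cfg.n_genes)
    width = len(str(max(cfg.n_genes - 1, 1)))
    genes: list[GeneModel] = []
    chrom_iter = iter(genome)
    chrom, clen = next(chrom_iter)
    slot = 0
    slots_here = max(0, (clen - 2 * margin) // cfg.gene_spacing)
    for i in range(cfg.n_genes):
        while slot >= slots_here:
            chrom, clen = next(chrom_iter)
            slots_here = max(0, (clen - 2 * margin) // cfg.gene_spacing)
            slot = 0
        start = margin + slot * cfg.gene_spacing
        genes.append(GeneModel(f"g{i:0{width}d}", chrom, start,
                               start + int(lengths[i]), str(strands[i])))
        slot += 1
    sizes = dict(genome)
    return genes, sizes


def _nb_counts(rng: np.random.Generator, mu: np.ndarray,
               dispersion: float) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mu).astype(float)
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p).astype(float)


def _build_track(sample_id: str, group: str, genes, chrom_sizes, counts,
                 window: int, background: float) -> SignalTrack:
    """Counts spread uniformly over each promoter window on a flat background."""
    per_chrom: dict[str, list[tuple[int, int, float]]] = {c: [] for c in chrom_sizes}
    wins = []
    for g, c in zip(genes, counts):
        s = max(0, g.tss - window)
        e = min(chrom_sizes[g.chrom], g.tss + window)
        wins.append((g.chrom, s, e, float(c) / (e - s)))
    wins.sort(key=lambda w: (w[0], w[1]))
    cursor: dict[str, int] = {c: 0 for c in chrom_sizes}
    for chrom, s, e, dens in wins:
        pos = cursor[chrom]
        if s > pos and background > 0:
            per_chrom[chrom].append((pos, s, background))
        per_chrom[chrom].append((s, e, background + dens))
        cursor[chrom] = e
    for chrom, size in chrom_sizes.items():
        pos = cursor[chrom]
        if pos < size and background > 0:
            per_chrom[chrom].append((pos, size, background))
    chroms = {}
    for chrom, rows in per_chrom.items():
        if not rows:
            continue
        chroms[chrom] = (
            np.array([r[0] for r in rows], dtype=np.int64),
            np.array([r[1] for r in rows], dtype=np.int64),
            np.array([r[2] for r in rows], dtype=float),
        )
    return SignalTrack(sample_id, group, chroms)


def plant_expression(truth: GroundTruth, config: SyntheticConfig,
                     rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Realize the expression matrix from planted effects.

    ``true_expr_log2`` in ``truth`` is the planted group-mean LN-HN log2
    difference (coupling already applied); here baselines and replicate
    noise are drawn and the genes x samples log2 matrix returned.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    n = len(truth.table)
    reps = config.n_reps_per_group
    baselines = rng.normal(config.expr_baseline_mean, config.expr_baseline_sd, n)
    delta = truth.table["true_expr_log2"].to_numpy()
    samples = [f"LN_{i + 1}" for i in range(reps)] + \
              [f"HN_{i + 1}" for i in range(reps)]
    group_shift = np.concatenate([np.full(reps, 0.5), np.full(reps, -0.5)])
    values = (baselines[:, None] + delta[:, None] * group_shift[None, :]
              + rng.normal(0.0, config.expr_rep_sd, (n, 2 * reps)))
    return pd.DataFrame(values, index=truth.table.index.copy(), columns=samples)


def simulate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a complete dataset plus ground truth from ``config``.

    Deterministic: the seed fully determines every array and file byte.
    """
    rng = np.random.default_rng(config.seed)
    genes, chrom_sizes = _layout_genes(config, rng)
    n = config.n_genes
    gene_ids = [g.gene_id for g in genes]
    reps = config.n_reps_per_group
    samples = [f"LN_{i + 1}" for i in range(reps)] + \
              [f"HN_{i + 1}" for i in range(reps)]
    groups = {s: ("LN" if s.startswith("LN") else "HN") for s in samples}

    # planted, disjoint gene sets
    n_dhg = int(round(config.frac_dhg * n))
    n_dmg = int(round(config.frac_dmg * n))
    perm = rng.permutation(n)
    planted = {
        "H3K4me3": perm[:n_dhg],
        "H3K27me3": perm[n_dhg:2 * n_dhg],
        "CpG": perm[2 * n_dhg:2 * n_dhg + n_dmg],
    }
    truth_tbl = pd.DataFrame(index=pd.Index(gene_ids, name="gene_id"))
    mod_log2 = {}
    for mark in MARKS:
        signs = rng.choice(np.array([1.0, -1.0]), size=n_dhg)
        m = np.zeros(n)
        m[planted[mark]] = signs * config.effect_log2
        mod_log2[mark] = m
        truth_tbl[f"dhg_{mark}"] = False
        truth_tbl.iloc[planted[mark],
                       truth_tbl.columns.get_loc(f"dhg_{mark}")] = True
        truth_tbl[f"mod_log2_{mark}"] = m
    meth_signs = rng.choice(np.array([1.0, -1.0]), size=n_dmg)
    meth_delta = np.zeros(n)
    meth_delta[planted["CpG"]] = meth_signs * config.meth_effect_beta
    truth_tbl["dmg_CpG"] = False
    truth_tbl.iloc[planted["CpG"], truth_tbl.columns.get_loc("dmg_CpG")] = True
    truth_tbl["meth_delta"] = meth_delta

    # mark counts -> coverage tracks
    tracks: dict[str, list[SignalTrack]] = {}
    for mark in MARKS:
        base = np.exp(rng.normal(config.baseline_log_mean,
                                 config.baseline_log_sd, n))
        mean_ln = base * np.exp2(mod_log2[mark] / 2.0)
        mean_hn = base * np.exp2(-mod_log2[mark] / 2.0)
        mark_tracks = []
        for s in samples:
            mu = mean_ln if groups[s] == "LN" else mean_hn
            counts = _nb_counts(rng, mu, config.nb_dispersion)
            mark_tracks.append(_build_track(s, groups[s], genes, chrom_sizes,
                                            counts, config.window,
                                            config.background_density))
        tracks[mark] = mark_tracks
    input_track = SignalTrack(
        "input", "input",
        {c: (np.array([0]), np.array([size]),
             np.array([max(config.background_density, 1e-3)]))
         for c, size in chrom_sizes.items()},
    )

    # expression coupling
    noise = rng.normal(0.0, config.expr_noise_sd, n) \
        if config.expr_noise_sd > 0 else np.zeros(n)
    true_expr = (config.coupling_slope_activating * mod_log2["H3K4me3"]
                 + config.coupling_slope_repressive * mod_log2["H3K27me3"]
                 + config.meth_coupling_slope * meth_delta
                 + noise)
    truth_tbl["true_expr_log2"] = true_expr
    truth = GroundTruth(truth_tbl)
    expression = plant_expression(truth, config, rng)

    # methylation betas
    base_beta = rng.uniform(0.2, 0.8, n)
    meth = np.empty((n, 2 * reps))
    group_shift = np.concatenate([np.full(reps, 0.5), np.full(reps, -0.5)])
    meth_noise = rng.normal(0.0, config.meth_rep_sd, (n, 2 * reps))
    meth[:] = base_beta[:, None] + meth_delta[:, None] * group_shift[None, :] \
        + meth_noise
    methylation = pd.DataFrame(np.clip(meth, 0.0, 1.0),
                               index=pd.Index(gene_ids, name="gene_id"),
                               columns=samples)

    # annotation: random terms + a few enriched in the planted H3K4me3 set
    annotation: list[tuple[str, str]] = []
    dhg_ids = [gene_ids[i] for i in planted["H3K4me3"]]
    other_ids = [g for g in gene_ids if g not in set(dhg_ids)]
    size = min(config.term_size, n)
    for t in range(config.n_terms):
        term = f"T{t:02d}"
        if t < config.n_enriched_terms and dhg_ids:
            n_in = min(int(round(config.enriched_frac * size)), len(dhg_ids))
            members = list(rng.choice(dhg_ids, size=n_in, replace=False))
            members += list(rng.choice(other_ids, size=size - n_in,
                                       replace=False))
        else:
            members = list(rng.choice(gene_ids, size=size, replace=False))
        annotation.extend((term, g) for g in sorted(members))

    return SyntheticDataset(
        config=config, genes=genes, chrom_sizes=chrom_sizes, tracks=tracks,
        input_track=input_track, expression=expression,
        methylation=methylation, annotation=annotation, groups=groups,
        truth=truth,
    )
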