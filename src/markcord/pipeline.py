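"""End-to-end orchestration: simulate -> quantify -> profile -> diff ->
cluster -> concordance -> enrichment, from one structured config.

Every threshold the analysis uses is surfaced in :class:`RunConfig`
(``alpha_dhr`` 0.05 for regions, ``alpha_dhg`` 0.01 for clustering,
``alpha_expr`` 0.05 / ``trend`` 0.10 for expression, ``K`` 20, ``fc`` 1.5,
promoter half-width ``window`` 1000, TSS-adjacency ``adjacency`` 1000,
metagene flanks 3000). A run writes all stage outputs plus ``manifest.json``
recording the config hash, input hashes and filter counts; re-running an
unchanged config reproduces every byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .concordance import ConcordanceAnalysis
from .diffmark import classify_dhg, cluster_dhg, diff_test
from .enrichment import enrich, validate_annotation
from .iolib import (
    read_bedgraph,
    read_gene_models,
    read_groups,
    read_matrix,
    write_matrix,
)
from .promoter_quant import metagene, promoter_windows, quantify_samples
from .synthio import MARKS, SyntheticConfig, simulate_dataset

__all__ = ["RunConfig", "PipelineError", "run_all"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: str):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    simulate: bool = True
    synthetic: dict[str, Any] = field(default_factory=dict)
    # external inputs (used when simulate is False)
    genes_path: str | None = None
    track_manifest: str | None = None  # TSV: sample_id  group  mark  path
    expression_path: str | None = None
    methylation_path: str | None = None
    annotation_path: str | None = None
    groups_path: str | None = None
    # thresholds
    alpha_dhr: float = 0.05
    alpha_dhg: float = 0.01
    alpha_expr: float = 0.05
    trend: float = 0.10
    top_k: int = 20
    fc: float = 1.5
    window: int = 1000
    adjacency: int = 1000
    flank: int = 3000
    body_bins: int = 60
    flank_bin: int = 100
    pseudocount: float = 1.0
    meth_pseudocount: float = 0.01
    # stage toggles
    stages: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("alpha_dhr", "alpha_dhg", "alpha_expr", "trend"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        for name in ("window", "adjacency", "flank", "top_k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        defaults = {"profile": True, "diff": True, "cluster": True,
                    "concord": True, "enrich": True}
        defaults.update(self.stages)
        self.stages = defaults

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def canonical(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(cfg: RunConfig, stage: str, needed: str) -> None:
    if not cfg.stages.get(needed, True):
        raise PipelineError(
            stage, f"requires output of stage {needed!r}, which is toggled off"
        )


def _load_inputs(cfg: RunConfig, data_dir: Path):
    """Return (genes, chrom_sizes, tracks-by-mark, input_track, expression,
    methylation, annotation pairs, groups) either simulated or from paths."""
    if cfg.simulate:
        synth = SyntheticConfig(seed=cfg.seed, **cfg.synthetic)
        ds = simulate_dataset(synth)
        ds.write(data_dir)
        ann = validate_annotation(ds.annotation)
        return (ds.genes, ds.chrom_sizes, ds.tracks, ds.input_track,
                ds.expression, ds.methylation, ann, ds.groups)
    for name in ("genes_path", "track_manifest", "expression_path",
                 "groups_path"):
        if getattr(cfg, name) is None:
            raise PipelineError("inputs", f"simulate is off and {name} not set")
    genes = read_gene_models(cfg.genes_path)
    groups = read_groups(cfg.groups_path)
    tracks: dict[str, list] = {}
    input_track = None
    manifest = pd.read_csv(cfg.track_manifest, sep="\t")
    for row in manifest.itertuples():
        t = read_bedgraph(row.path, row.sample_id, row.group)
        if row.group == "input":
            input_track = t
        else:
            tracks.setdefault(row.mark, []).append(t)
    expr = read_matrix(cfg.expression_path)
    meth = read_matrix(cfg.methylation_path) if cfg.methylation_path else None
    ann = (validate_annotation(cfg.annotation_path)
           if cfg.annotation_path else None)
    return genes, None, tracks, input_track, expr, meth, ann, groups


def run_all(cfg: RunConfig) -> dict[str, Any]:
    """Run every enabled stage; returns the manifest (also written to
    ``<out_dir>/manifest.json``)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data_dir = out / "data"
    manifest: dict[str, Any] = {
        "version": __version__,
        "config_hash": hashlib.sha256(cfg.canonical().encode()).hexdigest(),
        "config": json.loads(cfg.canonical()),
        "counts": {},
        "outputs": {},
    }
    try:
        (genes, chrom_sizes, tracks, input_track, expr, meth, ann,
         groups) = _load_inputs(cfg, data_dir)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - abort with stage name
        raise PipelineError("inputs", str(exc)) from exc

    windows = promoter_windows(genes, window=cfg.window,
                               chrom_sizes=chrom_sizes)
    diff_tables: dict[str, pd.DataFrame] = {}
    counts = manifest["counts"]

    for mark, mark_tracks in tracks.items():
        try:
            matrix = quantify_samples(mark_tracks, windows)
        except Exception as exc:
            raise PipelineError("quantify", f"{mark}: {exc}") from exc
        write_matrix(matrix, out / f"markmatrix_{mark}.tsv")
        if cfg.stages["profile"]:
            prof = metagene(mark_tracks, genes, upstream=cfg.flank,
                            downstream=cfg.flank, body_bins=cfg.body_bins,
                            flank_bin=cfg.flank_bin, input_track=input_track)
            prof.to_csv(out / f"profile_{mark}.tsv", sep="\t",
                        float_format="%.10g", lineterminator="\n")
        if cfg.stages["diff"]:
            res = diff_test(matrix, groups, alpha=cfg.alpha_dhr,
                            pseudocount=cfg.pseudocount)
            res.to_csv(out / f"diff_{mark}.tsv", sep="\t",
                       float_format="%.10g", lineterminator="\n")
            diff_tables[mark] = res
            hyper, hypo = classify_dhg(res, cfg.alpha_dhr)
            n_ns = len(res) - len(hyper) - len(hypo)
            assert len(hyper) + len(hypo) + n_ns == len(res)
            counts[mark] = {
                "regions_tested": len(res),
                "dhr_up": len(hyper),
                "dhr_down": len(hypo),
                "ns": n_ns,
            }
            hyp2, hyp2o = classify_dhg(res, cfg.alpha_dhg)
            counts[mark]["dhg_hyper"] = len(hyp2)
            counts[mark]["dhg_hypo"] = len(hyp2o)
            if cfg.stages["cluster"]:
                try:
                    clust = cluster_dhg(matrix, res, alpha=cfg.alpha_dhg,
                                        pseudocount=cfg.pseudocount)
                    cl = {
                        "gene_order": clust.gene_ids,
                        "sample_order": clust.sample_ids,
                        "sample_partition": clust.sample_partition,
                        "gene_linkage": clust.gene_linkage.tolist(),
                        "sample_linkage": clust.sample_linkage.tolist(),
                    }
                    with open(out / f"cluster_{mark}.json", "w") as fh:
                        json.dump(cl, fh, sort_keys=True, indent=1)
                except ValueError as exc:
                    logger.warning("cluster %s skipped: %s", mark, exc)

    if meth is not None and cfg.stages["diff"]:
        res = diff_test(meth, groups, alpha=cfg.alpha_dhr,
                        pseudocount=cfg.meth_pseudocount)
        res.to_csv(out / "diff_CpG.tsv", sep="\t", float_format="%.10g",
                   lineterminator="\n")
        diff_tables["CpG"] = res
        counts["CpG"] = {"regions_tested": len(res)}

    if cfg.stages["concord"]:
        _require(cfg, "concord", "diff")
        if not diff_tables:
            raise PipelineError("concord", "no differential tables produced")
        model = ConcordanceAnalysis(expr, groups, diff_tables)
        cres = model.fit(k=cfg.top_k, alpha=cfg.alpha_expr, trend=cfg.trend,
                         fc=cfg.fc)
        cres.records_frame().to_csv(out / "concord_records.tsv", sep="\t",
                                    index=False, float_format="%.10g",
                                    lineterminator="\n")
        cres.ranking.to_csv(out / "concord_ranking.tsv", sep="\t",
                            float_format="%.10g", lineterminator="\n")
        with open(out / "concord_ranking.json", "w") as fh:
            json.dump(json.loads(cres.ranking.to_json(orient="index")), fh,
                      sort_keys=True, indent=1)
        for s in cres.summaries:
            counts.setdefault(s.modifier, {}).update({
                "K_used": s.k,
                "n_significant": s.n_significant,
                "n_consistent": s.n_consistent,
                "n_high_fc_consistent": s.n_high_fc_consistent,
            })

    if cfg.stages["enrich"] and ann is not None:
        _require(cfg, "enrich", "diff")
        mark0 = MARKS[0] if MARKS[0] in diff_tables else next(iter(diff_tables))
        hyper, hypo = classify_dhg(diff_tables[mark0], cfg.alpha_dhr)
        gene_list = sorted(set(hyper) | set(hypo))
        if gene_list:
            try:
                etab = enrich(gene_list, ann, alpha=cfg.alpha_dhr)
                etab.to_csv(out / "enrich.tsv", sep="\t", index=False,
                            float_format="%.10g", lineterminator="\n")
                counts["enrich"] = {
                    "list_size": len(gene_list),
                    "terms_tested": len(etab),
                    "terms_significant": int(etab["significant"].sum()),
                }
            except Exception as exc:
                raise PipelineError("enrich", str(exc)) from exc

    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][str(p.relative_to(out))] = _sha256(p)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)
        fh.write("\n")
    return manifest
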