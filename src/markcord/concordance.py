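"""Epigenome-transcriptome concordance scoring.

For each epigenetic modifier (promoter H3K4me3, H3K27me3, CpG methylation)
the procedure takes the top-K most differentially modified genes (smallest
p, ties by |log2 ratio| then id; genes absent from the expression matrix are
skipped and the next rank promoted), classifies each against the expression
change under the modifier's polarity — H3K4me3 activating, H3K27me3 and CpG
methylation repressive — and rolls the calls up per modifier:

* ``consistent``: expression significantly altered (p < 0.05, Welch) *and*
  shifted in the direction the modification predicts (same sign for an
  activating mark, opposite for a repressive one). Trend-level genes
  (p < 0.10) are recorded but never count as consistent.
* ``high_fc``: |linear expression fold change| >= 1.5, i.e.
  |log2 ratio| >= log2(1.5).
* per-modifier OLS of expression log2 ratio on modification log2 ratio over
  the consistent genes (free intercept), with R^2 reported when at least 3
  consistent genes exist and the response has spread.

Modifiers are ranked by (n_high_fc_consistent, n_consistent, R^2).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .diffmark import _split_groups, _welch_from_arrays

__all__ = [
    "ModifierSpec",
    "DEFAULT_MODIFIERS",
    "ConcordanceRecord",
    "ConcordanceSummary",
    "select_top",
    "classify_concordance",
    "summarize_records",
    "compare_modifiers",
    "expression_diff",
    "ConcordanceAnalysis",
    "ConcordanceResults",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModifierSpec:
    """An epigenetic modifier and the expression polarity it predicts."""

    name: str
    polarity: str  # "activating" | "repressive"

    def __post_init__(self) -> None:
        if self.polarity not in ("activating", "repressive"):
            raise ValueError(f"polarity must be activating/repressive, "
                             f"got {self.polarity!r}")


DEFAULT_MODIFIERS: dict[str, ModifierSpec] = {
    "H3K4me3": ModifierSpec("H3K4me3", "activating"),
    "H3K27me3": ModifierSpec("H3K27me3", "repressive"),
    "CpG": ModifierSpec("CpG", "repressive"),
}


@dataclass(frozen=True)
class ConcordanceRecord:
    gene_id: str
    modifier: str
    mod_log2_ratio: float
    expr_log2_ratio: float
    expr_p: float
    significant: bool      # expr_p < alpha
    trend: bool            # expr_p < trend threshold
    consistent: bool       # significant and direction matches polarity
    high_fc: bool          # |expr linear FC| >= fc threshold


@dataclass
class ConcordanceSummary:
    modifier: str
    k: int
    n_significant: int
    n_consistent: int
    n_high_fc_consistent: int
    r_squared: float | None
    slope: float | None
    intercept: float | None
    degenerate: bool = False  # regression response had zero spread


def select_top(diff: pd.DataFrame, k: int = 20,
               eligible: Iterable[str] | None = None,
               gene_ids: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Top-``k`` genes by differential-modification p-value.

    ``diff`` is a diff_test-style table indexed by region id with columns
    ``p_value`` and ``log2_ratio``. When several regions (e.g. CpG sites)
    map to one gene, supply ``gene_ids`` (region -> gene) and the gene is
    represented by its best (smallest-p) site. Genes not in ``eligible``
    (typically: present in the expression matrix) are skipped and the next
    rank promoted. Ties in p break by |log2_ratio| descending, then gene id.
    """
    if diff.empty:
        raise ValueError("empty differential table")
    d = diff[["p_value", "log2_ratio"]].reset_index(names="region_id")
    d["gene_id"] = (
        [gene_ids[r] for r in d["region_id"]] if gene_ids is not None
        else d["region_id"]
    )
    d["abs_lr"] = d["log2_ratio"].abs()
    d = d.sort_values(["p_value", "abs_lr", "gene_id"],
                      ascending=[True, False, True], kind="mergesort")
    # best site per gene = first occurrence in this ordering
    d = d.drop_duplicates("gene_id", keep="first")
    if eligible is not None:
        eligible = set(eligible)
        n0 = len(d)
        d = d[d["gene_id"].isin(eligible)]
        if len(d) < n0:
            logger.info("select_top: skipped %d gene(s) absent from the "
                        "expression matrix", n0 - len(d))
    out = d.head(k)[["region_id", "gene_id", "p_value", "log2_ratio"]]
    out = out.reset_index(drop=True)
    if len(out) < k:
        logger.warning("select_top: only %d eligible gene(s) for K=%d",
                       len(out), k)
    return out


def classify_concordance(gene_id: str, modifier: ModifierSpec,
                         mod_log2: float, expr_log2: float, expr_p: float,
                         alpha: float = 0.05, trend: float = 0.10,
                         fc: float = 1.5) -> ConcordanceRecord:
    """Classify one gene's expression change against its modification change."""
    significant = expr_p < alpha
    trending = expr_p < trend
    if expr_log2 == 0 or mod_log2 == 0:
        direction_ok = False
    elif modifier.polarity == "activating":
        direction_ok = math.copysign(1, expr_log2) == math.copysign(1, mod_log2)
    else:
        direction_ok = math.copysign(1, expr_log2) == -math.copysign(1, mod_log2)
    return ConcordanceRecord(
        gene_id=gene_id,
        modifier=modifier.name,
        mod_log2_ratio=mod_log2,
        expr_log2_ratio=expr_log2,
        expr_p=expr_p,
        significant=significant,
        trend=trending,
        consistent=significant and direction_ok,
        high_fc=abs(expr_log2) >= math.log2(fc),
    )


def summarize_records(records: Sequence[ConcordanceRecord],
                      modifier: str | None = None) -> ConcordanceSummary:
    """Roll up one modifier's records; OLS over the consistent genes."""
    if modifier is None:
        modifier = records[0].modifier if records else "?"
    cons = [r for r in records if r.consistent]
    n_sig = sum(r.significant for r in records)
    n_hf = sum(r.consistent and r.high_fc for r in records)
    slope = intercept = r2 = None
    degenerate = False
    if len(cons) >= 3:
        x = np.array([r.mod_log2_ratio for r in cons])
        y = np.array([r.expr_log2_ratio for r in cons])
        sstot = float(np.sum((y - y.mean()) ** 2))
        if sstot == 0 or np.ptp(x) == 0:
            degenerate = True
        else:
            slope_, intercept_ = np.polyfit(x, y, 1)
            resid = y - (slope_ * x + intercept_)
            r2 = 1.0 - float(np.sum(resid**2)) / sstot
            slope, intercept = float(slope_), float(intercept_)
    return ConcordanceSummary(
        modifier=modifier, k=len(records), n_significant=n_sig,
        n_consistent=len(cons), n_high_fc_consistent=n_hf,
        r_squared=r2, slope=slope, intercept=intercept, degenerate=degenerate,
    )


def compare_modifiers(summaries: Sequence[ConcordanceSummary]) -> pd.DataFrame:
    """Rank modifiers by (n_high_fc_consistent, n_consistent, R^2), all
    descending; stable for exact ties."""
    def key(s: ConcordanceSummary):
        r2 = s.r_squared if s.r_squared is not None else -math.inf
        return (-s.n_high_fc_consistent, -s.n_consistent, -r2)

    ranked = sorted(summaries, key=key)  # stable
    return pd.DataFrame(
        {
            "modifier": [s.modifier for s in ranked],
            "K": [s.k for s in ranked],
            "n_significant": [s.n_significant for s in ranked],
            "n_consistent": [s.n_consistent for s in ranked],
            "n_high_fc_consistent": [s.n_high_fc_consistent for s in ranked],
            "r_squared": [s.r_squared for s in ranked],
            "slope": [s.slope for s in ranked],
        },
        index=pd.RangeIndex(1, len(ranked) + 1, name="rank"),
    )


def _ratio_log2(table: pd.DataFrame, region_id) -> float:
    """log2 of the linear ratio of group means; NaN/inf when undefined.

    Falls back to the pseudocounted ``log2_ratio`` for tables that carry no
    ``ln_hn_ratio`` column.
    """
    if "ln_hn_ratio" not in table.columns:
        return float(table.at[region_id, "log2_ratio"])
    r = float(table.at[region_id, "ln_hn_ratio"])
    if not math.isfinite(r) or r <= 0:
        return math.nan
    return math.log2(r)


def expression_diff(expr: pd.DataFrame, groups: Mapping[str, str],
                    group_a: str = "LN", group_b: str = "HN",
                    alternative: str = "two-sided") -> pd.DataFrame:
    """Per-gene Welch test on an already-log2 expression matrix.

    Returns columns ``expr_log2_ratio`` (mean difference on the log2 scale)
    and ``expr_p``. ``alternative`` may be one-sided (``"greater"``/``"less"``
    with respect to ``group_a`` minus ``group_b``) for qPCR-style follow-ups.
    """
    cols_a, cols_b = _split_groups(expr, groups, group_a, group_b)
    xa = expr[cols_a].to_numpy(dtype=float)
    xb = expr[cols_b].to_numpy(dtype=float)
    keep = ~(np.isnan(xa).any(axis=1) | np.isnan(xb).any(axis=1))
    if not keep.all():
        logger.info("expression_diff: dropping %d gene(s) with missing values",
                    int((~keep).sum()))
    xa, xb = xa[keep], xb[keep]
    t, p = _welch_from_arrays(xa, xb)
    if alternative == "greater":
        p = np.where(t > 0, p / 2.0, 1.0 - p / 2.0)
    elif alternative == "less":
        p = np.where(t < 0, p / 2.0, 1.0 - p / 2.0)
    elif alternative != "two-sided":
        raise ValueError(f"unknown alternative {alternative!r}")
    return pd.DataFrame(
        {"expr_log2_ratio": xa.mean(axis=1) - xb.mean(axis=1), "expr_p": p},
        index=expr.index[keep],
    )


class ConcordanceAnalysis:
    """Concordance model over one expression matrix and >= 1 modifiers.

    Parameters
    ----------
    expr
        Gene x sample expression matrix, log2 scale.
    groups
        Sample -> group mapping covering the expression columns.
    diff_tables
        Mapping modifier name -> diff_test-style table (``p_value``,
        ``log2_ratio`` indexed by region/gene id).
    specs
        Modifier polarity overrides; defaults to :data:`DEFAULT_MODIFIERS`
        (unknown names must be supplied here).
    gene_ids
        Optional per-modifier region -> gene mapping (CpG site tables).
    """

    def __init__(self, expr: pd.DataFrame, groups: Mapping[str, str],
                 diff_tables: Mapping[str, pd.DataFrame],
                 specs: Mapping[str, ModifierSpec] | None = None,
                 gene_ids: Mapping[str, Mapping[str, str]] | None = None,
                 group_a: str = "LN", group_b: str = "HN"):
        self.expr = expr
        self.groups = dict(groups)
        self.diff_tables = dict(diff_tables)
        self.specs = dict(DEFAULT_MODIFIERS)
        if specs:
            self.specs.update(specs)
        for name in self.diff_tables:
            if name not in self.specs:
                raise ValueError(f"no ModifierSpec for modifier {name!r}")
        self.gene_ids = dict(gene_ids) if gene_ids else {}
        self.group_a, self.group_b = group_a, group_b

    def fit(self, k: int = 20, alpha: float = 0.05, trend: float = 0.10,
            fc: float = 1.5) -> "ConcordanceResults":
        ediff = expression_diff(self.expr, self.groups,
                                self.group_a, self.group_b)
        records: dict[str, list[ConcordanceRecord]] = {}
        summaries: list[ConcordanceSummary] = []
        excluded: dict[str, int] = {}
        for name, table in self.diff_tables.items():
            spec = self.specs[name]
            top = select_top(table, k=k, eligible=ediff.index,
                             gene_ids=self.gene_ids.get(name))
            recs = []
            n_undef = 0
            for row in top.itertuples():
                # x axis is log2 of the linear LN/HN ratio (the scale the
                # concordance indices are defined on); genes with an
                # undefined ratio (zero group mean) are excluded and counted
                mod_log2 = _ratio_log2(table, row.region_id)
                if not math.isfinite(mod_log2):
                    n_undef += 1
                    continue
                recs.append(classify_concordance(
                    row.gene_id, spec, mod_log2,
                    float(ediff.at[row.gene_id, "expr_log2_ratio"]),
                    float(ediff.at[row.gene_id, "expr_p"]),
                    alpha=alpha, trend=trend, fc=fc,
                ))
            if n_undef:
                logger.warning("%s: %d top gene(s) with undefined LN/HN "
                               "ratio excluded", name, n_undef)
            excluded[name] = n_undef
            records[name] = recs
            summaries.append(summarize_records(recs, modifier=name))
        return ConcordanceResults(self, records, summaries, ediff,
                                  k=k, alpha=alpha, trend=trend, fc=fc,
                                  excluded=excluded)


class ConcordanceResults:
    def __init__(self, model, records, summaries, expression_table,
                 k, alpha, trend, fc, excluded=None):
        self.excluded_undefined_ratio = excluded or {}
        self.model = model
        self.records: dict[str, list[ConcordanceRecord]] = records
        self.summaries: list[ConcordanceSummary] = summaries
        self.expression_table = expression_table
        self.k, self.alpha, self.trend, self.fc = k, alpha, trend, fc

    @property
    def ranking(self) -> pd.DataFrame:
        return compare_modifiers(self.summaries)

    def records_frame(self) -> pd.DataFrame:
        rows = [r for recs in self.records.values() for r in recs]
        return pd.DataFrame([vars(r) for r in rows])

    def summary(self) -> str:
        lines = [
            f"Concordance of epigenetic modification with expression change "
            f"(top K={self.k}, expr alpha={self.alpha:g}, FC>={self.fc:g})",
            "",
            self.ranking.to_string(
                float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)
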