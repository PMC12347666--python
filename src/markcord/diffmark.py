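"""Differential modification between two replicate groups.

Per region, replicate levels are transformed ``x -> log2(x + c)`` (pseudocount
``c`` = 1 on the 1e7-scaled levels) and compared with a two-sided Welch t-test.
No multiple-testing correction is applied by default — DHR/DHG calls use raw
p thresholds (p < 0.05 regions, p < 0.01 for clustering), a deliberate
faithful-reproduction choice; Benjamini-Hochberg adjustment is available via
``adjust="bh"``.

The linear LN/HN ratio is computed from untransformed group means; the
``log2_ratio`` effect size is log2 of the pseudocounted ratio of group
means, so it is finite even when one group mean is zero and always agrees
in sign with the linear ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "diff_test",
    "classify_dhg",
    "cluster_dhg",
    "ClusteringResult",
    "group_ratio",
    "welch_p",
    "DifferentialMark",
    "DifferentialMarkResults",
]

logger = logging.getLogger(__name__)

_P_FLOOR = float(np.finfo(float).tiny)  # placeholder for zero-variance, unequal means


def _split_groups(matrix: pd.DataFrame, groups: Mapping[str, str],
                  group_a: str, group_b: str) -> tuple[list[str], list[str]]:
    a = [s for s in matrix.columns if groups.get(s) == group_a]
    b = [s for s in matrix.columns if groups.get(s) == group_b]
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"need >= 2 replicates per group; got {len(a)} {group_a!r} "
            f"and {len(b)} {group_b!r}"
        )
    return a, b


def _welch_from_arrays(xa: np.ndarray, xb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-sided Welch t-test across rows. Returns (t, p)."""
    na, nb = xa.shape[1], xb.shape[1]
    ma, mb = xa.mean(axis=1), xb.mean(axis=1)
    va, vb = xa.var(axis=1, ddof=1), xb.var(axis=1, ddof=1)
    se2 = va / na + vb / nb
    diff = ma - mb
    both_zero = se2 == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    # degenerate rows: both group variances zero
    p = np.where(both_zero & (diff == 0), 1.0, p)
    deg = both_zero & (diff != 0)
    if deg.any():
        logger.warning("%d region(s) with zero within-group variance but unequal "
                       "means; p set to machine-min placeholder", int(deg.sum()))
        p = np.where(deg, _P_FLOOR, p)
        t = np.where(deg, np.sign(diff) * np.inf, t)
    return t, p


def diff_test(
    matrix: pd.DataFrame,
    groups: Mapping[str, str],
    alpha: float = 0.05,
    pseudocount: float = 1.0,
    group_a: str = "LN",
    group_b: str = "HN",
    adjust: str | None = None,
) -> pd.DataFrame:
    """Per-region differential test of ``group_a`` vs ``group_b`` levels.

    Returns a DataFrame indexed by region id with columns ``mean_LN``,
    ``mean_HN`` (untransformed group means, named after the actual group
    labels), ``ln_hn_ratio`` (linear ratio of untransformed means; ``inf``
    when the denominator group mean is 0 and the numerator positive; 1.0 when
    both are 0), ``log2_ratio``, ``p_value``, optionally ``p_adj``, and
    ``direction`` in {``up``, ``down``, ``ns``} at the given ``alpha``
    (applied to adjusted p when ``adjust`` is set).
    """
    cols_a, cols_b = _split_groups(matrix, groups, group_a, group_b)
    xa_raw = matrix[cols_a].to_numpy(dtype=float)
    xb_raw = matrix[cols_b].to_numpy(dtype=float)
    if np.isnan(xa_raw).any() or np.isnan(xb_raw).any():
        keep = ~(np.isnan(xa_raw).any(axis=1) | np.isnan(xb_raw).any(axis=1))
        logger.info("dropping %d region(s) with missing values",
                    int((~keep).sum()))
        matrix = matrix.loc[keep]
        xa_raw, xb_raw = xa_raw[keep], xb_raw[keep]
    xa = np.log2(xa_raw + pseudocount)
    xb = np.log2(xb_raw + pseudocount)
    t, p = _welch_from_arrays(xa, xb)
    mean_a, mean_b = xa_raw.mean(axis=1), xb_raw.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = mean_a / mean_b
    ratio = np.where((mean_b == 0) & (mean_a == 0), 1.0, ratio)
    ratio = np.where((mean_b == 0) & (mean_a > 0), np.inf, ratio)
    # log2 effect on the pseudocounted mean ratio: finite even when a group
    # mean is 0, and sign-consistent with the linear ratio by construction
    log2_ratio = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
    out = pd.DataFrame(
        {
            f"mean_{group_a}": mean_a,
            f"mean_{group_b}": mean_b,
            "ln_hn_ratio": ratio,
            "log2_ratio": log2_ratio,
            "p_value": p,
        },
        index=matrix.index.copy(),
    )
    p_eff = out["p_value"]
    if adjust is not None:
        if adjust != "bh":
            raise ValueError(f"unknown adjustment {adjust!r}")
        from statsmodels.stats.multitest import multipletests

        out["p_adj"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
        p_eff = out["p_adj"]
    sig = p_eff < alpha
    out["direction"] = np.where(~sig, "ns", np.where(log2_ratio > 0, "up", "down"))
    out.attrs["groups"] = dict(groups)
    out.attrs["alpha"] = alpha
    out.attrs["group_labels"] = (group_a, group_b)
    return out


def classify_dhg(results: pd.DataFrame, alpha: float = 0.05,
                 use_adjusted: bool = False) -> tuple[list[str], list[str]]:
    """Partition significant regions into (hyper, hypo) lists by the sign of
    the log2 ratio (hyper = higher in the first group)."""
    p = results["p_adj" if use_adjusted else "p_value"]
    sig = results[p < alpha]
    hyper = sig.index[sig["log2_ratio"] > 0].tolist()
    hypo = sig.index[sig["log2_ratio"] < 0].tolist()
    logger.info("classify_dhg: %d hyper, %d hypo at alpha=%g",
                len(hyper), len(hypo), alpha)
    return hyper, hypo


@dataclass
class ClusteringResult:
    """Average-linkage HCA of DHGs (genes) and samples."""

    gene_ids: list[str]          # leaf order
    sample_ids: list[str]        # leaf order
    gene_linkage: np.ndarray
    sample_linkage: np.ndarray
    sample_partition: dict[str, int]   # k=2 cut of the sample dendrogram


def _corr_dist(x: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between rows; rows with zero variance get
    distance 1 to everything (logged)."""
    sd = x.std(axis=1, ddof=0)
    flat = sd == 0
    if flat.any():
        logger.warning("%d zero-variance row(s) in clustering; their correlation "
                       "distance is defined as 1", int(flat.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(x)
    d = 1.0 - c
    d[flat, :] = 1.0
    d[:, flat] = 1.0
    np.fill_diagonal(d, 0.0)
    # numerical guard: squareform requires exact symmetry
    d = (d + d.T) / 2.0
    return np.clip(d, 0.0, 2.0)


def cluster_dhg(matrix: pd.DataFrame, results: pd.DataFrame,
                alpha: float = 0.01, pseudocount: float = 1.0) -> ClusteringResult:
    """Hierarchical clustering of regions significant at ``alpha``.

    Distance is 1 - Pearson correlation (across samples for genes, across
    genes for samples); average linkage; regions sorted lexically first so
    linkage tie-breaking is deterministic.
    """
    dhg = sorted(results.index[results["p_value"] < alpha])
    if len(dhg) < 2:
        raise ValueError(f"need >= 2 regions at p < {alpha}, got {len(dhg)}")
    sub = np.log2(matrix.loc[dhg].to_numpy(dtype=float) + pseudocount)
    samples = list(matrix.columns)
    gene_link = hierarchy.linkage(squareform(_corr_dist(sub), checks=False),
                                  method="average")
    sample_link = hierarchy.linkage(squareform(_corr_dist(sub.T), checks=False),
                                    method="average")
    gene_order = hierarchy.leaves_list(gene_link)
    sample_order = hierarchy.leaves_list(sample_link)
    cut = hierarchy.fcluster(sample_link, t=2, criterion="maxclust")
    return ClusteringResult(
        gene_ids=[dhg[i] for i in gene_order],
        sample_ids=[samples[i] for i in sample_order],
        gene_linkage=gene_link,
        sample_linkage=sample_link,
        sample_partition={s: int(c) for s, c in zip(samples, cut)},
    )


def group_ratio(mean_a: float, mean_b: float) -> float:
    """Linear ratio a/b rounded half-up to 2 decimals (report convention)."""
    if mean_b == 0:
        raise ZeroDivisionError("denominator group mean is zero")
    q = Decimal(str(mean_a)) / Decimal(str(mean_b))
    return float(q.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def welch_p(mean_a: float, se_a: float, n_a: int,
            mean_b: float, se_b: float, n_b: int,
            alternative: str = "two-sided") -> float:
    """Welch t-test p-value from summary statistics (group mean, SE of the
    mean, n) via the Welch-Satterthwaite degrees of freedom."""
    se2 = se_a**2 + se_b**2
    if se2 == 0:
        return 1.0 if mean_a == mean_b else _P_FLOOR
    t = (mean_a - mean_b) / np.sqrt(se2)
    df = se2**2 / (se_a**4 / (n_a - 1) + se_b**4 / (n_b - 1))
    if alternative == "two-sided":
        return float(2.0 * stats.t.sf(abs(t), df))
    if alternative == "greater":
        return float(stats.t.sf(t, df))
    if alternative == "less":
        return float(stats.t.cdf(t, df))
    raise ValueError(f"unknown alternative {alternative!r}")


class DifferentialMark:
    """Differential-modification model for one mark.

    Parameters
    ----------
    matrix
        Gene x sample matrix of normalized promoter levels (a MarkMatrix).
    groups
        Mapping sample_id -> group label.
    mark
        Optional mark name carried into results.
    """

    def __init__(self, matrix: pd.DataFrame, groups: Mapping[str, str],
                 mark: str | None = None, group_a: str = "LN",
                 group_b: str = "HN"):
        self.matrix = matrix
        self.groups = dict(groups)
        self.mark = mark
        self.group_a = group_a
        self.group_b = group_b
        _split_groups(matrix, groups, group_a, group_b)  # validate early

    @classmethod
    def from_tracks(cls, tracks, windows, groups=None, mark=None, **kw):
        from .promoter_quant import quantify_samples

        matrix = quantify_samples(tracks, windows)
        groups = groups or {t.sample_id: t.group for t in tracks}
        return cls(matrix, groups, mark=mark, **kw)

    def fit(self, alpha: float = 0.05, pseudocount: float = 1.0,
            adjust: str | None = None) -> "DifferentialMarkResults":
        table = diff_test(self.matrix, self.groups, alpha=alpha,
                          pseudocount=pseudocount, group_a=self.group_a,
                          group_b=self.group_b, adjust=adjust)
        return DifferentialMarkResults(self, table, alpha=alpha,
                                       pseudocount=pseudocount)


class DifferentialMarkResults:
    """Results of :meth:`DifferentialMark.fit`; the per-region table is in
    ``.table``."""

    def __init__(self, model: DifferentialMark, table: pd.DataFrame,
                 alpha: float, pseudocount: float):
        self.model = model
        self.table = table
        self.alpha = alpha
        self.pseudocount = pseudocount

    def classify(self, alpha: float | None = None) -> tuple[list[str], list[str]]:
        return classify_dhg(self.table, alpha if alpha is not None else self.alpha)

    def cluster(self, alpha: float = 0.01) -> ClusteringResult:
        return cluster_dhg(self.model.matrix, self.table, alpha=alpha,
                           pseudocount=self.pseudocount)

    def summary(self) -> str:
        t = self.table
        hyper, hypo = self.classify()
        lines = [
            f"Differential modification ({self.model.mark or 'mark'}): "
            f"{self.model.group_a} vs {self.model.group_b}",
            f"regions tested: {len(t)}",
            f"significant at p<{self.alpha:g}: {len(hyper)} up, {len(hypo)} down, "
            f"{len(t) - len(hyper) - len(hypo)} ns",
            "",
            t.sort_values("p_value").head(10).to_string(
                float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)
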