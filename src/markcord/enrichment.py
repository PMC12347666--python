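"""Hypergeometric term enrichment of a gene list against an annotation table.

The background is the set of genes annotated with at least one term in the
user-supplied table (the convention of desktop annotation tools), not the
full gene universe. For a term with ``K_term`` background genes, a list of
``n`` background genes containing ``k`` of them gets the upper-tail
hypergeometric p-value

    p = sum_{i=k..min(n, K_term)} C(K_term, i) C(N - K_term, n - i) / C(N, n)

and fold enrichment FE = (k/n) / (K_term/N). No multiple-testing correction
by default (raw p < alpha extraction); Benjamini-Hochberg and the
EASE-score variant (k replaced by k-1 in the tail) are available as flags.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .iolib import ParseError, ValidationError

__all__ = ["AnnotationTable", "validate_annotation", "enrich"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnnotationTable:
    """term_id -> member genes, plus the annotated background."""

    terms: dict[str, frozenset[str]]
    background: frozenset[str]

    def __post_init__(self) -> None:
        for term, members in self.terms.items():
            if not members:
                raise ValidationError(f"term {term!r} has no member genes")
            if not members <= self.background:
                raise ValidationError(f"term {term!r} lists genes outside the "
                                      "background")


def validate_annotation(source) -> AnnotationTable:
    """Build an :class:`AnnotationTable` from a 2-column term_id<TAB>gene_id
    TSV (path) or an iterable of (term, gene) pairs. Duplicate pairs are
    collapsed; empty terms dropped with a warning."""
    pairs: list[tuple[str, str]] = []
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        with open(source) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 2:
                    raise ParseError(f"{source}:{lineno}: expected 2 columns")
                if lineno == 1 and fields == ["term_id", "gene_id"]:
                    continue
                pairs.append((fields[0], fields[1]))
    else:
        pairs = [(str(t), str(g)) for t, g in source]
    if not pairs:
        raise ValidationError("annotation source is empty")
    terms: dict[str, set[str]] = {}
    for term, gene in pairs:
        terms.setdefault(term, set()).add(gene)
    empty = [t for t, m in terms.items() if not m]
    for t in empty:
        logger.warning("dropping empty term %r", t)
        del terms[t]
    background = frozenset(g for m in terms.values() for g in m)
    return AnnotationTable({t: frozenset(m) for t, m in terms.items()}, background)


def enrich(gene_list: Iterable[str], annotation: AnnotationTable,
           alpha: float = 0.05, ease: bool = False,
           adjust: str | None = None) -> pd.DataFrame:
    """Hypergeometric enrichment of ``gene_list`` over every term with at
    least one hit, sorted by p ascending.

    Genes outside the annotated background are dropped (logged); an empty
    intersection is an error. Columns: k, n, K_term, N, p_value,
    fold_enrichment, significant (p < alpha; on adjusted p if requested).
    """
    genes = set(gene_list)
    inside = genes & annotation.background
    dropped = len(genes) - len(inside)
    if dropped:
        logger.info("enrich: dropped %d gene(s) outside the background", dropped)
    if not inside:
        raise ValidationError("gene list has empty intersection with the "
                              "annotated background")
    N = len(annotation.background)
    n = len(inside)
    rows = []
    for term, members in annotation.terms.items():
        k = len(inside & members)
        if k < 1:
            continue
        K_term = len(members)
        k_eff = k - 1 if ease else k
        # upper tail P(X >= k_eff); EASE uses k-1 (p=1 when k_eff <= 0)
        p = float(stats.hypergeom.sf(k_eff - 1, N, K_term, n)) if k_eff > 0 else 1.0
        fe = (k / n) / (K_term / N)
        rows.append((term, k, n, K_term, N, p, fe))
    df = pd.DataFrame(rows, columns=["term_id", "k", "n", "K_term", "N",
                                     "p_value", "fold_enrichment"])
    df = df.sort_values(["p_value", "term_id"], kind="mergesort",
                        ignore_index=True)
    p_eff = df["p_value"]
    if adjust is not None:
        if adjust != "bh":
            raise ValueError(f"unknown adjustment {adjust!r}")
        from statsmodels.stats.multitest import multipletests

        df["p_adj"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
        p_eff = df["p_adj"]
    df["significant"] = p_eff < alpha
    return df
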