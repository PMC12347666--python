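"""Strand-aware promoter quantification and TSS metagene profiles.

Promoter windows are ``[tss - W, tss + W)`` with ``W`` = 1000 bp by default,
the -1 kb..+1 kb region treated as the functional window for transcriptional
regulation. Signal is expressed as library-scaled density:

    level = (sum of value x overlap_bp / window_length) * (1e7 / library_size)

The 1e7 scale (signal per 10 Mb-equivalent of library) is arbitrary but
fixed; only between-group ratios matter downstream.

Metagene profiles use a scale-regions layout: 30 upstream bins of 100 bp,
60 length-rescaled gene-body bins, 30 downstream bins of 100 bp (120 bins
total). Minus-strand genes are flipped so bin 0 is always the 5' end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .iolib import GeneModel, Interval, SignalTrack, ValidationError

__all__ = [
    "PromoterWindow",
    "promoter_windows",
    "quantify",
    "quantify_samples",
    "tss_adjacent",
    "metagene",
    "SCALE",
]

logger = logging.getLogger(__name__)

#: library-normalization constant: signal per 10 Mb-equivalent of library
SCALE = 1.0e7


@dataclass(frozen=True)
class PromoterWindow:
    """A gene's promoter window, clipped at chromosome bounds."""

    gene_id: str
    interval: Interval


def promoter_windows(
    genes: Iterable[GeneModel],
    window: int = 1000,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[PromoterWindow]:
    """One window ``[tss - window, tss + window)`` per gene, clipped to
    ``[0, chrom_size)`` (the upper clip only if ``chrom_sizes`` is given)."""
    if window <= 0:
        raise ValueError("window must be > 0")
    out = []
    for g in genes:
        start = max(0, g.tss - window)
        end = g.tss + window
        if chrom_sizes is not None and g.chrom in chrom_sizes:
            end = min(end, chrom_sizes[g.chrom])
        out.append(PromoterWindow(g.gene_id, Interval(g.chrom, start, end)))
    return out


def quantify(track: SignalTrack, windows: Sequence[PromoterWindow],
             scale: float = SCALE) -> pd.Series:
    """Library-scaled mean signal density per window for one sample.

    Raises on an unusable (zero library size) track.
    """
    if not track.usable:
        raise ValidationError(
            f"track {track.sample_id!r} has zero library size; cannot normalize"
        )
    ids = [w.gene_id for w in windows]
    levels = np.empty(len(windows))
    by_chrom: dict[str, list[int]] = {}
    for i, w in enumerate(windows):
        by_chrom.setdefault(w.interval.chrom, []).append(i)
    factor = scale / track.library_size
    for chrom, idx in by_chrom.items():
        idx = np.asarray(idx)
        starts = np.array([windows[i].interval.start for i in idx], dtype=float)
        ends = np.array([windows[i].interval.end for i in idx], dtype=float)
        sums = track.integral_many(chrom, starts, ends)
        levels[idx] = sums / (ends - starts) * factor
    return pd.Series(levels, index=pd.Index(ids, name="gene_id"),
                     name=track.sample_id)


def quantify_samples(tracks: Sequence[SignalTrack],
                     windows: Sequence[PromoterWindow],
                     scale: float = SCALE) -> pd.DataFrame:
    """Stack :func:`quantify` over samples into a gene x sample MarkMatrix."""
    cols = [quantify(t, windows, scale=scale) for t in tracks]
    df = pd.concat(cols, axis=1)
    df.attrs["groups"] = {t.sample_id: t.group for t in tracks}
    return df


def tss_adjacent(peak: Interval, gene: GeneModel, max_distance: int = 1000) -> bool:
    """True iff the peak contains the TSS or either peak end lies within
    ``max_distance`` bp of it."""
    tss = gene.tss
    if peak.start <= tss < peak.end:
        return True
    return min(abs(peak.start - tss), abs(peak.end - 1 - tss)) <= max_distance


def _gene_bin_edges(gene: GeneModel, upstream: int, downstream: int,
                    n_flank_up: int, n_body: int, n_flank_down: int,
                    flank_bin: int) -> tuple[np.ndarray, np.ndarray]:
    """Genomic bin edges (ascending) and, per ascending genomic bin, the
    5'->3' profile bin it feeds (minus-strand genes are mirrored)."""
    n_bins = n_flank_up + n_body + n_flank_down
    body = gene.start + (gene.end - gene.start) * np.linspace(0.0, 1.0, n_body + 1)
    if gene.strand == "+":
        lo = gene.start - upstream + flank_bin * np.arange(n_flank_up + 1, dtype=float)
        hi = gene.end + flank_bin * np.arange(n_flank_down + 1, dtype=float)
        order = np.arange(n_bins)
    else:
        lo = gene.start - downstream + flank_bin * np.arange(n_flank_down + 1,
                                                             dtype=float)
        hi = gene.end + flank_bin * np.arange(n_flank_up + 1, dtype=float)
        order = np.arange(n_bins)[::-1]
    edges = np.concatenate([lo, body[1:], hi[1:]])
    return edges, order


def _profile_one_track(track: SignalTrack, genes: Sequence[GeneModel],
                       upstream: int, downstream: int, body_bins: int,
                       flank_bin: int) -> np.ndarray:
    n_up = upstream // flank_bin
    n_down = downstream // flank_bin
    n_bins = n_up + body_bins + n_down
    factor = SCALE / track.library_size
    acc = np.zeros(n_bins)
    for gene in genes:
        edges, order = _gene_bin_edges(gene, upstream, downstream,
                                       n_up, body_bins, n_down, flank_bin)
        sums = track.integral_many(gene.chrom, edges[:-1], edges[1:])
        widths = np.diff(edges)
        dens = np.where(widths > 0, sums / np.where(widths > 0, widths, 1.0), 0.0)
        acc[order] += dens * factor
    return acc / len(genes)


def metagene(
    tracks: Sequence[SignalTrack],
    genes: Sequence[GeneModel],
    upstream: int = 3000,
    downstream: int = 3000,
    body_bins: int = 60,
    flank_bin: int = 100,
    input_track: SignalTrack | None = None,
) -> pd.DataFrame:
    """Group-mean scaled metagene profiles.

    Returns a DataFrame with one row per profile bin (5' flank, scaled body,
    3' flank) and one column per replicate group present in ``tracks``; the
    optional input control is profiled alongside as column ``"input"``
    (reported, never subtracted). Values are group means over samples of
    per-gene mean library-scaled densities.
    """
    if upstream % flank_bin or downstream % flank_bin:
        raise ValueError("flank lengths must be multiples of flank_bin")
    if not genes:
        raise ValueError("no genes supplied")
    for g in genes:
        if g.length < 1:
            raise ValidationError(f"gene {g.gene_id} has empty body")
    n_up = upstream // flank_bin
    n_down = downstream // flank_bin
    by_group: dict[str, list[np.ndarray]] = {}
    for t in tracks:
        if not t.usable:
            raise ValidationError(f"track {t.sample_id!r} unusable (library size 0)")
        prof = _profile_one_track(t, genes, upstream, downstream, body_bins, flank_bin)
        by_group.setdefault(t.group, []).append(prof)
    data = {grp: np.mean(np.vstack(profs), axis=0)
            for grp, profs in by_group.items()}
    if input_track is not None:
        data["input"] = _profile_one_track(input_track, genes, upstream,
                                           downstream, body_bins, flank_bin)
    labels = ([f"up{i}" for i in range(n_up)]
              + [f"body{i}" for i in range(body_bins)]
              + [f"down{i}" for i in range(n_down)])
    df = pd.DataFrame(data, index=pd.Index(labels, name="bin"))
    df.attrs["layout"] = {"upstream_bins": n_up, "body_bins": body_bins,
                          "downstream_bins": n_down, "flank_bin": flank_bin}
    return df
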