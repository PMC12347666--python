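"""Readers/writers for the plain-text formats the pipeline exchanges.

Coordinate contract: every interval in this package is 0-based, half-open
``[start, end)`` (the BED dialect). The TSS of a ``-`` strand gene is
``end - 1``; its TES is ``start``. External gene lists printed 1-based
inclusive must be converted explicitly via
:meth:`Interval.from_one_based_inclusive`.

All writers emit tab-separated, LF-terminated text with no quoting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "ValidationError",
    "Interval",
    "GeneModel",
    "SignalTrack",
    "read_gene_models",
    "write_gene_models",
    "read_bedgraph",
    "write_bedgraph",
    "read_matrix",
    "write_matrix",
    "read_groups",
    "write_groups",
]


class ParseError(ValueError):
    """A malformed line or cell in an input file."""


class ValidationError(ValueError):
    """Structurally parseable input that violates a contract."""


@dataclass(frozen=True)
class Interval:
    """A 0-based half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end (0-based half-open)"
            )

    @classmethod
    def from_one_based_inclusive(cls, chrom: str, start: int, end: int) -> "Interval":
        """Convert a 1-based inclusive span (as printed in journal tables) to
        the package's 0-based half-open convention."""
        return cls(chrom, start - 1, end)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """One gene's span and strand; TSS/TES are derived, never stored."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"gene {self.gene_id}: require 0 <= start < end, got "
                f"[{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )

    @property
    def tss(self) -> int:
        """Transcription start site (a single base, 0-based)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        """Transcription end site (a single base, 0-based)."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start


class SignalTrack:
    """Per-sample coverage as sorted, disjoint, non-negative intervals.

    Parameters
    ----------
    sample_id, group
        Sample identity and its replicate group (e.g. ``"LN"``, ``"HN"``,
        ``"input"``).
    chroms
        Mapping chrom -> ``(starts, ends, values)`` integer/float arrays.
        Intervals within a chrom must be sorted and pairwise disjoint.
    """

    def __init__(self, sample_id: str, group: str,
                 chroms: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self.sample_id = sample_id
        self.group = group
        self.chroms: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        lib = 0.0
        for chrom, (starts, ends, values) in chroms.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=float)
            if not (starts.shape == ends.shape == values.shape):
                raise ValidationError(f"{sample_id}/{chrom}: ragged interval arrays")
            if np.any(starts >= ends) or np.any(starts < 0):
                raise ValidationError(
                    f"{sample_id}/{chrom}: intervals must satisfy 0 <= start < end"
                )
            if starts.size > 1 and np.any(starts[1:] < ends[:-1]):
                raise ValidationError(
                    f"{sample_id}/{chrom}: intervals overlap or are unsorted"
                )
            if np.any(values < 0):
                raise ValidationError(f"{sample_id}/{chrom}: negative coverage value")
            self.chroms[chrom] = (starts, ends, values)
            lib += float(np.sum(values * (ends - starts)))
        self.library_size = lib
        # cumulative-integral knots per chrom, built lazily
        self._cum: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    @property
    def usable(self) -> bool:
        """False for an empty/zero track that cannot be library-normalized."""
        return self.library_size > 0

    def _knots(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """Positions x and cumulative integral F(x) of coverage over [0, x)."""
        try:
            return self._cum[chrom]
        except KeyError:
            starts, ends, values = self.chroms.get(
                chrom, (np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0))
            )
            areas = values * (ends - starts)
            cum_end = np.cumsum(areas)
            cum_start = cum_end - areas
            x = np.empty(2 * starts.size, dtype=float)
            f = np.empty_like(x)
            x[0::2], x[1::2] = starts, ends
            f[0::2], f[1::2] = cum_start, cum_end
            self._cum[chrom] = (x, f)
            return x, f

    def integral(self, chrom: str, start: float, end: float) -> float:
        """Integral of coverage over genomic span [start, end)."""
        return float(self.integral_many(chrom, [start], [end])[0])

    def integral_many(self, chrom: str, starts, ends) -> np.ndarray:
        """Vectorized :meth:`integral` for arrays of span boundaries."""
        x, f = self._knots(chrom)
        starts = np.asarray(starts, dtype=float)
        ends = np.asarray(ends, dtype=float)
        if x.size == 0:
            return np.zeros(starts.shape)
        hi = float(x[-1])
        Fa = np.interp(np.clip(starts, 0.0, hi), x, f)
        Fb = np.interp(np.clip(ends, 0.0, hi), x, f)
        return Fb - Fa


def read_gene_models(path) -> list[GeneModel]:
    """Parse a BED6 file into :class:`GeneModel` records.

    Columns: chrom, start, end, gene_id, score (ignored), strand.
    Duplicate gene ids are rejected.
    """
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected 6 tab-separated columns, "
                                 f"got {len(fields)}")
            chrom, start_s, end_s, gene_id, _score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if gene_id in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            try:
                genes.append(GeneModel(gene_id, chrom, start, end, strand))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return genes


def write_gene_models(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def read_bedgraph(path, sample_id: str, group: str) -> SignalTrack:
    """Parse a 4-column bedGraph into a :class:`SignalTrack`.

    Intervals within a chrom must not overlap; values must be non-negative.
    """
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
                value = float(fields[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric field") from exc
            if value < 0:
                raise ValidationError(f"{path}:{lineno}: negative value {value}")
            per_chrom.setdefault(chrom, []).append((start, end, value))
    chroms = {}
    for chrom, rows in per_chrom.items():
        rows.sort(key=lambda r: (r[0], r[1]))
        starts = np.array([r[0] for r in rows], dtype=np.int64)
        ends = np.array([r[1] for r in rows], dtype=np.int64)
        values = np.array([r[2] for r in rows], dtype=float)
        if starts.size > 1 and np.any(starts[1:] < ends[:-1]):
            i = int(np.argmax(starts[1:] < ends[:-1]))
            raise ValidationError(
                f"{path}: overlapping intervals on {chrom} near "
                f"{starts[i + 1]}..{ends[i]}"
            )
        chroms[chrom] = (starts, ends, values)
    return SignalTrack(sample_id, group, chroms)


def write_bedgraph(track: SignalTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.chroms):
            starts, ends, values = track.chroms[chrom]
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.10g}\n")


def read_matrix(path) -> pd.DataFrame:
    """Read a gene x sample TSV matrix (header of sample ids, first column
    gene_id). Missing cells (``NA`` or empty) become NaN, never zero."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    if len(set(samples)) != len(samples):
        dup = sorted({s for s in samples if samples.count(s) > 1})
        raise ValidationError(f"{path}: duplicate sample id(s) in header: {dup}")
    df = pd.read_csv(
        path, sep="\t", index_col=0, header=0,
        na_values=["NA", "NaN", "nan", ""], keep_default_na=False, dtype=str,
    )
    df.columns = samples
    if df.index.has_duplicates:
        dup = sorted(df.index[df.index.duplicated()].unique())
        raise ValidationError(f"{path}: duplicate gene id(s): {dup[:5]}")
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        raw = df[col]
        num = pd.to_numeric(raw, errors="coerce")
        bad = num.isna() & raw.notna()
        if bad.any():
            gene = bad.idxmax()
            raise ParseError(
                f"{path}: non-numeric cell at gene {gene!r}, sample {col!r}: "
                f"{raw[gene]!r}"
            )
        out[col] = num
    out.index.name = df.index.name or "gene_id"
    return out


def write_matrix(matrix: pd.DataFrame, path, float_format: str = "%.10g") -> None:
    """Write a matrix as TSV; NaN cells are emitted as ``NA``."""
    matrix.to_csv(path, sep="\t", na_rep="NA", float_format=float_format,
                  index_label=matrix.index.name or "gene_id", lineterminator="\n")


def read_groups(path) -> dict[str, str]:
    """Read a two-column sample_id -> group TSV (no header required; a
    ``sample_id<TAB>group`` header line is tolerated and skipped)."""
    groups: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            if lineno == 1 and fields == ["sample_id", "group"]:
                continue
            sample, grp = fields
            if sample in groups:
                raise ValidationError(f"{path}:{lineno}: duplicate sample {sample!r}")
            groups[sample] = grp
    if not groups:
        raise ValidationError(f"{path}: empty groups file")
    return groups


def write_groups(groups: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tgroup\n")
        for sample, grp in groups.items():
            fh.write(f"{sample}\t{grp}\n")
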