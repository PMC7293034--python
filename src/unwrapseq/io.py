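"""Readers and writers for the genomic formats the pipeline touches.

All coordinates follow the BED convention: 0-based, half-open ``[start, end)``.
A fragment's length is ``end - start`` and its center is ``floor((start+end)/2)``
(the lower-median base for even lengths); every downstream stage — V-plots,
genome tracks, window membership — uses these two definitions and no other.

Fragment inputs are assumed to be already alignment-filtered (concordant pairs,
mapq > 10); this module consumes fragment intervals, it does not judge
alignments. PCR duplicates are neither removed nor required to be removed.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Fragment",
    "FragmentSet",
    "ReferencePoint",
    "GenomicInterval",
    "REFERENCE_KINDS",
    "read_fragments",
    "write_fragments",
    "read_reference_points",
    "write_reference_points",
    "read_expression_table",
    "write_expression_table",
    "write_bedgraph",
    "write_matrix_tsv",
    "read_matrix_tsv",
]

REFERENCE_KINDS = ("TSS", "CBS", "NUC_CENTER", "PEAK_SUMMIT")
#: kinds for which a strand is biologically meaningful and therefore required
_STRANDED_KINDS = ("TSS", "CBS")


class FormatError(ValueError):
    """A malformed row in an input file; the message names the line."""


@dataclass(frozen=True)
class Fragment:
    """One sequenced chromatin particle as a genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"fragment end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class FragmentSet:
    """A columnar collection of fragments from one sample (one library).

    ``total_pairs`` (the library size used for CPB/RPM normalization) always
    equals the number of stored fragments.
    """

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    label: str = "sample"

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        if not (len(self.chrom) == len(self.start) == len(self.end)):
            raise ValueError("chrom/start/end arrays must have equal length")
        if np.any(self.end <= self.start):
            bad = int(np.argmax(self.end <= self.start))
            raise ValueError(
                f"fragment {bad}: end must exceed start "
                f"([{self.start[bad]}, {self.end[bad]}))"
            )
        if not self.label:
            raise ValueError("label must be non-empty")

    @property
    def length(self) -> np.ndarray:
        return self.end - self.start

    @property
    def center(self) -> np.ndarray:
        # floor((start+end)/2); start+end fits comfortably in int64
        return (self.start + self.end) // 2

    @property
    def total_pairs(self) -> int:
        return len(self.start)

    def __len__(self) -> int:
        return len(self.start)

    def __iter__(self) -> Iterator[Fragment]:
        for c, s, e in zip(self.chrom, self.start, self.end):
            yield Fragment(str(c), int(s), int(e))

    def subset(self, mask: np.ndarray, label: str | None = None) -> "FragmentSet":
        return FragmentSet(
            self.chrom[mask], self.start[mask], self.end[mask],
            label=label or self.label,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": self.start,
                "end": self.end,
                "length": self.length,
                "center": self.center,
            }
        )

    @classmethod
    def from_fragments(
        cls, fragments: Iterable[Fragment], label: str = "sample"
    ) -> "FragmentSet":
        frags = list(fragments)
        return cls(
            np.array([f.chrom for f in frags], dtype=object),
            np.array([f.start for f in frags], dtype=np.int64),
            np.array([f.end for f in frags], dtype=np.int64),
            label=label,
        )

    @classmethod
    def empty(cls, label: str = "sample") -> "FragmentSet":
        return cls(np.array([], dtype=object), np.array([], dtype=np.int64),
                   np.array([], dtype=np.int64), label=label)

    def concat(self, other: "FragmentSet", label: str | None = None) -> "FragmentSet":
        return FragmentSet(
            np.concatenate([self.chrom, other.chrom]),
            np.concatenate([self.start, other.start]),
            np.concatenate([self.end, other.end]),
            label=label or self.label,
        )


@dataclass(frozen=True)
class ReferencePoint:
    """A strand-aware single-bp anchor (TSS, CTCF site, nucleosome center...)."""

    chrom: str
    pos: int
    strand: str = "+"
    kind: str = "NUC_CENTER"
    name: str = "."

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"reference position must be >= 0, got {self.pos}")
        if self.kind not in REFERENCE_KINDS:
            raise ValueError(f"unknown reference kind {self.kind!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"interval end must exceed start, got [{self.start}, {self.end})"
            )


def _tokenize(path: str | Path) -> Iterator[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t") if "\t" in line else line.split()


def _int_field(tok: str, what: str, lineno: int) -> int:
    try:
        return int(tok)
    except ValueError:
        raise FormatError(f"line {lineno}: cannot parse {what} {tok!r} as integer")


def read_fragments(
    path: str | Path,
    min_len: int = 1,
    max_len: int = 1000,
    fmt: str = "auto",
    label: str | None = None,
) -> FragmentSet:
    """Read fragments from a fragment BED (3+ columns) or 10-column BEDPE.

    BEDPE rows are collapsed to the outer span of the two mates. Only
    fragments with ``min_len <= length <= max_len`` are kept (defaults are
    deliberately loose so ingestion is lossless; analysis-level length bounds
    are applied downstream). Rows failing to parse raise :class:`FormatError`
    naming the offending line. An empty file yields an empty set.
    """
    if min_len > max_len:
        raise ValueError(f"min_len ({min_len}) > max_len ({max_len})")
    if fmt not in ("auto", "bed", "bedpe"):
        raise ValueError(f"unknown format {fmt!r}")

    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    for lineno, tok in _tokenize(path):
        row_fmt = fmt
        if row_fmt == "auto":
            # BEDPE: col 4 is mate-2 chrom (non-numeric context: cols 5,6 ints);
            # BED6 has strand (+/-/.) in col 6.
            if len(tok) >= 6 and _is_int(tok[4]) and _is_int(tok[5]) and not _is_int(tok[3]):
                row_fmt = "bedpe"
            else:
                row_fmt = "bed"
        if row_fmt == "bedpe":
            if len(tok) < 6:
                raise FormatError(f"line {lineno}: BEDPE needs >= 6 columns, got {len(tok)}")
            c1, s1, e1 = tok[0], _int_field(tok[1], "start1", lineno), _int_field(tok[2], "end1", lineno)
            c2, s2, e2 = tok[3], _int_field(tok[4], "start2", lineno), _int_field(tok[5], "end2", lineno)
            if c1 != c2:
                raise FormatError(f"line {lineno}: inter-chromosomal pair {c1}/{c2}")
            start, end = min(s1, s2), max(e1, e2)
            chrom = c1
        else:
            if len(tok) < 3:
                raise FormatError(f"line {lineno}: BED needs >= 3 columns, got {len(tok)}")
            chrom = tok[0]
            start = _int_field(tok[1], "start", lineno)
            end = _int_field(tok[2], "end", lineno)
        if end <= start:
            raise FormatError(f"line {lineno}: end ({end}) <= start ({start})")
        if min_len <= end - start <= max_len:
            chroms.append(chrom)
            starts.append(start)
            ends.append(end)
    return FragmentSet(
        np.array(chroms, dtype=object),
        np.array(starts, dtype=np.int64),
        np.array(ends, dtype=np.int64),
        label=label or Path(path).stem,
    )


def _is_int(tok: str) -> bool:
    try:
        int(tok)
        return True
    except ValueError:
        return False


def write_fragments(frags: FragmentSet, path: str | Path) -> None:
    """Write a FragmentSet as 3-column fragment BED (one row per fragment)."""
    with open(path, "w") as fh:
        for c, s, e in zip(frags.chrom, frags.start, frags.end):
            fh.write(f"{c}\t{s}\t{e}\n")


def read_reference_points(path: str | Path, kind: str) -> list[ReferencePoint]:
    """Read BED6 reference points of a given kind.

    Single-bp records anchor at ``start``; wider intervals anchor at their
    midpoint ``floor((start+end)/2)``. TSS and CBS records must carry a strand;
    other kinds default to "+" by convention.
    """
    if kind not in REFERENCE_KINDS:
        raise ValueError(f"unknown reference kind {kind!r}")
    points: list[ReferencePoint] = []
    for lineno, tok in _tokenize(path):
        if len(tok) < 3:
            raise FormatError(f"line {lineno}: BED needs >= 3 columns, got {len(tok)}")
        chrom = tok[0]
        start = _int_field(tok[1], "start", lineno)
        end = _int_field(tok[2], "end", lineno)
        if end <= start:
            raise FormatError(f"line {lineno}: end ({end}) <= start ({start})")
        name = tok[3] if len(tok) > 3 else "."
        strand = tok[5] if len(tok) > 5 else "."
        if strand not in ("+", "-"):
            if kind in _STRANDED_KINDS:
                raise FormatError(
                    f"line {lineno}: {kind} records require a '+'/'-' strand, got {strand!r}"
                )
            strand = "+"
        pos = start if end - start == 1 else (start + end) // 2
        points.append(ReferencePoint(chrom, pos, strand, kind, name))
    return points


def write_reference_points(points: Sequence[ReferencePoint], path: str | Path) -> None:
    """Write reference points as single-bp BED6 records."""
    with open(path, "w") as fh:
        for p in points:
            fh.write(f"{p.chrom}\t{p.pos}\t{p.pos + 1}\t{p.name}\t0\t{p.strand}\n")


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Read a gene-expression TSV: gene_id, chrom, tss, strand, expression.

    Returns a DataFrame with exactly those columns (plus ``tier`` if present).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "tss", "strand", "expression"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"expression table missing columns: {sorted(missing)}")
    if (df["expression"] < 0).any():
        raise FormatError("expression values must be non-negative")
    return df


def write_expression_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_bedgraph(
    track: pd.DataFrame,
    path: str | Path,
    name: str = "track",
    bin_size: int = 10,
) -> None:
    """Write a fixed-width binned track (columns chrom/start/end/value) as bedGraph.

    Bins must be sorted and non-overlapping per chromosome and ``bin_size`` wide
    (the last bin of a chromosome may be shorter). Zero bins are omitted and
    values are printed with 4 decimal places — one track per file.
    """
    req = ["chrom", "start", "end", "value"]
    if list(track.columns[:4]) != req and not set(req) <= set(track.columns):
        raise ValueError(f"track needs columns {req}")
    for chrom, sub in track.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if np.any(np.diff(starts) <= 0) or np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"bins on {chrom} are unsorted or overlapping")
        widths = ends - starts
        if np.any(widths[:-1] != bin_size) or widths[-1] > bin_size:
            raise ValueError(f"bins on {chrom} are not fixed {bin_size}-bp bins")
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{name}"\n')
        nonzero = track[track["value"] != 0]
        for row in nonzero.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.value:.4f}\n")


def write_matrix_tsv(
    values: np.ndarray | pd.DataFrame,
    path: str | Path,
    row_labels: Sequence | None = None,
    col_labels: Sequence | None = None,
    meta: dict | None = None,
    index_name: str = "row",
) -> None:
    """Write a labelled matrix as TSV with optional ``# key=value`` metadata lines.

    Round-trips losslessly with :func:`read_matrix_tsv` (float values at full
    ``repr`` precision).
    """
    if isinstance(values, pd.DataFrame):
        df = values
    else:
        df = pd.DataFrame(np.asarray(values), index=row_labels, columns=col_labels)
        df.index.name = index_name
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", float_format=None)


def read_matrix_tsv(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Read a matrix written by :func:`write_matrix_tsv`; returns (df, meta)."""
    meta: dict[str, str] = {}
    lines = Path(path).read_text().splitlines(keepends=True)
    body_at = 0
    for i, line in enumerate(lines):
        if line.startswith("# ") and "=" in line:
            k, _, v = line[2:].strip().partition("=")
            meta[k] = v
            body_at = i + 1
        else:
            break
    body = "".join(lines[body_at:])
    df = pd.read_csv(_io.StringIO(body), sep="\t", index_col=0)
    return df, meta
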