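"""Five-way fragment-length groups, per-window ratios, +1 nucleosome selection
and per-group genome tracks.

The partition of 30–168 bp fragments into G80/G100/G120/G140/G168 follows the
sub-peak structure of canonical-histone fragment-length profiles: tetrasome- or
factor-scale protections (30–80), three partially unwrapped intermediates
(81–100, 101–120, 121–140 — the last compatible with hexasomes) and intact
cores (141–168). Ranges are inclusive integer ranges on fragment length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import FragmentSet, GenomicInterval, ReferencePoint

__all__ = [
    "FragmentGroupScheme",
    "GroupRatioTable",
    "OverlapResult",
    "assign_group",
    "window_group_ratios",
    "windows_from_points",
    "select_plus1",
    "group_tracks",
    "interval_overlap",
]

logger = logging.getLogger(__name__)

GROUP_LABELS = ("G80", "G100", "G120", "G140", "G168")


@dataclass(frozen=True)
class FragmentGroupScheme:
    """Ordered, disjoint, contiguous inclusive length ranges with labels."""

    bounds: tuple[tuple[str, int, int], ...] = (
        ("G80", 30, 80),
        ("G100", 81, 100),
        ("G120", 101, 120),
        ("G140", 121, 140),
        ("G168", 141, 168),
    )

    def __post_init__(self) -> None:
        prev_hi = None
        for label, lo, hi in self.bounds:
            if lo > hi:
                raise ValueError(f"group {label}: empty range {lo}-{hi}")
            if prev_hi is not None and lo != prev_hi + 1:
                raise ValueError(
                    f"group {label}: ranges must be contiguous and ascending "
                    f"(previous upper bound {prev_hi}, got lower bound {lo})"
                )
            prev_hi = hi

    @classmethod
    def default(cls) -> "FragmentGroupScheme":
        return cls()

    @classmethod
    def narrow_small(cls) -> "FragmentGroupScheme":
        """Variant with the smallest group starting at 35 bp instead of 30."""
        return cls((("G80", 35, 80),) + cls().bounds[1:])

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for label, _, _ in self.bounds)

    @property
    def min_len(self) -> int:
        return self.bounds[0][1]

    @property
    def max_len(self) -> int:
        return self.bounds[-1][2]

    def ranges(self) -> dict[str, tuple[int, int]]:
        return {label: (lo, hi) for label, lo, hi in self.bounds}

    def assign_codes(self, lengths: np.ndarray) -> np.ndarray:
        """Vectorized group assignment; -1 for lengths outside all groups."""
        lengths = np.asarray(lengths)
        edges = np.array([lo for _, lo, _ in self.bounds] + [self.max_len + 1])
        codes = np.searchsorted(edges, lengths, side="right") - 1
        codes[(lengths < self.min_len) | (lengths > self.max_len)] = -1
        return codes


def assign_group(length: int, scheme: FragmentGroupScheme | None = None) -> str | None:
    """Group label of a fragment length, or None outside the scheme's span."""
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    scheme = scheme or FragmentGroupScheme.default()
    for label, lo, hi in scheme.bounds:
        if lo <= length <= hi:
            return label
    return None


@dataclass
class GroupRatioTable:
    """Per-window group counts and ratios.

    ``table`` columns: window_id, chrom, start, end, one count column per
    group, ``total`` (in-range fragments) and one ``ratio_<group>`` column per
    group; ``included`` marks windows with enough fragments for downstream
    scaling/clustering. Ratios of excluded windows are NaN.
    """

    table: pd.DataFrame
    scheme: FragmentGroupScheme
    min_fragments: int

    @property
    def ratios(self) -> pd.DataFrame:
        cols = [f"ratio_{g}" for g in self.scheme.labels]
        sub = self.table.loc[self.table["included"], cols]
        sub.columns = list(self.scheme.labels)
        sub.index = self.table.loc[self.table["included"], "window_id"]
        return sub


def windows_from_points(
    points: Sequence[ReferencePoint], halfwidth: int
) -> pd.DataFrame:
    """Center ± halfwidth windows (half-open) around reference points."""
    return pd.DataFrame(
        {
            "window_id": [p.name if p.name != "." else f"w{i}" for i, p in enumerate(points)],
            "chrom": [p.chrom for p in points],
            "start": [max(0, p.pos - halfwidth) for p in points],
            "end": [p.pos + halfwidth for p in points],
        }
    )


def windows_from_intervals(intervals: Sequence[GenomicInterval]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "window_id": [iv.name if iv.name != "." else f"w{i}" for i, iv in enumerate(intervals)],
            "chrom": [iv.chrom for iv in intervals],
            "start": [iv.start for iv in intervals],
            "end": [iv.end for iv in intervals],
        }
    )


def window_group_ratios(
    frags: FragmentSet,
    windows: pd.DataFrame,
    scheme: FragmentGroupScheme | None = None,
    min_fragments: int = 20,
) -> GroupRatioTable:
    """Count the five length groups per window and form ratios.

    A fragment belongs to a window iff its *center* lies in the half-open
    window interval; only fragments within the scheme's length span enter the
    counts, so ratios sum to 1 per included window. Windows with fewer than
    ``min_fragments`` in-range fragments are flagged ``included=False`` (their
    ratios are NaN) — too few fragments make ratio estimates unstable for
    robust scaling.
    """
    if len(windows) == 0:
        raise ValueError("windows must be non-empty")
    scheme = scheme or FragmentGroupScheme.default()
    codes_all = scheme.assign_codes(frags.length)
    centers = frags.center
    chroms = frags.chrom

    # per-chromosome center-sorted views for fast window slicing
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in np.unique(chroms.astype(str)):
        mask = chroms == chrom
        order = np.argsort(centers[mask], kind="stable")
        by_chrom[chrom] = (centers[mask][order], codes_all[mask][order])

    n_groups = len(scheme.labels)
    rows = []
    for row in windows.itertuples(index=False):
        centers_c, codes_c = by_chrom.get(str(row.chrom), (np.array([]), np.array([])))
        lo = np.searchsorted(centers_c, row.start, side="left")
        hi = np.searchsorted(centers_c, row.end, side="left")
        codes = codes_c[lo:hi]
        codes = codes[codes >= 0]
        counts = np.bincount(codes, minlength=n_groups)
        rows.append(counts)
    counts_mat = np.array(rows, dtype=np.int64).reshape(len(windows), n_groups)
    totals = counts_mat.sum(axis=1)
    included = totals >= min_fragments
    n_excluded = int((~included).sum())
    if n_excluded:
        logger.info(
            "window_group_ratios: %d/%d windows below %d in-range fragments",
            n_excluded, len(windows), min_fragments,
        )

    out = windows.copy().reset_index(drop=True)
    for j, g in enumerate(scheme.labels):
        out[g] = counts_mat[:, j]
    out["total"] = totals
    with np.errstate(invalid="ignore", divide="ignore"):
        ratios = counts_mat / totals[:, None]
    ratios[~included] = np.nan
    for j, g in enumerate(scheme.labels):
        out[f"ratio_{g}"] = ratios[:, j]
    out["included"] = included
    return GroupRatioTable(out, scheme, min_fragments)


def select_plus1(
    centers: Sequence[ReferencePoint],
    tss: Sequence[ReferencePoint],
    min_dist: int = 50,
    max_dist: int = 200,
) -> dict[str, ReferencePoint]:
    """Map each gene to its +1 nucleosome center.

    A candidate center lies 50–200 bp downstream of the TSS (strand-aware:
    ``[pos+50, pos+200]`` for "+", ``[pos-200, pos-50]`` for "−"). Among
    candidates the one nearest the TSS wins; exact distance ties break toward
    the smaller coordinate. Genes without a candidate are omitted (and
    counted in the log).
    """
    by_chrom: dict[str, tuple[np.ndarray, list[ReferencePoint]]] = {}
    for chrom in {c.chrom for c in centers}:
        pts = sorted((c for c in centers if c.chrom == chrom), key=lambda c: c.pos)
        by_chrom[chrom] = (np.array([c.pos for c in pts]), pts)

    result: dict[str, ReferencePoint] = {}
    n_missed = 0
    for t in tss:
        pos_arr, pts = by_chrom.get(t.chrom, (np.array([]), []))
        if t.strand == "+":
            lo, hi = t.pos + min_dist, t.pos + max_dist
        else:
            lo, hi = t.pos - max_dist, t.pos - min_dist
        i0 = np.searchsorted(pos_arr, lo, side="left")
        i1 = np.searchsorted(pos_arr, hi, side="right")
        cands = pts[i0:i1]
        if not cands:
            n_missed += 1
            continue
        # nearest to the TSS; ties toward the smaller coordinate
        result[t.name] = min(cands, key=lambda c: (abs(c.pos - t.pos), c.pos))
    if n_missed:
        logger.info("select_plus1: %d/%d TSSs had no center in range", n_missed, len(tss))
    return result


def group_tracks(
    frags: FragmentSet,
    scheme: FragmentGroupScheme | None = None,
    bin_size: int = 10,
) -> dict[str, pd.DataFrame]:
    """Per-group RPM genome tracks: fragment centers binned at 10 bp.

    Values are ``count * 1e6 / total_pairs`` with the *library-level* total
    (all fragments in the set), so the group tracks of one library share one
    denominator and sum bin-wise to the all-in-range track.
    """
    scheme = scheme or FragmentGroupScheme.default()
    total = frags.total_pairs
    codes = scheme.assign_codes(frags.length)
    centers = frags.center
    chroms = frags.chrom
    tracks: dict[str, pd.DataFrame] = {}
    for j, g in enumerate(scheme.labels):
        parts = []
        mask_g = codes == j
        for chrom in np.unique(chroms[mask_g].astype(str)):
            mask = mask_g & (chroms == chrom)
            bins = centers[mask] // bin_size
            counts = np.bincount(bins)
            nz = np.nonzero(counts)[0]
            parts.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "start": nz * bin_size,
                        "end": (nz + 1) * bin_size,
                        "value": counts[nz] * 1e6 / total if total else 0.0,
                    }
                )
            )
        tracks[g] = (
            pd.concat(parts, ignore_index=True)
            if parts
            else pd.DataFrame(columns=["chrom", "start", "end", "value"])
        )
    return tracks


@dataclass(frozen=True)
class OverlapResult:
    """Venn-style interval overlap counts between two interval sets."""

    a_specific: int
    b_specific: int
    shared_a: int
    shared_b: int


def interval_overlap(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> OverlapResult:
    """Classify intervals as set-specific or shared (>= 1 bp overlap).

    ``shared_a``/``shared_b`` count intervals of each set overlapping at least
    one interval of the other (half-open overlap: [0,100) and [99,200) share
    one bp; [0,100) and [100,200) do not).
    """

    def overlaps_any(queries, subjects) -> np.ndarray:
        by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom in {s.chrom for s in subjects}:
            subs = sorted((s for s in subjects if s.chrom == chrom), key=lambda s: s.start)
            starts = np.array([s.start for s in subs])
            ends_cummax = np.maximum.accumulate(np.array([s.end for s in subs]))
            by_chrom[chrom] = (starts, ends_cummax)
        hits = np.zeros(len(queries), dtype=bool)
        for i, q in enumerate(queries):
            if q.chrom not in by_chrom:
                continue
            starts, ends_cummax = by_chrom[q.chrom]
            # subjects with start < q.end; overlap iff some such subject ends > q.start
            k = np.searchsorted(starts, q.end, side="left")
            hits[i] = k > 0 and ends_cummax[k - 1] > q.start
        return hits

    a_hits = overlaps_any(a, b)
    b_hits = overlaps_any(b, a)
    return OverlapResult(
        a_specific=int((~a_hits).sum()),
        b_specific=int((~b_hits).sum()),
        shared_a=int(a_hits.sum()),
        shared_b=int(b_hits.sum()),
    )
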