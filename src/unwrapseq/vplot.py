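"""Strand-oriented V-plots, group meta-profiles and difference-V-plots.

A V-plot is a 2-D density of fragment centers around a set of reference
points: x = oriented offset of the fragment center from the reference
(downstream positive), y = fragment length. Intact nucleosomes trace the
canonical "V" (longer protections, centers converging on the dyad); bound
factors leave short-fragment footprint spots. Densities are normalized to
centers of fragments per billion read pairs (CPB): raw center counts scaled
by 1e9 over the library's total read-pair count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .groups import FragmentGroupScheme
from .io import FragmentSet, ReferencePoint

__all__ = [
    "VPlotMatrix",
    "MetaProfile",
    "DiffVPlot",
    "compute_vplot",
    "aggregate_groups",
    "difference_vplot",
]


@dataclass
class VPlotMatrix:
    """Fragment-length x center-offset density matrix.

    Rows index fragment length ``len_min..len_max`` (inclusive); columns index
    oriented offset ``-window..+window`` at 1-bp resolution.
    """

    values: np.ndarray
    len_min: int
    len_max: int
    window: int
    norm: str  # "CPB" or "raw"
    total_pairs: int
    n_refpoints: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (self.len_max - self.len_min + 1, 2 * self.window + 1)
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape} != {expected}")
        if self.norm not in ("CPB", "raw"):
            raise ValueError(f"norm must be 'CPB' or 'raw', got {self.norm!r}")

    @property
    def lengths(self) -> np.ndarray:
        return np.arange(self.len_min, self.len_max + 1)

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.window, self.window + 1)

    def row(self, length: int) -> np.ndarray:
        if not self.len_min <= length <= self.len_max:
            raise ValueError(f"length {length} outside [{self.len_min}, {self.len_max}]")
        return self.values[length - self.len_min]

    def length_slice(self, lo: int, hi: int) -> np.ndarray:
        """Rows for lengths in the inclusive range [lo, hi]."""
        if lo < self.len_min or hi > self.len_max:
            raise ValueError(
                f"range [{lo}, {hi}] outside [{self.len_min}, {self.len_max}]"
            )
        return self.values[lo - self.len_min : hi - self.len_min + 1]


@dataclass
class MetaProfile:
    """Per-group column profiles over offsets (exact row sums of a V-plot)."""

    profiles: dict[str, np.ndarray]
    window: int
    norm: str

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.window, self.window + 1)


@dataclass
class DiffVPlot:
    """Elementwise treatment − control CPB difference matrix."""

    values: np.ndarray
    len_min: int
    len_max: int
    window: int

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.window, self.window + 1)

    def length_slice(self, lo: int, hi: int) -> np.ndarray:
        if lo < self.len_min or hi > self.len_max:
            raise ValueError(
                f"range [{lo}, {hi}] outside [{self.len_min}, {self.len_max}]"
            )
        return self.values[lo - self.len_min : hi - self.len_min + 1]


CPB_SCALE = 1e9


def compute_vplot(
    frags: FragmentSet,
    refs: Sequence[ReferencePoint],
    window: int = 2000,
    len_range: tuple[int, int] = (30, 200),
    norm: str = "CPB",
) -> VPlotMatrix:
    """Accumulate fragment centers around reference points into a V-plot.

    For every (fragment, reference) pair with ``|center − pos| <= window`` and
    fragment length within ``len_range``, the cell (length, oriented offset)
    is incremented, where the oriented offset is ``center − pos`` for a "+"
    reference and ``pos − center`` for a "−" reference. A fragment near
    several reference points contributes to each (each anchor is independent).
    CPB scaling multiplies raw counts by 1e9 / total_pairs, with the
    *library-level* total (all fragments in the set, in or out of window).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    len_min, len_max = len_range
    if not (1 <= len_min <= len_max <= 1000):
        raise ValueError(f"len_range {len_range} outside [1, 1000]")
    if len(refs) == 0:
        raise ValueError("refs must be non-empty")
    if norm == "CPB" and frags.total_pairs == 0:
        raise ValueError("CPB normalization needs a non-empty library")

    values = np.zeros((len_max - len_min + 1, 2 * window + 1))

    lengths = frags.length
    in_len = (lengths >= len_min) & (lengths <= len_max)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in np.unique(frags.chrom[in_len].astype(str)):
        mask = in_len & (frags.chrom == chrom)
        centers = frags.center[mask]
        order = np.argsort(centers, kind="stable")
        by_chrom[chrom] = (centers[order], lengths[mask][order])

    for ref in refs:
        if ref.chrom not in by_chrom:
            continue
        centers, lens = by_chrom[ref.chrom]
        lo = np.searchsorted(centers, ref.pos - window, side="left")
        hi = np.searchsorted(centers, ref.pos + window, side="right")
        offs = centers[lo:hi] - ref.pos
        if ref.strand == "-":
            offs = -offs
        np.add.at(values, (lens[lo:hi] - len_min, offs + window), 1.0)

    if norm == "CPB":
        # keep the exact raw x 1e9 / total association so CPB and raw
        # matrices agree bit-for-bit after rescaling
        values = values * CPB_SCALE / frags.total_pairs
    return VPlotMatrix(
        values, len_min, len_max, window, norm, frags.total_pairs, len(refs)
    )


def aggregate_groups(
    v: VPlotMatrix, scheme: FragmentGroupScheme | None = None
) -> MetaProfile:
    """Sum V-plot rows into per-group offset profiles (exact column sums)."""
    scheme = scheme or FragmentGroupScheme.default()
    profiles: dict[str, np.ndarray] = {}
    for label, lo, hi in scheme.bounds:
        if lo < v.len_min or hi > v.len_max:
            raise ValueError(
                f"group {label} ({lo}-{hi} bp) outside the V-plot's length "
                f"range [{v.len_min}, {v.len_max}]"
            )
        profiles[label] = v.length_slice(lo, hi).sum(axis=0)
    return MetaProfile(profiles, v.window, v.norm)


def difference_vplot(treat: VPlotMatrix, ctrl: VPlotMatrix) -> DiffVPlot:
    """Cell-for-cell CPB difference (treatment − control).

    Both inputs must be CPB-normalized and share length range and window so
    that every subtracted pair of cells has the same (offset, length).
    """
    if treat.norm != "CPB" or ctrl.norm != "CPB":
        raise ValueError("difference V-plots require CPB-normalized inputs")
    same_shape = (
        treat.len_min == ctrl.len_min
        and treat.len_max == ctrl.len_max
        and treat.window == ctrl.window
    )
    if not same_shape:
        raise ValueError("treatment and control V-plots must have identical shape")
    return DiffVPlot(
        treat.values - ctrl.values, treat.len_min, treat.len_max, treat.window
    )
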