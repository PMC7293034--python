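"""CTCF binding-site orientation on the consensus motif.

CTCF's core motif is directional; orienting CBSs on the 14-bp consensus
5'-CCACNAGGTGGCAG-3' (N = any base) lets V-plots and meta-profiles around
CBSs be averaged in a common motif frame. Matching is exact on the consensus
(no mismatch tolerance); an N in the *sequence* matches nothing.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io import GenomicInterval, ReferencePoint

__all__ = ["MotifHit", "CONSENSUS", "scan_consensus", "orient_cbs", "revcomp"]

logger = logging.getLogger(__name__)

CONSENSUS = "CCACNAGGTGGCAG"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


#: center of the even-length 14-mer is fixed at start + 7
MOTIF_CENTER_OFFSET = 7

# N in the consensus matches any base; N in the sequence matches nothing,
# hence the [ACGT] wildcard class. Lookahead makes overlapping hits visible.
_FWD = re.compile(r"(?=(" + CONSENSUS.replace("N", "[ACGT]") + r"))")
_REV = re.compile(r"(?=(" + revcomp(CONSENSUS).replace("N", "[ACGT]") + r"))")
_VALID = re.compile(r"^[ACGTN]*$")


@dataclass(frozen=True)
class MotifHit:
    chrom: str
    start: int
    end: int
    strand: str

    @property
    def center(self) -> int:
        return self.start + MOTIF_CENTER_OFFSET


def scan_consensus(seq: str, offset: int = 0, chrom: str = ".") -> list[MotifHit]:
    """Find all exact consensus matches on both strands of ``seq``.

    ``offset`` is the genomic coordinate of ``seq[0]``; reported hits are in
    genomic coordinates. Overlapping hits are all reported, sorted by start
    then strand ("+" first).
    """
    seq = seq.upper()
    if not _VALID.match(seq):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"sequence contains invalid characters: {bad}")
    hits = [
        MotifHit(chrom, offset + m.start(), offset + m.start() + len(CONSENSUS), "+")
        for m in _FWD.finditer(seq)
    ] + [
        MotifHit(chrom, offset + m.start(), offset + m.start() + len(CONSENSUS), "-")
        for m in _REV.finditer(seq)
    ]
    return sorted(hits, key=lambda h: (h.start, h.strand))


def _fetch(seqs, chrom: str, start: int, end: int) -> str:
    """Extract a subsequence from a dict of strings or a pyfaidx.Fasta."""
    record = seqs[chrom]
    if isinstance(record, str):
        return record[start:end]
    return str(record[start:end])  # pyfaidx FastaRecord slice


def orient_cbs(
    peaks: Sequence[GenomicInterval],
    seqs: Mapping[str, str],
) -> tuple[list[ReferencePoint], int]:
    """Center and orient CBS peaks on the consensus motif.

    For each peak the contained sequence is scanned; the hit nearest the peak
    midpoint wins (ties: "+" strand, then smaller coordinate) and becomes a
    strand-aware CBS reference point at the hit's center. Returns the points
    and the count of peaks dropped for lack of any hit.

    ``seqs`` may be a plain ``{chrom: sequence}`` mapping or a
    ``pyfaidx.Fasta`` handle.
    """
    points: list[ReferencePoint] = []
    n_dropped = 0
    for peak in peaks:
        seq = _fetch(seqs, peak.chrom, peak.start, peak.end)
        hits = scan_consensus(seq, offset=peak.start, chrom=peak.chrom)
        if not hits:
            n_dropped += 1
            continue
        midpoint = (peak.start + peak.end) // 2
        best = min(
            hits,
            key=lambda h: (abs(h.center - midpoint), 0 if h.strand == "+" else 1, h.start),
        )
        points.append(
            ReferencePoint(peak.chrom, best.center, best.strand, "CBS", peak.name)
        )
    if n_dropped:
        logger.info("orient_cbs: %d/%d peaks had no consensus hit", n_dropped, len(peaks))
    return points, n_dropped
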