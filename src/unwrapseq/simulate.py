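"""Synthetic MNase-X-ChIP-seq fragment generator with known ground truth.

Emulates the statistical structure the downstream analyses assume, on a single
synthetic chromosome ("chrS"): multi-modal fragment-length mixtures per histone
(intact ~147 bp cores plus shorter unwrapping intermediates), phased nucleosome
arrays with a nucleosome-depleted region (NDR) at TSSs, short CTCF-footprint
fragments at CBS centers, bimodal sub-nucleosomal placement on CBS-flanking
nucleosomes, expression-linked unwrapping ratios at +1 nucleosomes, and a
knockdown condition shifting length mixtures toward longer fragments.

One-sided unwrapping is modelled by anchoring the retained fragment edge at
dyad +/- 73 bp (half of the 147-bp core): a left-retained fragment of length L
spans ``[dyad-73, dyad-73+L)``, a right-retained one ``[dyad+73-L, dyad+73)``,
so sub-nucleosomal fragments from the two sides produce mirror-image center
modes flanking the dyad — the origin of the bimodal V-plot signature.

All draws flow from ``numpy.random.default_rng`` children of a single seed;
outputs are byte-identical under a fixed seed.
"""

from __future__ import annotations

import textwrap
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    Fragment,
    FragmentSet,
    GenomicInterval,
    ReferencePoint,
    write_expression_table,
    write_fragments,
    write_reference_points,
)
from .motif import CONSENSUS, revcomp

__all__ = [
    "UnwrapStateSpec",
    "LandscapeSpec",
    "TssLandscape",
    "CbsLandscape",
    "CANONICAL_LONGMN",
    "H2AZ_LONGMN",
    "GROUP_STATES",
    "sample_fragment",
    "simulate_histone_sample",
    "simulate_tss_landscape",
    "simulate_cbs_landscape",
    "simulate_knockdown",
    "write_fasta",
]

PLACEMENTS = ("symmetric", "left_retained", "right_retained", "footprint")

#: half of the 147-bp nucleosome core; the retained-edge anchor
CORE_HALF = 73

LENGTH_CLIP = (20, 200)


@dataclass(frozen=True)
class UnwrapStateSpec:
    """One unwrapping state: a fragment-length mode and a placement rule."""

    name: str
    length_mode: float
    length_sd: float
    placement: str
    weight: float

    def __post_init__(self) -> None:
        if not 20 <= self.length_mode <= 200:
            raise ValueError(f"{self.name}: length_mode must be in [20, 200]")
        if self.length_sd <= 0:
            raise ValueError(f"{self.name}: length_sd must be > 0")
        if self.placement not in PLACEMENTS:
            raise ValueError(f"{self.name}: unknown placement {self.placement!r}")
        if self.weight < 0:
            raise ValueError(f"{self.name}: weight must be >= 0")


def _check_mixture(states: Sequence[UnwrapStateSpec]) -> None:
    if not states:
        raise ValueError("mixture must contain at least one state")
    total = sum(s.weight for s in states)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"mixture weights must sum to 1, got {total}")


#: canonical-histone longMN mixture: intact core plus the four unwrapping
#: intermediates seen as FLP sub-peaks
CANONICAL_LONGMN: tuple[UnwrapStateSpec, ...] = (
    UnwrapStateSpec("core147", 147, 3.0, "symmetric", 0.45),
    UnwrapStateSpec("unwrap127", 127, 3.0, "symmetric", 0.20),
    UnwrapStateSpec("unwrap105", 105, 3.0, "symmetric", 0.15),
    UnwrapStateSpec("unwrap91", 91, 3.0, "symmetric", 0.12),
    UnwrapStateSpec("unwrap69", 69, 3.0, "symmetric", 0.08),
)

#: H2A.Z-like longMN mixture: dominant short-fragment (30-80 bp) protection,
#: far lower signal from longer fragments
H2AZ_LONGMN: tuple[UnwrapStateSpec, ...] = (
    UnwrapStateSpec("small55", 55, 8.0, "symmetric", 0.55),
    UnwrapStateSpec("unwrap91", 91, 3.0, "symmetric", 0.12),
    UnwrapStateSpec("unwrap105", 105, 3.0, "symmetric", 0.10),
    UnwrapStateSpec("unwrap127", 127, 3.0, "symmetric", 0.10),
    UnwrapStateSpec("core147", 147, 3.0, "symmetric", 0.13),
)

#: one representative state per fragment-length analysis group, used by the
#: landscape generators; modes sit centrally so boundary leakage is small
GROUP_STATES: tuple[UnwrapStateSpec, ...] = (
    UnwrapStateSpec("G80", 60, 8.0, "left_retained", 0.2),  # split left/right at draw
    UnwrapStateSpec("G100", 91, 4.0, "symmetric", 0.2),
    UnwrapStateSpec("G120", 110, 4.0, "symmetric", 0.2),
    UnwrapStateSpec("G140", 130, 4.0, "symmetric", 0.2),
    UnwrapStateSpec("G168", 150, 5.0, "symmetric", 0.2),
)

CLUSTER_NAMES = ("A", "B", "C", "D", "E")


def _draw_lengths(rng: np.random.Generator, mode: float, sd: float, n: int) -> np.ndarray:
    lengths = np.rint(rng.normal(mode, sd, size=n)).astype(np.int64)
    return np.clip(lengths, *LENGTH_CLIP)


def _place(
    dyads: np.ndarray, lengths: np.ndarray, placement: str
) -> tuple[np.ndarray, np.ndarray]:
    """Fragment [start, end) from dyad and length under a placement rule."""
    if placement in ("symmetric", "footprint"):
        starts = dyads - lengths // 2
    elif placement == "left_retained":
        starts = dyads - CORE_HALF
    elif placement == "right_retained":
        starts = dyads + CORE_HALF - lengths
    else:
        raise ValueError(f"unknown placement {placement!r}")
    return starts, starts + lengths


def sample_fragment(
    dyad: int,
    state: UnwrapStateSpec,
    rng: np.random.Generator,
    jitter_sd: float = 0.0,
    chrom: str = "chrS",
) -> Fragment:
    """Draw a single fragment from one unwrapping state at a dyad.

    Length ~ round(Normal(length_mode, length_sd)) clipped to [20, 200];
    dyad jitter (round(Normal(0, jitter_sd))) is added before placement.
    """
    if dyad < 100:
        raise ValueError("dyad must be >= 100 to keep fragments on-chromosome")
    d = dyad + (int(np.rint(rng.normal(0.0, jitter_sd))) if jitter_sd > 0 else 0)
    length = int(_draw_lengths(rng, state.length_mode, state.length_sd, 1)[0])
    starts, ends = _place(np.array([d]), np.array([length]), state.placement)
    return Fragment(chrom, int(starts[0]), int(ends[0]))


def simulate_histone_sample(
    mixture: Sequence[UnwrapStateSpec],
    n: int,
    seed: int,
    chrom: str = "chrS",
    chrom_length: int = 5_000_000,
    label: str = "histone-sim",
) -> FragmentSet:
    """Draw n fragments i.i.d. from a state mixture at uniform random dyads."""
    _check_mixture(mixture)
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    margin = 300
    dyads = rng.integers(margin, chrom_length - margin, size=n)
    weights = np.array([s.weight for s in mixture])
    counts = rng.multinomial(n, weights)
    starts = np.empty(n, dtype=np.int64)
    ends = np.empty(n, dtype=np.int64)
    at = 0
    for state, k in zip(mixture, counts):
        lengths = _draw_lengths(rng, state.length_mode, state.length_sd, k)
        s, e = _place(dyads[at : at + k], lengths, state.placement)
        starts[at : at + k], ends[at : at + k] = s, e
        at += k
    chroms = np.full(n, chrom, dtype=object)
    return FragmentSet(chroms, starts, ends, label=label)


@dataclass(frozen=True)
class LandscapeSpec:
    """Parameters of a simulated TSS or CBS chromatin landscape.

    Defaults emulate mouse-ES-like geometry: ~180-bp nucleosome repeat, an NDR
    with the first nucleosome ~120 bp from the anchor, modest dyad jitter, and
    Dirichlet-distributed five-group mixtures (concentration 50) around class
    means that over-weight one group by 0.45 (renormalized) — enough
    separation that the planted classes are distinguishable by clustering, as
    the five observed unwrapping classes are. Expression is linked to
    unwrapping through a tier-wise linear weight adjustment: the 30-80 bp
    weight falls and the 121-168 bp weights rise with expression tier
    (``tier_delta`` per tier step; the default reproduces rank correlations
    of roughly |rho| 0.2-0.3 between ratios and expression).
    """

    n_refpoints: int = 200
    spacing: int = 180
    ndr_halfwidth: int = 120
    dyad_jitter_sd: float = 8.0
    fragments_per_nucleosome: int = 300
    n_downstream: int = 3  # phased nucleosomes beyond +1 (TSS landscapes)
    n_flank: int = 2  # phased nucleosomes per side of a CBS
    footprint_weight: float = 0.1  # CBS-center footprint proportion
    fragile_weight: float = 0.0  # NDR "fragile" small-fragment proportion
    cluster_overweight: float = 0.45
    dirichlet_conc: float = 50.0
    tier_delta: float = 0.04
    expression_log_sd: float = 1.0
    flank_small_placement: str = "retained"  # or "symmetric"
    chrom: str = "chrS"
    chrom_length: int = 5_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if not 0 <= self.footprint_weight <= 1:
            raise ValueError("footprint_weight must be in [0, 1]")
        if self.flank_small_placement not in ("retained", "symmetric"):
            raise ValueError("flank_small_placement must be 'retained' or 'symmetric'")


@dataclass
class TssLandscape:
    """Simulated promoter landscape with planted unwrapping classes."""

    fragments: FragmentSet
    tss: list[ReferencePoint]
    nuc_centers: list[ReferencePoint]
    expression: pd.DataFrame
    truth: pd.DataFrame
    spec: LandscapeSpec

    def write(self, outdir: str | Path, prefix: str = "tss") -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fragments": outdir / f"{prefix}_fragments.bed",
            "tss": outdir / f"{prefix}_tss.bed",
            "nuc_centers": outdir / f"{prefix}_nuc_centers.bed",
            "expression": outdir / f"{prefix}_expression.tsv",
            "truth": outdir / f"{prefix}_truth.tsv",
        }
        write_fragments(self.fragments, paths["fragments"])
        write_reference_points(self.tss, paths["tss"])
        write_reference_points(self.nuc_centers, paths["nuc_centers"])
        write_expression_table(self.expression, paths["expression"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


@dataclass
class CbsLandscape:
    """Simulated CTCF-binding-site landscape with embedded consensus motifs."""

    fragments: FragmentSet
    cbs: list[ReferencePoint]
    peaks: list[GenomicInterval]
    sequence: dict[str, str]
    truth: pd.DataFrame
    spec: LandscapeSpec

    def write(self, outdir: str | Path, prefix: str = "cbs") -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fragments": outdir / f"{prefix}_fragments.bed",
            "cbs": outdir / f"{prefix}_sites.bed",
            "peaks": outdir / f"{prefix}_peaks.bed",
            "fasta": outdir / f"{prefix}_genome.fa",
            "truth": outdir / f"{prefix}_truth.tsv",
        }
        write_fragments(self.fragments, paths["fragments"])
        write_reference_points(self.cbs, paths["cbs"])
        with open(paths["peaks"], "w") as fh:
            for p in self.peaks:
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t0\t.\n")
        write_fasta(self.sequence, paths["fasta"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            fh.write("\n".join(textwrap.wrap(seq, width)) + "\n")


_BASE_WEIGHTS = np.array([0.40, 0.15, 0.15, 0.15, 0.15])
#: direction of the tier-wise weight adjustment: short fragments down,
#: long fragments up with increasing expression tier
_TIER_DIRECTION = np.array([-1.0, 0.0, 0.0, 0.5, 0.5])


def _class_mean(cluster_idx: int, overweight: float) -> np.ndarray:
    w = _BASE_WEIGHTS.copy()
    w[cluster_idx] += overweight
    return w / w.sum()


def _shift_weights(w: np.ndarray, shift: float) -> np.ndarray:
    """Move probability mass from the sub-120-bp groups to the 120+ groups."""
    if shift == 0:
        return w
    small, large = w[..., :3], w[..., 3:]
    small_sum = small.sum(axis=-1, keepdims=True)
    if shift < 0 or np.any(shift > small_sum + 1e-12):
        raise ValueError(
            f"shift must be in [0, mass of sub-120-bp states] (max {small_sum.min():.3f})"
        )
    out = np.concatenate(
        [
            small * (1 - shift / small_sum),
            large + shift * large / large.sum(axis=-1, keepdims=True),
        ],
        axis=-1,
    )
    if np.any(out < -1e-12):
        raise ValueError("weight shift produced an invalid mixture")
    return out


def _emit_nucleosome_fragments(
    rng: np.random.Generator,
    dyads: np.ndarray,
    counts: np.ndarray,
    jitter_sd: float,
    small_placement: str = "retained",
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized fragment draws for one nucleosome slot across all genes.

    ``counts`` is (n_sites, 5): per-site fragment counts for the five group
    states. G80 fragments split evenly between left- and right-retained
    placement (unless ``small_placement='symmetric'``); other groups are
    symmetric about the (jittered) dyad.
    """
    starts_parts: list[np.ndarray] = []
    ends_parts: list[np.ndarray] = []
    for g, state in enumerate(GROUP_STATES):
        n_g = int(counts[:, g].sum())
        if n_g == 0:
            continue
        rep_dyads = np.repeat(dyads, counts[:, g])
        if jitter_sd > 0:
            rep_dyads = rep_dyads + np.rint(rng.normal(0, jitter_sd, n_g)).astype(np.int64)
        lengths = _draw_lengths(rng, state.length_mode, state.length_sd, n_g)
        if g == 0 and small_placement == "retained":
            right = rng.random(n_g) < 0.5
            s = np.where(
                right, rep_dyads + CORE_HALF - lengths, rep_dyads - CORE_HALF
            )
            e = s + lengths
        else:
            s, e = _place(rep_dyads, lengths, "symmetric")
        starts_parts.append(s)
        ends_parts.append(e)
    if not starts_parts:
        return np.array([], dtype=np.int64), np.array([], dtype=np.int64)
    return np.concatenate(starts_parts), np.concatenate(ends_parts)


def simulate_tss_landscape(
    spec: LandscapeSpec, weight_shift: float = 0.0, label: str = "tss-sim"
) -> TssLandscape:
    """Simulate phased promoter nucleosome arrays with planted A-E classes.

    Each gene gets a TSS (alternating strand), an NDR, a +1 nucleosome dyad
    50-200 bp downstream, and ``n_downstream`` further dyads at the repeat
    spacing. Genes are assigned balanced planted classes A-E; the gene's
    five-group mixture is a Dirichlet draw around the class mean, then
    adjusted by expression tier (short-fragment weight down, long up). All
    nucleosomes of a gene share its mixture. ``weight_shift`` moves mixture
    mass from the sub-120-bp groups to the 120+ groups (knockdown emulation)
    without touching any layout draw.
    """
    if spec.n_refpoints < 10:
        raise ValueError("n_refpoints must be >= 10 for downstream analyses")
    n = spec.n_refpoints
    rng_layout = np.random.default_rng([spec.seed, 0])
    rng_frags = np.random.default_rng([spec.seed, 1])

    # --- layout: positions, strands, classes, expression, mixtures ---
    margin = 5_000
    stride = (spec.chrom_length - 2 * margin) // n
    if stride < 2 * (spec.ndr_halfwidth + (spec.n_downstream + 2) * spec.spacing):
        raise ValueError("chromosome too short for this many reference points")
    tss_pos = margin + stride * np.arange(n) + rng_layout.integers(0, stride // 4, n)
    strands = np.where(rng_layout.random(n) < 0.5, "+", "-")

    clusters = np.tile(np.arange(5), n // 5 + 1)[:n]
    clusters = rng_layout.permutation(clusters)

    expression = rng_layout.lognormal(mean=2.0, sigma=spec.expression_log_sd, size=n)
    tier = np.empty(n, dtype=int)  # 0 = low, 1 = medium, 2 = high tertile
    order = np.argsort(expression, kind="stable")
    tier[order] = np.arange(n) * 3 // n

    means = np.stack([_class_mean(c, spec.cluster_overweight) for c in clusters])
    w = np.stack([rng_layout.dirichlet(spec.dirichlet_conc * m) for m in means])
    w = w + spec.tier_delta * (tier[:, None] - 1) * _TIER_DIRECTION
    w = np.clip(w, 1e-4, None)
    w /= w.sum(axis=1, keepdims=True)
    w = _shift_weights(w, weight_shift)

    offsets = rng_layout.integers(50, 201, size=n)
    sign = np.where(strands == "+", 1, -1)
    plus1 = tss_pos + sign * offsets

    # --- fragments: per-slot multinomial counts then vectorized draws ---
    starts_parts: list[np.ndarray] = []
    ends_parts: list[np.ndarray] = []
    for slot in range(spec.n_downstream + 1):
        dyads = plus1 + sign * slot * spec.spacing
        counts = rng_frags.multinomial(spec.fragments_per_nucleosome, w)
        s, e = _emit_nucleosome_fragments(rng_frags, dyads, counts, spec.dyad_jitter_sd)
        starts_parts.append(s)
        ends_parts.append(e)
    n_fragile = int(round(spec.fragile_weight * spec.fragments_per_nucleosome))
    if n_fragile > 0:
        rep = np.repeat(tss_pos, n_fragile)
        lengths = _draw_lengths(rng_frags, 45, 8.0, len(rep))
        s, e = _place(rep, lengths, "footprint")
        starts_parts.append(s)
        ends_parts.append(e)

    starts = np.concatenate(starts_parts)
    ends = np.concatenate(ends_parts)
    frags = FragmentSet(
        np.full(len(starts), spec.chrom, dtype=object), starts, ends, label=label
    )

    gene_ids = [f"gene{i}" for i in range(n)]
    tss_points = [
        ReferencePoint(spec.chrom, int(p), s, "TSS", g)
        for p, s, g in zip(tss_pos, strands, gene_ids)
    ]
    nuc_centers = []
    for slot in range(spec.n_downstream + 1):
        dyads = plus1 + sign * slot * spec.spacing
        nuc_centers.extend(
            ReferencePoint(spec.chrom, int(d), "+", "NUC_CENTER", f"{g}_nuc{slot + 1}")
            for d, g in zip(dyads, gene_ids)
        )
    tier_names = np.array(["low", "medium", "high"])
    expr_df = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chrom": spec.chrom,
            "tss": tss_pos,
            "strand": strands,
            "expression": expression,
            "tier": tier_names[tier],
        }
    )
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "tss": tss_pos,
            "strand": strands,
            "plus1_dyad": plus1,
            "cluster": [CLUSTER_NAMES[c] for c in clusters],
            "tier": tier_names[tier],
            "expression": expression,
            **{f"w_{s.name}": w[:, j] for j, s in enumerate(GROUP_STATES)},
        }
    )
    return TssLandscape(frags, tss_points, nuc_centers, expr_df, truth, spec)


def simulate_knockdown(
    base: LandscapeSpec, shift: float = 0.2
) -> tuple[TssLandscape, TssLandscape]:
    """Paired wild-type / knockdown promoter landscapes.

    Both conditions share every layout draw (reference points, classes,
    expression) and RNG seeds; the knockdown differs only in its mixture
    weights, with ``shift`` probability mass moved from the sub-120-bp states
    to the 120+ states — the depletion phenotype of longer protected
    fragments. ``shift=0`` reproduces the wild type exactly.
    """
    wt = simulate_tss_landscape(base, weight_shift=0.0, label="wt")
    kd = simulate_tss_landscape(base, weight_shift=shift, label="kd")
    return wt, kd


#: CBS-flanking nucleosome mixture: half sub-nucleosomal (30-80 bp,
#: edge-retained -> bimodal centers), the rest intact or intermediate
_FLANK_SMALL = UnwrapStateSpec("flank55", 55, 5.0, "left_retained", 0.5)
_FLANK_STATES: tuple[tuple[UnwrapStateSpec, float], ...] = (
    (_FLANK_SMALL, 0.5),
    (UnwrapStateSpec("core147", 147, 3.0, "symmetric", 0.35), 0.35),
    (UnwrapStateSpec("unwrap105", 105, 4.0, "symmetric", 0.15), 0.15),
)


def simulate_cbs_landscape(spec: LandscapeSpec, label: str = "cbs-sim") -> CbsLandscape:
    """Simulate oriented CTCF sites with flanking phased nucleosomes.

    Each site embeds the 14-bp consensus (N drawn uniformly) on a random
    strand into the emitted genome sequence. Flanking nucleosome dyads sit at
    ``±(ndr_halfwidth + k*spacing)``; their sub-nucleosomal (30-80 bp)
    fragments are edge-retained (half left, half right), producing bimodal
    center modes around each dyad, unless ``flank_small_placement`` is
    "symmetric". Footprint fragments (30-55 bp) are centered on the CBS with
    proportion ``footprint_weight`` of a nucleosome's fragment count.
    """
    n = spec.n_refpoints
    rng_layout = np.random.default_rng([spec.seed, 2])
    rng_frags = np.random.default_rng([spec.seed, 3])

    margin = 5_000
    stride = (spec.chrom_length - 2 * margin) // n
    centers = margin + stride * np.arange(n) + rng_layout.integers(0, stride // 4, n)
    strands = np.where(rng_layout.random(n) < 0.5, "+", "-")

    # background sequence free of spurious consensus hits with overwhelming
    # probability (13 fixed positions: expected chance hits << 1 per 5 Mb)
    codes = rng_layout.integers(0, 4, spec.chrom_length).astype(np.uint8)
    seq = np.frombuffer(b"ACGT", dtype=np.uint8)[codes]
    half = len(CONSENSUS) // 2
    for c, s in zip(centers, strands):
        motif = CONSENSUS.replace("N", "ACGT"[rng_layout.integers(0, 4)])
        if s == "-":
            motif = revcomp(motif)
        seq[c - half : c - half + len(CONSENSUS)] = np.frombuffer(
            motif.encode(), dtype=np.uint8
        )
    sequence = {spec.chrom: seq.tobytes().decode()}

    starts_parts: list[np.ndarray] = []
    ends_parts: list[np.ndarray] = []
    small_placement = (
        "retained" if spec.flank_small_placement == "retained" else "symmetric"
    )
    flank_offsets = [
        side * (spec.ndr_halfwidth + k * spec.spacing)
        for side in (-1, 1)
        for k in range(spec.n_flank)
    ]
    for off in flank_offsets:
        dyads = centers + off
        counts = rng_frags.multinomial(
            spec.fragments_per_nucleosome,
            np.tile([w for _, w in _FLANK_STATES], (n, 1)),
        )
        for j, (state, _) in enumerate(_FLANK_STATES):
            n_j = int(counts[:, j].sum())
            if n_j == 0:
                continue
            rep = np.repeat(dyads, counts[:, j])
            if spec.dyad_jitter_sd > 0:
                rep = rep + np.rint(
                    rng_frags.normal(0, spec.dyad_jitter_sd, n_j)
                ).astype(np.int64)
            lengths = _draw_lengths(rng_frags, state.length_mode, state.length_sd, n_j)
            if state.name == "flank55" and small_placement == "retained":
                right = rng_frags.random(n_j) < 0.5
                s = np.where(right, rep + CORE_HALF - lengths, rep - CORE_HALF)
                e = s + lengths
            else:
                s, e = _place(rep, lengths, "symmetric")
            starts_parts.append(s)
            ends_parts.append(e)

    n_fp = int(round(spec.footprint_weight * spec.fragments_per_nucleosome))
    if n_fp > 0:
        rep = np.repeat(centers, n_fp)
        rep = rep + np.rint(rng_frags.normal(0, 3.0, len(rep))).astype(np.int64)
        lengths = np.clip(_draw_lengths(rng_frags, 42, 5.0, len(rep)), 30, 55)
        s, e = _place(rep, lengths, "footprint")
        starts_parts.append(s)
        ends_parts.append(e)

    starts = np.concatenate(starts_parts)
    ends = np.concatenate(ends_parts)
    frags = FragmentSet(
        np.full(len(starts), spec.chrom, dtype=object), starts, ends, label=label
    )

    names = [f"cbs{i}" for i in range(n)]
    cbs_points = [
        ReferencePoint(spec.chrom, int(c), s, "CBS", nm)
        for c, s, nm in zip(centers, strands, names)
    ]
    peaks = [
        GenomicInterval(spec.chrom, int(c) - 200, int(c) + 200, nm)
        for c, nm in zip(centers, names)
    ]
    truth = pd.DataFrame(
        {
            "cbs_id": names,
            "center": centers,
            "strand": strands,
            "left_flank_dyad": centers - spec.ndr_halfwidth,
            "right_flank_dyad": centers + spec.ndr_halfwidth,
        }
    )
    return CbsLandscape(frags, cbs_points, peaks, sequence, truth, spec)
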