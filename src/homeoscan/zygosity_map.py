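"""Zygosity segmentation, LOH ordering and generation estimates.

Between the two phased copies of each chromosome pair, window-level
divergence separates three states: heterozygous territory (the two parental
haplotypes, ~11% diverged), homozygous territory created by loss of
heterozygosity (LOH; near-identical copies with a low residual SNP density),
and hemizygous territory where one copy has no alignable counterpart.
Residual SNP density inside LOH blocks orders the LOH events in time (the
densest block has been re-accumulating polymorphism the longest) and, given
a per-site per-generation mutation rate, dates the onset of each event.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .allele_pairing import GenePair, PairAlignment
from .genome_io import GeneAnnotation

HETEROZYGOUS = "heterozygous"
HOMOZYGOUS = "homozygous"
HEMIZYGOUS = "hemizygous"


@dataclass
class WindowStats:
    starts: np.ndarray
    divergence: np.ndarray  # NaN where no aligned columns
    aligned_fraction: np.ndarray
    window_bp: int
    step_bp: int


def window_divergence(
    alignment: PairAlignment, window_bp: int = 10_000, step_bp: int = 1_000
) -> WindowStats:
    """Per-window divergence and aligned fraction on copy-1 coordinates.

    Divergence counts mismatched aligned columns over aligned columns; gap
    and N columns are excluded from both numerator and denominator.
    """
    L = len(alignment.aligned)
    ca = np.concatenate([[0], np.cumsum(alignment.aligned.astype(np.int64))])
    cm = np.concatenate([[0], np.cumsum(alignment.mismatch.astype(np.int64))])
    if L < window_bp:
        starts = np.array([0])
        ends = np.array([L])
    else:
        starts = np.arange(0, L - window_bp + 1, step_bp)
        ends = starts + window_bp
    aligned = ca[ends] - ca[starts]
    mism = cm[ends] - cm[starts]
    with np.errstate(divide="ignore", invalid="ignore"):
        div = np.where(aligned > 0, mism / np.maximum(aligned, 1), np.nan)
    frac = aligned / (ends - starts)
    return WindowStats(starts, div, frac, window_bp, step_bp)


@dataclass
class ZygositySegment:
    pair_id: str
    chromosome_id: str  # copy-1 chromosome
    start: int
    end: int
    label: str
    divergence: float
    aligned_fraction: float
    snp_per_10kb: Optional[float] = None

    @property
    def length(self) -> int:
        return self.end - self.start


def _label_windows(
    stats: WindowStats,
    homo_max: float,
    het_max: float,
    min_aligned: float,
) -> np.ndarray:
    """0 = heterozygous, 1 = homozygous, 2 = hemizygous, per window."""
    lab = np.zeros(len(stats.starts), dtype=np.int8)
    div = stats.divergence
    hemi = (stats.aligned_fraction < min_aligned) | ~np.isfinite(div) | (div > het_max)
    homo = ~hemi & (div < homo_max)
    lab[homo] = 1
    lab[hemi] = 2
    return lab


def _refine_junction(alignment: PairAlignment, coarse: int, radius: int) -> int:
    """Refine a junction to base precision by a two-rate change-point fit.

    Within +-radius of the coarse junction the mismatch process is modeled
    as Poisson with a different rate on each side; the split maximizing the
    profile log-likelihood over aligned positions is the junction.
    """
    L = len(alignment.aligned)
    lo = max(0, coarse - radius)
    hi = min(L, coarse + radius)
    al = alignment.aligned[lo:hi]
    mm = alignment.mismatch[lo:hi]
    idx = np.nonzero(al)[0]
    if idx.size < 10:
        return coarse
    y = mm[idx].astype(np.float64)
    n = y.size
    c = np.concatenate([[0.0], np.cumsum(y)])
    total = c[-1]
    ks = np.arange(1, n)
    left_counts = c[ks]
    right_counts = total - left_counts
    nl = ks.astype(np.float64)
    nr = n - nl
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(left_counts > 0, left_counts * np.log(left_counts / nl), 0.0) + np.where(
            right_counts > 0, right_counts * np.log(right_counts / nr), 0.0
        )
    k = int(ks[np.argmax(ll)])
    return int(lo + idx[k - 1] + 1)


def segment_zygosity(
    alignment: PairAlignment,
    stats: WindowStats,
    pair_id: str = "",
    chromosome_id: str = "",
    homo_max: float = 0.005,
    het_max: float = 0.25,
    min_aligned: float = 0.4,
    min_segment: int = 5_000,
    refine: bool = True,
) -> list[ZygositySegment]:
    """Partition a chromosome pair into het/homo/hemizygous segments.

    Windows are labeled individually, same-label runs merged, segments
    shorter than ``min_segment`` absorbed into the longer neighbor, and each
    junction refined to base precision with the alignment.
    """
    lab = _label_windows(stats, homo_max, het_max, min_aligned)
    L = len(alignment.aligned)
    # runs over window indices
    runs: list[tuple[int, int, int]] = []
    start = 0
    for i in range(1, len(lab) + 1):
        if i == len(lab) or lab[i] != lab[start]:
            runs.append((start, i, int(lab[start])))
            start = i
    # coarse junction = midpoint between the centers of the flanking windows
    bounds = [0]
    for (a_s, a_e, _), (b_s, _, _) in zip(runs, runs[1:]):
        c_left = stats.starts[a_e - 1] + stats.window_bp // 2
        c_right = stats.starts[b_s] + stats.window_bp // 2
        bounds.append(int((c_left + c_right) // 2))
    bounds.append(L)
    segs = [
        (bounds[i], bounds[i + 1], runs[i][2]) for i in range(len(runs))
        if bounds[i + 1] > bounds[i]
    ]
    # absorb short segments into the longer neighbor
    changed = True
    while changed and len(segs) > 1:
        changed = False
        for i, (s, e, lb) in enumerate(segs):
            if e - s >= min_segment:
                continue
            left_len = segs[i - 1][1] - segs[i - 1][0] if i > 0 else -1
            right_len = segs[i + 1][1] - segs[i + 1][0] if i < len(segs) - 1 else -1
            if left_len < 0 and right_len < 0:
                continue
            if left_len >= right_len:
                segs[i - 1] = (segs[i - 1][0], e, segs[i - 1][2])
            else:
                segs[i + 1] = (s, segs[i + 1][1], segs[i + 1][2])
            del segs[i]
            changed = True
            break
    # merge adjacent same-label segments
    merged: list[tuple[int, int, int]] = []
    for s, e, lb in segs:
        if merged and merged[-1][2] == lb:
            merged[-1] = (merged[-1][0], e, lb)
        else:
            merged.append((s, e, lb))
    # refine junctions between het and homo
    if refine:
        for i in range(len(merged) - 1):
            la, lb_ = merged[i][2], merged[i + 1][2]
            if {la, lb_} == {0, 1}:
                j = _refine_junction(alignment, merged[i][1], stats.window_bp)
                j = max(merged[i][0] + 1, min(merged[i + 1][1] - 1, j))
                merged[i] = (merged[i][0], j, la)
                merged[i + 1] = (j, merged[i + 1][1], lb_)
    names = {0: HETEROZYGOUS, 1: HOMOZYGOUS, 2: HEMIZYGOUS}
    out: list[ZygositySegment] = []
    ca = np.concatenate([[0], np.cumsum(alignment.aligned.astype(np.int64))])
    cm = np.concatenate([[0], np.cumsum(alignment.mismatch.astype(np.int64))])
    for s, e, lb in merged:
        aligned = int(ca[e] - ca[s])
        mism = int(cm[e] - cm[s])
        div = mism / aligned if aligned else float("nan")
        seg = ZygositySegment(
            pair_id=pair_id,
            chromosome_id=chromosome_id,
            start=int(s),
            end=int(e),
            label=names[lb],
            divergence=div,
            aligned_fraction=aligned / (e - s),
        )
        if seg.label == HOMOZYGOUS:
            seg.snp_per_10kb = loh_density(seg, alignment)
        out.append(seg)
    return out


def loh_density(segment: ZygositySegment, alignment: PairAlignment) -> float:
    """Residual SNP density of a homozygous segment, per 10 kb of aligned sites."""
    if segment.label != HOMOZYGOUS:
        raise ValueError("loh_density requires a homozygous segment")
    sl = slice(segment.start, segment.end)
    aligned = int(alignment.aligned[sl].sum())
    mism = int(alignment.mismatch[sl].sum())
    if aligned == 0:
        return float("nan")
    return mism / aligned * 1e4


@dataclass
class LohEvent:
    segment: ZygositySegment
    rank: int  # 1 = oldest (densest)
    snp_per_10kb: float
    tied: bool = False
    generations_estimate: Optional[float] = None


def order_loh_events(segments: Sequence[ZygositySegment]) -> list[LohEvent]:
    """Rank homozygous segments by residual SNP density (densest = oldest).

    Ties share a rank and are flagged.
    """
    homo = [s for s in segments if s.label == HOMOZYGOUS]
    if not homo:
        return []
    ordered = sorted(homo, key=lambda s: (-(s.snp_per_10kb or 0.0), s.pair_id, s.start))
    events: list[LohEvent] = []
    rank = 0
    prev_density: Optional[float] = None
    for i, seg in enumerate(ordered):
        d = seg.snp_per_10kb or 0.0
        if prev_density is None or d != prev_density:
            rank = i + 1
        events.append(LohEvent(seg, rank, d))
        prev_density = d
    densities = [e.snp_per_10kb for e in events]
    for e in events:
        e.tied = densities.count(e.snp_per_10kb) > 1
    return events


def estimate_generations(
    snp_per_site: float,
    mutation_rate_per_site_per_generation: float,
    ploidy_factor: int,
) -> float:
    """Generations since LOH onset from residual polymorphism.

    generations = d / (ploidy_factor * mu), with mu the per-site
    per-generation mutation rate and ploidy_factor in {1, 2} stating whether
    divergence accrues on one or both copies.  Both parameters are mandatory:
    published estimates of this kind depend entirely on that choice, so no
    silent default is provided.
    """
    if mutation_rate_per_site_per_generation <= 0:
        raise ValueError("mutation rate must be positive")
    if ploidy_factor not in (1, 2):
        raise ValueError("ploidy_factor must be 1 or 2")
    if snp_per_site == 0:
        warnings.warn("zero residual density: generations estimate is an upper bound of 0")
        return 0.0
    return snp_per_site / (ploidy_factor * mutation_rate_per_site_per_generation)


@dataclass
class JunctionAnnotation:
    pair_id: str
    position: int
    left_label: str
    right_label: str
    gene_id: Optional[str]
    gene_identity: Optional[float]
    flank_het_identity: Optional[float]


def junction_report(
    segments: Sequence[ZygositySegment],
    gene_pairs: Sequence[GenePair],
    alignment: PairAlignment,
    flank_bp: int = 50_000,
) -> list[JunctionAnnotation]:
    """Annotate het/homo junctions with the overlapping gene pair (if any).

    Reports the allele identity of the gene spanning each junction and, for
    contrast, the mean identity of the flanking 50 kb on the heterozygous
    side.
    """
    out: list[JunctionAnnotation] = []
    segs = sorted(segments, key=lambda s: s.start)
    for a, b in zip(segs, segs[1:]):
        if {a.label, b.label} != {HETEROZYGOUS, HOMOZYGOUS}:
            continue
        pos = a.end
        gene_id = None
        gene_ident = None
        for p in gene_pairs:
            if p.gene_2 is not None and p.gene_1.start <= pos < p.gene_1.end:
                gene_id = p.gene_1.gene_id
                gene_ident = p.nucleotide_identity
                break
        het_side = a if a.label == HETEROZYGOUS else b
        if het_side is a:
            lo, hi = max(a.start, pos - flank_bp), pos
        else:
            lo, hi = pos, min(b.end, pos + flank_bp)
        aligned = int(alignment.aligned[lo:hi].sum())
        mism = int(alignment.mismatch[lo:hi].sum())
        flank_ident = 1.0 - mism / aligned if aligned else None
        out.append(
            JunctionAnnotation(
                pair_id=a.pair_id,
                position=pos,
                left_label=a.label,
                right_label=b.label,
                gene_id=gene_id,
                gene_identity=gene_ident,
                flank_het_identity=flank_ident,
            )
        )
    return out
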