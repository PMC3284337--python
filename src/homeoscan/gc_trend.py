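"""Within-pair GC statistics: dGC, trend curves, polarity and exchanges.

The parental subgenomes of an allodiploid differ subtly in nucleotide
composition.  For every allelic gene pair the GC fractions of the two CDS
copies are compared through their ratio to the pair mean:

    dGC_1 = GC_1 / ((GC_1 + GC_2) / 2),   dGC_2 = GC_2 / ((GC_1 + GC_2) / 2)

so dGC_1 + dGC_2 = 2 always, identical alleles give exactly (1, 1), and the
GC-richer allele has dGC > 1.  An 11-gene moving average of dGC along each
chromosome separates the two copies into a GC-richer track (parent "Pgamma")
and a GC-poorer track ("Pepsilon"); a stable swap of the two trend curves
marks a reciprocal inter-homeolog exchange.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .allele_pairing import GenePair

P_GAMMA = "Pgamma"
P_EPSILON = "Pepsilon"
UNDETERMINED = "undetermined"


def gc_fraction(seq: str) -> float:
    """GC fraction of a sequence; N bases are excluded from the denominator."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    gc = int(((arr == ord("G")) | (arr == ord("C"))).sum())
    denom = int((arr != ord("N")).sum())
    if denom == 0:
        return float("nan")
    return gc / denom


def compute_dgc(gc_1: float, gc_2: float) -> tuple[float, float]:
    """Normalized within-pair GC ratios (dGC_1, dGC_2)."""
    if gc_1 + gc_2 <= 0:
        raise ValueError("degenerate gene pair: GC_1 + GC_2 = 0")
    if gc_1 == gc_2:
        return 1.0, 1.0
    mean = (gc_1 + gc_2) / 2.0
    return gc_1 / mean, gc_2 / mean


@dataclass
class DgcValue:
    gene_pair_id: str
    dgc_1: float
    dgc_2: float
    anchor_position: int  # start codon coordinate on the anchoring copy


def dgc_values(
    pairs: Sequence[GenePair],
    genome=None,
    anchor_copy: int = 1,
) -> list[DgcValue]:
    """Per-gene-pair dGC values ordered along the anchoring chromosome copy.

    Alleles that are identical at the nucleotide level get the identity
    relation dGC_1 = dGC_2 = 1 regardless of sampling noise in GC.
    """
    vals: list[DgcValue] = []
    for p in pairs:
        if p.gene_2 is None:
            continue
        anchor_gene = p.gene_1 if anchor_copy == 1 else p.gene_2
        anchor = anchor_gene.start if anchor_gene.strand == "+" else anchor_gene.end
        if p.nucleotide_identity == 1.0:
            d1 = d2 = 1.0
        else:
            d1, d2 = compute_dgc(p.gc_1, p.gc_2)
        vals.append(DgcValue(p.gene_1.gene_id, d1, d2, anchor))
    vals.sort(key=lambda v: v.anchor_position)
    return vals


@dataclass
class TrendCurve:
    """Moving-average dGC curves for one chromosome pair."""

    positions: np.ndarray  # anchor coordinate of each window's central gene
    dgc_1: np.ndarray
    dgc_2: np.ndarray
    window: int
    step: int

    def __len__(self) -> int:
        return len(self.positions)


def build_trend_curve(
    values: Sequence[DgcValue], window: int = 11, step: int = 1
) -> TrendCurve:
    """Unweighted moving average of dGC over ``window`` adjacent genes.

    Each output point is anchored at the central gene of its window (the
    6th of 11 by default).
    """
    n = len(values)
    if n < window:
        if n:
            warnings.warn(f"fewer than {window} dGC values: empty trend curve")
        empty = np.empty(0)
        return TrendCurve(empty.astype(int), empty, empty, window, step)
    d1 = np.array([v.dgc_1 for v in values])
    d2 = np.array([v.dgc_2 for v in values])
    pos = np.array([v.anchor_position for v in values])
    kernel = np.ones(window) / window
    m1 = np.convolve(d1, kernel, mode="valid")[::step]
    m2 = np.convolve(d2, kernel, mode="valid")[::step]
    centers = pos[window // 2 : n - (window - 1 - window // 2)][::step]
    return TrendCurve(centers, m1, m2, window, step)


@dataclass
class PolarityCall:
    copy_1: str
    copy_2: str
    mean_dgc_1: float
    mean_dgc_2: float
    separation: float  # |mean difference| / pooled s.d.


def assign_polarity(
    curve: TrendCurve,
    region_interval: tuple[int, int],
    min_genes: int = 20,
    epsilon: float = 0.001,
) -> PolarityCall:
    """Label the two copies of a heterozygous region Pgamma/Pepsilon.

    The copy whose mean smoothed dGC over the region exceeds 1 is the
    GC-richer parent Pgamma.  Regions where both means sit within
    ``epsilon`` of 1 are undetermined (homozygous-like).
    """
    start, end = region_interval
    mask = (curve.positions >= start) & (curve.positions < end)
    if int(mask.sum()) == 0:
        raise ValueError("region overlaps no trend-curve points")
    if int(mask.sum()) < min_genes:
        warnings.warn(
            f"region [{start},{end}) overlaps only {int(mask.sum())} curve points"
        )
    m1 = float(curve.dgc_1[mask].mean())
    m2 = float(curve.dgc_2[mask].mean())
    sd = float(np.sqrt((curve.dgc_1[mask].var() + curve.dgc_2[mask].var()) / 2.0))
    sep = abs(m1 - m2) / sd if sd > 0 else float("inf")
    if abs(m1 - 1.0) < epsilon and abs(m2 - 1.0) < epsilon:
        return PolarityCall(UNDETERMINED, UNDETERMINED, m1, m2, sep)
    if m1 > m2:
        return PolarityCall(P_GAMMA, P_EPSILON, m1, m2, sep)
    return PolarityCall(P_EPSILON, P_GAMMA, m1, m2, sep)


@dataclass
class GcProfile:
    chromosome_id: str
    window_starts: np.ndarray
    gc: np.ndarray
    window_bp: int
    step_bp: int


def gc_profile(
    sequence: str,
    window_bp: int = 10_000,
    step_bp: int = 1_000,
    chromosome_id: str = "",
) -> GcProfile:
    """Sliding-window GC fraction along a sequence (N excluded)."""
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    L = len(arr)
    if L < window_bp:
        return GcProfile(
            chromosome_id, np.empty(0, dtype=int), np.empty(0), window_bp, step_bp
        )
    isgc = ((arr == ord("G")) | (arr == ord("C"))).astype(np.int64)
    isn = (arr == ord("N")).astype(np.int64)
    cg = np.concatenate([[0], np.cumsum(isgc)])
    cn = np.concatenate([[0], np.cumsum(isn)])
    starts = np.arange(0, L - window_bp + 1, step_bp)
    gc_counts = cg[starts + window_bp] - cg[starts]
    denom = window_bp - (cn[starts + window_bp] - cn[starts])
    with np.errstate(divide="ignore", invalid="ignore"):
        gc = np.where(denom > 0, gc_counts / np.maximum(denom, 1), np.nan)
    return GcProfile(chromosome_id, starts, gc, window_bp, step_bp)


@dataclass
class ExchangeBreakpoint:
    """A trend-curve swap: interval between the flanking genes' anchors."""

    start: int
    end: int
    left_sign: int
    right_sign: int
    left_index: int  # curve index of the last point of the left run
    right_index: int


def detect_trend_exchange(
    curve: TrendCurve,
    min_run: int = 40,
    min_amplitude: float = 0.0035,
    zero_eps: float = 1e-9,
) -> list[ExchangeBreakpoint]:
    """Detect reciprocal-exchange breakpoints as stable trend-curve swaps.

    The signed difference s(i) = dGC_1(i) - dGC_2(i) is partitioned into
    maximal runs of constant sign.  Runs of at least ``min_run`` points with
    mean |s| >= ``min_amplitude`` are anchors; a breakpoint is emitted
    between consecutive anchors of opposite sign.  Short sign flips and
    low-amplitude stretches are noise; long near-zero (homozygous) stretches
    separate anchors without creating a breakpoint.
    """
    if len(curve) == 0:
        return []
    s = curve.dgc_1 - curve.dgc_2
    sign = np.zeros(len(s), dtype=np.int8)
    sign[s > zero_eps] = 1
    sign[s < -zero_eps] = -1
    # maximal runs
    runs: list[tuple[int, int, int]] = []  # (start, end, sign)
    start = 0
    for i in range(1, len(sign) + 1):
        if i == len(sign) or sign[i] != sign[start]:
            runs.append((start, i, int(sign[start])))
            start = i
    anchors: list[tuple[int, int, int]] = []
    neutral_blocks: set[int] = set()  # run indices of long zero stretches
    for ridx, (rs, re, sg) in enumerate(runs):
        if sg == 0 and re - rs >= min_run:
            neutral_blocks.add(ridx)
        if sg != 0 and re - rs >= min_run:
            if float(np.abs(s[rs:re]).mean()) >= min_amplitude:
                anchors.append((rs, re, sg))
    breakpoints: list[ExchangeBreakpoint] = []
    for (a_s, a_e, a_sign), (b_s, b_e, b_sign) in zip(anchors, anchors[1:]):
        if a_sign == b_sign:
            continue
        # a long homozygous stretch between the anchors is not an exchange
        separated = any(
            a_e <= runs[r][0] and runs[r][1] <= b_s for r in neutral_blocks
        )
        if separated:
            continue
        breakpoints.append(
            ExchangeBreakpoint(
                start=int(curve.positions[a_e - 1]),
                end=int(curve.positions[b_s]),
                left_sign=a_sign,
                right_sign=b_sign,
                left_index=a_e - 1,
                right_index=b_s,
            )
        )
    return breakpoints
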