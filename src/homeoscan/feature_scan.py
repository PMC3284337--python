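"""Centromere-island calling and NUMT detection.

Centromeres of CTG-clade yeasts lack point sequences; instead each
chromosome carries a single short, gene-free island of markedly reduced GC
content.  The scanner flags maximal runs of GC-poor windows, merges runs
across short interruptions, and filters by length and gene overlap.

NUMTs (nuclear sequences of mitochondrial origin) are found by homology to
the organism's own mitochondrial genome with an exact k-mer seed /
ungapped-extension search on both strands, then classified hemizygous or
biallelic according to whether the allelic position on the partner
chromosome carries an overlapping hit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .allele_pairing import PairAlignment
from .gc_trend import UNDETERMINED, gc_profile
from .genome_io import GeneAnnotation, Genome, reverse_complement

# ---------------------------------------------------------------------------
# Centromere candidates
# ---------------------------------------------------------------------------


@dataclass
class CentromereCandidate:
    chromosome_id: str
    start: int
    end: int
    gc_deficit: float  # percent below chromosome-global GC (relative)
    mean_gc: float
    global_gc: float
    gene_free: bool
    unique: bool = True
    partner_start: Optional[int] = None
    partner_end: Optional[int] = None

    @property
    def length_bp(self) -> int:
        return self.end - self.start


def scan_centromeres(
    sequence: str,
    genes: Sequence[GeneAnnotation],
    chromosome_id: str = "",
    window_bp: int = 1_000,
    step_bp: int = 200,
    rel_deficit: float = 0.08,
    merge_gap: int = 600,
    min_len: int = 1_500,
    max_len: int = 5_000,
) -> list[CentromereCandidate]:
    """Call candidate centromeres as unique gene-free GC-poor islands.

    Windows with GC <= (1 - rel_deficit) * global GC are flagged; maximal
    flagged runs closer than ``merge_gap`` are merged; candidates must fall
    in [min_len, max_len] and overlap no gene.  If more than one candidate
    survives on a chromosome, all are reported flagged non-unique.
    """
    prof = gc_profile(sequence, window_bp, step_bp, chromosome_id)
    if len(prof.gc) == 0:
        return []
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    denom = int((arr != ord("N")).sum())
    global_gc = float(((arr == ord("G")) | (arr == ord("C"))).sum() / denom) if denom else float("nan")
    threshold = (1.0 - rel_deficit) * global_gc
    low = prof.gc <= threshold
    # maximal runs of low windows -> base intervals
    intervals: list[tuple[int, int]] = []
    i = 0
    while i < len(low):
        if low[i]:
            j = i
            while j + 1 < len(low) and low[j + 1]:
                j += 1
            intervals.append(
                (int(prof.window_starts[i]), int(prof.window_starts[j]) + window_bp)
            )
            i = j + 1
        else:
            i += 1
    merged: list[tuple[int, int]] = []
    for s, e in intervals:
        if merged and s - merged[-1][1] <= merge_gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    cands: list[CentromereCandidate] = []
    for s, e in merged:
        if not (min_len <= e - s <= max_len):
            continue
        gene_free = not any(g.start < e and g.end > s for g in genes)
        if not gene_free:
            continue
        sub = arr[s:e]
        sub_denom = int((sub != ord("N")).sum())
        mean_gc = float(((sub == ord("G")) | (sub == ord("C"))).sum() / sub_denom) if sub_denom else float("nan")
        if not mean_gc < global_gc:
            continue
        cands.append(
            CentromereCandidate(
                chromosome_id=chromosome_id,
                start=s,
                end=e,
                gc_deficit=100.0 * (global_gc - mean_gc) / global_gc,
                mean_gc=mean_gc,
                global_gc=global_gc,
                gene_free=True,
            )
        )
    if len(cands) > 1:
        for c in cands:
            c.unique = False
    return cands


def match_centromere_pairs(
    candidates_copy1: Sequence[CentromereCandidate],
    candidates_copy2: Sequence[CentromereCandidate],
    alignment: PairAlignment,
    max_offset: int = 50_000,
) -> list[tuple[CentromereCandidate, Optional[CentromereCandidate]]]:
    """Match candidate islands at equivalent positions on the two copies.

    A copy-1 candidate is matched to the copy-2 candidate whose midpoint is
    within ``max_offset`` of its alignment-projected position; unmatched
    candidates keep a None partner.
    """
    out: list[tuple[CentromereCandidate, Optional[CentromereCandidate]]] = []
    used: set[int] = set()
    for c1 in candidates_copy1:
        proj = alignment.project_interval(
            max(0, c1.start - max_offset), min(len(alignment.aligned), c1.end + max_offset)
        )
        best = None
        best_d = None
        if proj is not None:
            target_mid = (proj[0] + proj[1]) / 2
            for k, c2 in enumerate(candidates_copy2):
                if k in used:
                    continue
                d = abs((c2.start + c2.end) / 2 - target_mid)
                if d <= max_offset and (best_d is None or d < best_d):
                    best, best_d = k, d
        if best is not None:
            used.add(best)
            c2 = candidates_copy2[best]
            c1.partner_start, c1.partner_end = c2.start, c2.end
            out.append((c1, c2))
        else:
            out.append((c1, None))
    return out


# ---------------------------------------------------------------------------
# NUMT detection
# ---------------------------------------------------------------------------


@dataclass
class NumtHit:
    chromosome_id: str
    start: int
    end: int
    mito_start: int
    mito_end: int
    strand: str  # '+' or '-' relative to the mitochondrial genome
    identity: float
    state: Optional[str] = None  # 'hemizygous' | 'biallelic'

    @property
    def length_bp(self) -> int:
        return self.end - self.start


HEMIZYGOUS_NUMT = "hemizygous"
BIALLELIC_NUMT = "biallelic"

_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _kmer_codes(arr2: np.ndarray, k: int) -> np.ndarray:
    """Rolling 2-bit k-mer codes; -1 where the window contains a non-ACGT base."""
    L = len(arr2)
    if L < k:
        return np.empty(0, dtype=np.int64)
    codes = np.zeros(L - k + 1, dtype=np.int64)
    for j in range(k):
        codes = codes * 4 + np.where(arr2[j : L - k + 1 + j] >= 0, arr2[j : L - k + 1 + j], 0)
    bad = np.zeros(L - k + 1, dtype=bool)
    invalid = (arr2 < 0).astype(np.int64)
    ci = np.concatenate([[0], np.cumsum(invalid)])
    bad = (ci[k:] - ci[:-k]) > 0
    return np.where(bad, -1, codes)


def extend_seed(
    nuc: np.ndarray,
    ref: np.ndarray,
    i: int,
    j: int,
    k: int,
    min_identity: float,
    tail_window: int = 30,
) -> tuple[int, int, int]:
    """Ungapped extension of an exact k-mer seed.

    Extends in both directions one base at a time, stopping when the
    identity over the trailing ``tail_window`` bases drops below
    ``min_identity``; trailing mismatches are then trimmed.  Returns
    (nuc_start, nuc_end, matches) of the extended ungapped segment.
    """

    def run(direction: int) -> int:
        # returns number of extra bases kept beyond the seed in `direction`
        outcomes: list[bool] = []
        kept = 0
        t = 0
        while True:
            t += 1
            if direction > 0:
                ni, ri = i + k - 1 + t, j + k - 1 + t
            else:
                ni, ri = i - t, j - t
            if ni < 0 or ri < 0 or ni >= len(nuc) or ri >= len(ref):
                break
            match = nuc[ni] >= 0 and nuc[ni] == ref[ri]
            outcomes.append(bool(match))
            window = outcomes[-tail_window:]
            if sum(window) / len(window) < min_identity:
                break
        # trim trailing mismatches
        while outcomes and not outcomes[-1]:
            outcomes.pop()
        return len(outcomes)

    right = run(+1)
    left = run(-1)
    s, e = i - left, i + k + right
    matches = int((nuc[s:e] == ref[j - left : j - left + (e - s)]).sum())
    return s, e, matches


def scan_numts(
    genome: Genome,
    mito_sequence: str,
    min_len: int = 50,
    min_identity: float = 0.8,
    k: int = 12,
    max_gap: int = 40,
) -> list[NumtHit]:
    """Seed-and-extend search for mitochondrial fragments in the nucleus.

    Exact ``k``-mer seeds on both strands of the (circular) mitochondrial
    genome are extended without gaps until the identity over a 30-bp sliding
    tail drops below ``min_identity``; extended segments of at least
    ``min_len`` are kept, and same-strand hits separated by at most
    ``max_gap`` bases are chained into one hit.
    """
    L = len(mito_sequence)
    ext = mito_sequence + mito_sequence[: min_len - 1]  # circular origin
    refs = {"+": ext, "-": reverse_complement(ext)}
    index: dict[int, list[tuple[int, str]]] = {}
    ref_arrays: dict[str, np.ndarray] = {}
    for strand, seq in refs.items():
        arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        ref_arrays[strand] = arr
        for pos, code in enumerate(_kmer_codes(arr, k)):
            if code >= 0:
                index.setdefault(int(code), []).append((pos, strand))
    hits: list[NumtHit] = []
    key_arr = np.fromiter(index.keys(), dtype=np.int64, count=len(index))
    for chrom_id in genome.chromosomes:
        nuc = _CODE[genome.seq_array(chrom_id)]
        codes = _kmer_codes(nuc, k)
        cand = np.nonzero(np.isin(codes, key_arr))[0]
        raw: list[NumtHit] = []
        covered: dict[str, list[tuple[int, int]]] = {"+": [], "-": []}
        for i in cand:
            code = int(codes[i])
            for j, strand in index[code]:
                if any(s <= i < e for s, e in covered[strand]):
                    continue
                s, e, matches = extend_seed(
                    nuc, ref_arrays[strand], int(i), j, k, min_identity
                )
                ident = matches / (e - s)
                if e - s >= min_len and ident >= min_identity:
                    rj = j - (int(i) - s)  # ref start of the segment
                    if strand == "+":
                        ms, me = rj, rj + (e - s)
                    else:  # map back to forward mitochondrial coordinates
                        ms, me = len(ext) - (rj + (e - s)), len(ext) - rj
                    raw.append(
                        NumtHit(
                            chromosome_id=chrom_id,
                            start=s,
                            end=e,
                            mito_start=ms,
                            mito_end=me,
                            strand=strand,
                            identity=ident,
                        )
                    )
                    covered[strand].append((s, e))
        hits.extend(_chain_hits(raw, L, max_gap))
    return hits


def _chain_hits(raw: list[NumtHit], mito_len: int, max_gap: int) -> list[NumtHit]:
    """Chain same-strand hits whose nuclear intervals overlap or nearly touch."""
    out: list[NumtHit] = []
    for strand in ("+", "-"):
        part = sorted(
            (h for h in raw if h.strand == strand), key=lambda h: (h.start, h.end)
        )
        for h in part:
            if out and out[-1].strand == strand and h.start - out[-1].end <= max_gap:
                prev = out[-1]
                total = (prev.end - prev.start) + (h.end - h.start)
                ident = (
                    prev.identity * (prev.end - prev.start)
                    + h.identity * (h.end - h.start)
                ) / total
                prev.end = max(prev.end, h.end)
                prev.mito_start = min(prev.mito_start, h.mito_start)
                prev.mito_end = max(prev.mito_end, h.mito_end)
                prev.identity = ident
            else:
                out.append(
                    NumtHit(
                        h.chromosome_id,
                        h.start,
                        h.end,
                        h.mito_start,
                        h.mito_end,
                        strand,
                        h.identity,
                    )
                )
    for h in out:
        # circular genome: keep start in [0, mito_len); end > mito_len wraps
        if h.mito_start >= mito_len:
            h.mito_start -= mito_len
            h.mito_end -= mito_len
    return sorted(out, key=lambda h: (h.chromosome_id, h.start))


def classify_numt_states(
    hits: Sequence[NumtHit],
    genome: Genome,
    alignments: dict[str, PairAlignment],
    slack: int = 100,
) -> None:
    """Label each hit hemizygous or biallelic via the partner chromosome.

    A hit is biallelic when the alignment-projected allelic interval on the
    partner chromosome (padded by ``slack``) overlaps a hit there; otherwise
    it is hemizygous.
    """
    by_chrom: dict[str, list[NumtHit]] = {}
    for h in hits:
        by_chrom.setdefault(h.chromosome_id, []).append(h)
    for h in hits:
        chrom = genome.chromosomes[h.chromosome_id]
        aln = alignments[chrom.pair_id]
        if chrom.copy_index == 1:
            proj = aln.project_interval(h.start, h.end)
            partner_id = aln.chrom2_id
        else:
            rev = aln.c1pos()
            sub = rev[h.start : h.end]
            sub = sub[sub >= 0]
            proj = (int(sub.min()), int(sub.max()) + 1) if sub.size else None
            partner_id = aln.chrom1_id
        h.state = HEMIZYGOUS_NUMT
        if proj is not None:
            lo, hi = proj[0] - slack, proj[1] + slack
            for other in by_chrom.get(partner_id, []):
                if other.start < hi and other.end > lo:
                    h.state = BIALLELIC_NUMT
                    break


@dataclass
class NumtAsymmetry:
    counts: dict[str, int]
    n_loci: int
    ratio: Optional[float]  # epsilon / gamma; None when gamma count is 0
    infinite: bool = False


def numt_asymmetry(
    hits: Sequence[NumtHit],
    genome: Genome,
    alignments: dict[str, PairAlignment],
    origin_of: Callable[[str, int], str],
) -> NumtAsymmetry:
    """Per-subgenome NUMT locus counts and the epsilon:gamma ratio.

    Biallelic twin hits on the two copies are counted as a single locus;
    hits in regions of undetermined subgenome are tallied separately.
    """
    from .gc_trend import P_EPSILON, P_GAMMA

    counts = {P_GAMMA: 0, P_EPSILON: 0, UNDETERMINED: 0}
    n_loci = 0
    for h in hits:
        chrom = genome.chromosomes[h.chromosome_id]
        if h.state == BIALLELIC_NUMT and chrom.copy_index == 2:
            continue  # counted once via the copy-1 twin
        n_loci += 1
        label = origin_of(h.chromosome_id, (h.start + h.end) // 2)
        counts[label] = counts.get(label, 0) + 1
    gamma, eps = counts[P_GAMMA], counts[P_EPSILON]
    if gamma == 0:
        return NumtAsymmetry(counts, n_loci, None, infinite=eps > 0)
    return NumtAsymmetry(counts, n_loci, eps / gamma, infinite=False)
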