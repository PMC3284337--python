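"""Syntenic allele pairing and allele/chromosome alignment.

Each chromosome pair of an allodiploid carries two allelic copies of nearly
every gene in conserved (collinear) order.  This module establishes the
partial one-to-one matching between the two gene lists (synteny-first,
identity-second), aligns allele sequences, and builds an anchored piecewise
whole-chromosome alignment that every downstream window statistic consumes.

Global allele alignment uses affine gap scoring: match +1, mismatch -1,
gap open -2 (first gap base), gap extend -1 (each further base).  Ties are
broken deterministically: diagonal (match/mismatch) over a gap placed in
seq1, over a gap placed in seq2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import edlib
import numpy as np
from numba import njit

from .genome_io import GeneAnnotation, Genome

MATCH = 1.0
MISMATCH = -1.0
GAP_OPEN = -2.0
GAP_EXTEND = -1.0

NEG_INF = -1e18


# ---------------------------------------------------------------------------
# Global affine alignment (Gotoh, canonical tie-break)
# ---------------------------------------------------------------------------

# Pointer codes: which matrix the predecessor came from.
_FROM_M, _FROM_Y, _FROM_X = 0, 1, 2


@njit(cache=True)
def _gotoh(a: np.ndarray, b: np.ndarray):  # pragma: no cover - exercised via wrapper
    n, m = a.shape[0], b.shape[0]
    M = np.full((n + 1, m + 1), NEG_INF)
    X = np.full((n + 1, m + 1), NEG_INF)  # gap in seq2: consumes a[i-1]
    Y = np.full((n + 1, m + 1), NEG_INF)  # gap in seq1: consumes b[j-1]
    PM = np.zeros((n + 1, m + 1), dtype=np.uint8)
    PX = np.zeros((n + 1, m + 1), dtype=np.uint8)
    PY = np.zeros((n + 1, m + 1), dtype=np.uint8)
    M[0, 0] = 0.0
    for j in range(1, m + 1):
        Y[0, j] = GAP_OPEN + GAP_EXTEND * (j - 1)
        PY[0, j] = _FROM_M if j == 1 else _FROM_Y
    for i in range(1, n + 1):
        X[i, 0] = GAP_OPEN + GAP_EXTEND * (i - 1)
        PX[i, 0] = _FROM_M if i == 1 else _FROM_X
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = MATCH if ai == b[j - 1] and ai != 78 else MISMATCH  # 78 = 'N'
            # M: predecessors in preference order M, Y, X
            best = M[i - 1, j - 1]
            ptr = _FROM_M
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                ptr = _FROM_Y
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                ptr = _FROM_X
            M[i, j] = best + s
            PM[i, j] = ptr
            # Y (gap in seq1, consumes b): preference M, Y(extend), X
            best = M[i, j - 1] + GAP_OPEN
            ptr = _FROM_M
            if Y[i, j - 1] + GAP_EXTEND > best:
                best = Y[i, j - 1] + GAP_EXTEND
                ptr = _FROM_Y
            if X[i, j - 1] + GAP_OPEN > best:
                best = X[i, j - 1] + GAP_OPEN
                ptr = _FROM_X
            Y[i, j] = best
            PY[i, j] = ptr
            # X (gap in seq2, consumes a): preference M, Y, X(extend)
            best = M[i - 1, j] + GAP_OPEN
            ptr = _FROM_M
            if Y[i - 1, j] + GAP_OPEN > best:
                best = Y[i - 1, j] + GAP_OPEN
                ptr = _FROM_Y
            if X[i - 1, j] + GAP_EXTEND > best:
                best = X[i - 1, j] + GAP_EXTEND
                ptr = _FROM_X
            X[i, j] = best
            PX[i, j] = ptr
    return M, X, Y, PM, PX, PY


@dataclass
class AlleleAlignment:
    """Result of a global allele alignment."""

    score: float
    columns: int  # total alignment columns (incl. gap columns)
    matches: int
    mismatches: int
    gap_columns: int
    n_columns: int  # columns containing N (excluded from identity)
    identity: float
    # per-column operation string over {'M','X','I','D'}: M match, X mismatch,
    # I consumes seq1 only, D consumes seq2 only
    ops: str


def align_alleles(seq_1: str, seq_2: str) -> AlleleAlignment:
    """Globally align two allele sequences with affine gap penalties.

    Identity is matches / alignment columns, where columns containing an N
    are excluded from both numerator and denominator.
    """
    if not seq_1 or not seq_2:
        raise ValueError("align_alleles requires non-empty sequences")
    a = np.frombuffer(seq_1.encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(seq_2.encode("ascii"), dtype=np.uint8)
    M, X, Y, PM, PX, PY = _gotoh(a, b)
    n, m = len(a), len(b)
    # final state preference M, Y, X
    state = _FROM_M
    best = M[n, m]
    if Y[n, m] > best:
        best, state = Y[n, m], _FROM_Y
    if X[n, m] > best:
        best, state = X[n, m], _FROM_X
    score = float(best)
    i, j = n, m
    ops_rev: list[str] = []
    matches = mismatches = n_cols = 0
    while i > 0 or j > 0:
        if state == _FROM_M:
            prev = PM[i, j]
            ca, cb = seq_1[i - 1], seq_2[j - 1]
            if ca == "N" or cb == "N":
                n_cols += 1
                ops_rev.append("X")
            elif ca == cb:
                matches += 1
                ops_rev.append("M")
            else:
                mismatches += 1
                ops_rev.append("X")
            i -= 1
            j -= 1
            state = prev
        elif state == _FROM_Y:
            prev = PY[i, j]
            ops_rev.append("D")
            j -= 1
            state = prev
        else:
            prev = PX[i, j]
            ops_rev.append("I")
            i -= 1
            state = prev
    ops = "".join(reversed(ops_rev))
    columns = len(ops)
    gap_columns = ops.count("I") + ops.count("D")
    denom = columns - n_cols
    identity = matches / denom if denom > 0 else float("nan")
    return AlleleAlignment(
        score=score,
        columns=columns,
        matches=matches,
        mismatches=mismatches,
        gap_columns=gap_columns,
        n_columns=n_cols,
        identity=identity,
        ops=ops,
    )


# ---------------------------------------------------------------------------
# Fast identity estimates (screening / indel-free fast path)
# ---------------------------------------------------------------------------


def hamming_identity(seq_1: str, seq_2: str) -> float:
    """Ungapped identity of two equal-length sequences, N columns excluded."""
    a = np.frombuffer(seq_1.encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(seq_2.encode("ascii"), dtype=np.uint8)
    if a.shape != b.shape:
        raise ValueError("hamming_identity requires equal lengths")
    nmask = (a == ord("N")) | (b == ord("N"))
    denom = int((~nmask).sum())
    if denom == 0:
        return float("nan")
    return float(((a == b) & ~nmask).sum() / denom)


def quick_identity(seq_1: str, seq_2: str, floor: float = 0.0) -> float:
    """Cheap identity estimate used for pairing eligibility.

    Equal-length, modestly diverged sequences are compared ungapped; other
    cases use an edit-distance bound (edlib) with early bail-out when the
    identity cannot reach ``floor``.  Returns 0.0 when below the floor.
    """
    la, lb = len(seq_1), len(seq_2)
    if la == lb:
        ident = hamming_identity(seq_1, seq_2)
        if ident >= 0.7:
            return ident
    if min(la, lb) / max(la, lb) < floor:
        return 0.0
    k = int((1.0 - floor) * max(la, lb)) + 1 if floor > 0 else -1
    res = edlib.align(seq_1, seq_2, mode="NW", task="distance", k=k)
    dist = res["editDistance"]
    if dist < 0:
        return 0.0
    return max(0.0, 1.0 - dist / max(la, lb))


# ---------------------------------------------------------------------------
# Gene pairing
# ---------------------------------------------------------------------------


@dataclass
class GenePair:
    """Two allelic gene copies (gene_2 is None for single-allele genes)."""

    pair_id: str
    gene_1: GeneAnnotation
    gene_2: Optional[GeneAnnotation]
    cds_length_1: int
    cds_length_2: Optional[int]
    identical_length: bool
    nucleotide_identity: Optional[float]
    gc_1: Optional[float] = None
    gc_2: Optional[float] = None


def _collinear_matching(
    weights: dict[tuple[int, int], float],
    n: int,
    m: int,
    max_rank_offset: int,
) -> list[tuple[int, int]]:
    """Maximum-total-identity collinear matching.

    Accepted pairs must be strictly increasing on both sides and consecutive
    accepted pairs may not drift in rank by more than ``max_rank_offset``
    (|(i'-i) - (j'-j)| <= offset), which anchors the matching on previously
    accepted pairs exactly as a synteny-first pairing requires.
    """
    from bisect import bisect_left

    cands = sorted(weights)
    dp: dict[tuple[int, int], float] = {}
    parent: dict[tuple[int, int], Optional[tuple[int, int]]] = {}
    # lanes indexed by diagonal d = i - j; transition needs |d - d'| <= offset.
    # Each lane keeps entries in increasing i with running prefix maxima so a
    # predecessor query (ip < i and jp < j) is a binary search.
    lanes: dict[int, tuple[list[int], list[float], list[tuple[int, int]]]] = {}
    for (i, j) in cands:
        w = weights[(i, j)]
        d = i - j
        best_prev = 0.0
        best_cell: Optional[tuple[int, int]] = None
        for dprime in range(d - max_rank_offset, d + max_rank_offset + 1):
            lane = lanes.get(dprime)
            if lane is None:
                continue
            ips, prefmax, prefcell = lane
            # ip < i and jp = ip - dprime < j  =>  ip < min(i, j + dprime)
            cut = bisect_left(ips, min(i, j + dprime))
            if cut > 0 and prefmax[cut - 1] > best_prev:
                best_prev = prefmax[cut - 1]
                best_cell = prefcell[cut - 1]
        dp[(i, j)] = best_prev + w
        parent[(i, j)] = best_cell
        lane = lanes.setdefault(d, ([], [], []))
        ips, prefmax, prefcell = lane
        if prefmax and prefmax[-1] >= dp[(i, j)]:
            ips.append(i)
            prefmax.append(prefmax[-1])
            prefcell.append(prefcell[-1])
        else:
            ips.append(i)
            prefmax.append(dp[(i, j)])
            prefcell.append((i, j))
    if not dp:
        return []
    end = max(dp, key=lambda c: (dp[c], (-c[0], -c[1])))
    path: list[tuple[int, int]] = []
    cur: Optional[tuple[int, int]] = end
    while cur is not None:
        path.append(cur)
        cur = parent[cur]
    path.reverse()
    return path


def pair_genes(
    genes_copy1: Sequence[GeneAnnotation],
    genes_copy2: Sequence[GeneAnnotation],
    genome: Genome,
    min_identity: float = 0.5,
    max_rank_offset: int = 3,
    pair_id: str = "",
) -> tuple[list[GenePair], list[GeneAnnotation], list[GeneAnnotation]]:
    """Match allelic gene copies between the two chromosomes of a pair.

    Synteny-first: candidates are restricted to near-collinear rank positions
    and scored by sequence identity; a maximum-identity collinear matching is
    selected.  Unmatched genes are returned as single-allele genes for each
    side.
    """
    from .gc_trend import gc_fraction

    g1 = sorted(genes_copy1, key=lambda g: g.start)
    g2 = sorted(genes_copy2, key=lambda g: g.start)
    n, m = len(g1), len(g2)
    if n == 0 or m == 0:
        return [], list(g1), list(g2)
    cds1 = [genome.cds_sequence(g) for g in g1]
    cds2 = [genome.cds_sequence(g) for g in g2]
    band = max_rank_offset + abs(n - m) + 5
    weights: dict[tuple[int, int], float] = {}
    for i in range(n):
        lo, hi = max(0, i - band), min(m, i + band + 1)
        for j in range(lo, hi):
            ident = quick_identity(cds1[i], cds2[j], floor=min_identity)
            if ident >= min_identity:
                weights[(i, j)] = ident
    matching = _collinear_matching(weights, n, m, max_rank_offset)
    pairs: list[GenePair] = []
    used1: set[int] = set()
    used2: set[int] = set()
    for i, j in matching:
        used1.add(i)
        used2.add(j)
        l1, l2 = len(cds1[i]), len(cds2[j])
        if l1 == l2:
            ident = hamming_identity(cds1[i], cds2[j])
        else:
            ident = align_alleles(cds1[i], cds2[j]).identity
        pairs.append(
            GenePair(
                pair_id=pair_id or g1[i].chromosome_id,
                gene_1=g1[i],
                gene_2=g2[j],
                cds_length_1=l1,
                cds_length_2=l2,
                identical_length=(l1 == l2),
                nucleotide_identity=ident,
                gc_1=gc_fraction(cds1[i]),
                gc_2=gc_fraction(cds2[j]),
            )
        )
    singles1 = [g for k, g in enumerate(g1) if k not in used1]
    singles2 = [g for k, g in enumerate(g2) if k not in used2]
    return pairs, singles1, singles2


def select_dgc_genes(pairs: Sequence[GenePair]) -> list[GenePair]:
    """Keep only gene pairs whose two CDS have identical length.

    Restricting the GC-ratio statistic to identical-size allele pairs
    minimizes the effect of insertions/deletions on the GC values.
    """
    import warnings

    subset = [p for p in pairs if p.gene_2 is not None and p.identical_length]
    if pairs and not subset:
        warnings.warn("no identical-length gene pairs: dGC curve will be empty")
    return subset


# ---------------------------------------------------------------------------
# Anchored piecewise chromosome alignment
# ---------------------------------------------------------------------------


@dataclass
class PairAlignment:
    """Column-level alignment of a chromosome pair, on copy-1 coordinates.

    ``aligned``/``mismatch`` are boolean arrays over copy-1 positions;
    ``c2pos`` maps each aligned copy-1 position to its copy-2 coordinate
    (-1 where unaligned).  Columns containing N are marked unaligned so that
    every composition/divergence denominator excludes them.
    """

    pair_id: str
    chrom1_id: str
    chrom2_id: str
    aligned: np.ndarray
    mismatch: np.ndarray
    c2pos: np.ndarray
    len2: int

    def c1pos(self) -> np.ndarray:
        """Reverse projection: copy-2 position -> copy-1 position (-1 = none)."""
        rev = np.full(self.len2, -1, dtype=np.int64)
        idx = np.nonzero(self.aligned)[0]
        rev[self.c2pos[idx]] = idx
        return rev

    def project_interval(self, start: int, end: int) -> Optional[tuple[int, int]]:
        """Project a copy-1 interval onto copy-2 via aligned columns."""
        sub = self.c2pos[start:end]
        sub = sub[sub >= 0]
        if sub.size == 0:
            return None
        return int(sub.min()), int(sub.max()) + 1


_FAST_PATH_MAX_DIV = 0.30


def _fill_block(
    s1: np.ndarray,
    s2: np.ndarray,
    off1: int,
    off2: int,
    aligned: np.ndarray,
    mismatch: np.ndarray,
    c2pos: np.ndarray,
) -> None:
    """Align one inter-anchor block and write its columns into the arrays."""
    l1, l2 = len(s1), len(s2)
    if l1 == 0:
        return
    if l2 == 0:
        return  # copy-1 bases stay unaligned
    if l1 == l2:
        diff = s1 != s2
        if diff.mean() <= _FAST_PATH_MAX_DIV:
            # indel-free fast path: 1:1 columns
            nmask = (s1 == 78) | (s2 == 78)
            sl = slice(off1, off1 + l1)
            aligned[sl] = ~nmask
            mismatch[sl] = diff & ~nmask
            c2pos[sl] = np.where(~nmask, np.arange(off2, off2 + l1), -1)
            return
    res = edlib.align(
        s1.tobytes().decode("ascii"),
        s2.tobytes().decode("ascii"),
        mode="NW",
        task="path",
    )
    i = j = 0
    num = 0
    for ch in res["cigar"]:
        if ch.isdigit():
            num = num * 10 + int(ch)
            continue
        if ch in "=X":
            sl1 = s1[i : i + num]
            sl2 = s2[j : j + num]
            nmask = (sl1 == 78) | (sl2 == 78)
            rng = np.arange(off1 + i, off1 + i + num)
            aligned[rng] = ~nmask
            mismatch[rng] = (sl1 != sl2) & ~nmask
            c2pos[rng] = np.where(~nmask, np.arange(off2 + j, off2 + j + num), -1)
            i += num
            j += num
        elif ch == "I":  # consumes copy-1 only
            i += num
        elif ch == "D":  # consumes copy-2 only
            j += num
        num = 0


def align_chromosome_pair(
    genome: Genome,
    pair_id: str,
    gene_pairs: Sequence[GenePair],
) -> PairAlignment:
    """Anchored piecewise alignment of the two copies of a chromosome pair.

    Accepted gene pairs serve as anchors; each anchor block and each
    intergenic block between consecutive anchors is aligned independently
    (ungapped when the block is indel-free, edit-distance path otherwise).
    """
    chrom1, chrom2 = genome.pair_chromosomes(pair_id)
    s1 = genome.seq_array(chrom1.id)
    s2 = genome.seq_array(chrom2.id)
    L1, L2 = len(s1), len(s2)
    aligned = np.zeros(L1, dtype=bool)
    mismatch = np.zeros(L1, dtype=bool)
    c2pos = np.full(L1, -1, dtype=np.int64)

    anchors = [
        (p.gene_1.start, p.gene_1.end, p.gene_2.start, p.gene_2.end)
        for p in sorted(gene_pairs, key=lambda p: p.gene_1.start)
        if p.gene_2 is not None
    ]
    # boundaries: alternating inter-anchor and anchor blocks
    cur1 = cur2 = 0
    blocks: list[tuple[int, int, int, int]] = []
    for a1s, a1e, a2s, a2e in anchors:
        if a1s < cur1 or a2s < cur2:  # overlapping anchors: skip defensively
            continue
        blocks.append((cur1, a1s, cur2, a2s))
        blocks.append((a1s, a1e, a2s, a2e))
        cur1, cur2 = a1e, a2e
    blocks.append((cur1, L1, cur2, L2))
    for b1s, b1e, b2s, b2e in blocks:
        _fill_block(
            s1[b1s:b1e], s2[b2s:b2e], b1s, b2s, aligned, mismatch, c2pos
        )
    return PairAlignment(
        pair_id=pair_id,
        chrom1_id=chrom1.id,
        chrom2_id=chrom2.id,
        aligned=aligned,
        mismatch=mismatch,
        c2pos=c2pos,
        len2=L2,
    )
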