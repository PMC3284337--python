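"""Independent brute-force oracles used to validate the fast implementations.

Everything here is written for clarity, not speed: plain Python loops and
exhaustive enumeration, kept deliberately separate from the package code it
checks.
"""

from __future__ import annotations

from itertools import combinations

NEG = float("-inf")
MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1.0, -1.0, -2.0, -1.0


def nw_affine_oracle(s1: str, s2: str) -> tuple[float, float, str]:
    """Reference Gotoh global alignment with the canonical tie-break.

    Returns (score, identity, ops) where ops is over {'M','X','I','D'}
    ('I' consumes s1 only, 'D' consumes s2 only).  Tie preference at every
    maximum: diagonal state first, then the gap-in-seq1 state (consuming
    s2), then the gap-in-seq2 state (consuming s1); within gap states the
    incoming-state preference is M, then extension/other as in the
    implementation contract.
    """
    n, m = len(s1), len(s2)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in s2 (consumes s1)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in s1 (consumes s2)
    PM = [[0] * (m + 1) for _ in range(n + 1)]
    PX = [[0] * (m + 1) for _ in range(n + 1)]
    PY = [[0] * (m + 1) for _ in range(n + 1)]
    FROM_M, FROM_Y, FROM_X = 0, 1, 2
    M[0][0] = 0.0
    for j in range(1, m + 1):
        Y[0][j] = GAP_OPEN + GAP_EXTEND * (j - 1)
        PY[0][j] = FROM_M if j == 1 else FROM_Y
    for i in range(1, n + 1):
        X[i][0] = GAP_OPEN + GAP_EXTEND * (i - 1)
        PX[i][0] = FROM_M if i == 1 else FROM_X
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if s1[i - 1] == "N" or s2[j - 1] == "N" or s1[i - 1] != s2[j - 1]:
                s = MISMATCH
            else:
                s = MATCH
            cands = [
                (M[i - 1][j - 1], FROM_M),
                (Y[i - 1][j - 1], FROM_Y),
                (X[i - 1][j - 1], FROM_X),
            ]
            best, ptr = cands[0]
            for v, p in cands[1:]:
                if v > best:
                    best, ptr = v, p
            M[i][j] = best + s
            PM[i][j] = ptr
            cands = [
                (M[i][j - 1] + GAP_OPEN, FROM_M),
                (Y[i][j - 1] + GAP_EXTEND, FROM_Y),
                (X[i][j - 1] + GAP_OPEN, FROM_X),
            ]
            best, ptr = cands[0]
            for v, p in cands[1:]:
                if v > best:
                    best, ptr = v, p
            Y[i][j] = best
            PY[i][j] = ptr
            cands = [
                (M[i - 1][j] + GAP_OPEN, FROM_M),
                (Y[i - 1][j] + GAP_OPEN, FROM_Y),
                (X[i - 1][j] + GAP_EXTEND, FROM_X),
            ]
            best, ptr = cands[0]
            for v, p in cands[1:]:
                if v > best:
                    best, ptr = v, p
            X[i][j] = best
            PX[i][j] = ptr
    state, best = FROM_M, M[n][m]
    if Y[n][m] > best:
        state, best = FROM_Y, Y[n][m]
    if X[n][m] > best:
        state, best = FROM_X, X[n][m]
    score = best
    i, j = n, m
    ops = []
    matches = n_cols = 0
    while i > 0 or j > 0:
        if state == FROM_M:
            prev = PM[i][j]
            if s1[i - 1] == "N" or s2[j - 1] == "N":
                n_cols += 1
                ops.append("X")
            elif s1[i - 1] == s2[j - 1]:
                matches += 1
                ops.append("M")
            else:
                ops.append("X")
            i, j = i - 1, j - 1
        elif state == FROM_Y:
            prev = PY[i][j]
            ops.append("D")
            j -= 1
        else:
            prev = PX[i][j]
            ops.append("I")
            i -= 1
        state = prev
    ops.reverse()
    denom = len(ops) - n_cols
    identity = matches / denom if denom else float("nan")
    return score, identity, "".join(ops)


def sliding_mean_oracle(values: list[float], window: int) -> list[float]:
    """Brute-force windowed means."""
    return [
        sum(values[i : i + window]) / window
        for i in range(len(values) - window + 1)
    ]


def brute_collinear_matching(
    weights: dict[tuple[int, int], float], max_rank_offset: int
) -> tuple[float, list[tuple[int, int]]]:
    """Exhaustive maximum-weight collinear matching (tiny inputs only)."""
    cands = sorted(weights)
    best = (0.0, [])
    for k in range(len(cands), 0, -1):
        for combo in combinations(cands, k):
            ok = True
            for (i1, j1), (i2, j2) in zip(combo, combo[1:]):
                if not (i2 > i1 and j2 > j1 and abs((i2 - i1) - (j2 - j1)) <= max_rank_offset):
                    ok = False
                    break
            if ok:
                w = sum(weights[c] for c in combo)
                if w > best[0]:
                    best = (w, list(combo))
    return best


def brute_exchange_breakpoints(
    s: list[float], min_run: int, min_amplitude: float
) -> list[tuple[int, int]]:
    """Brute-force run-length exchange detection on a difference series.

    Returns (left_index, right_index) pairs of the flanking points of each
    breakpoint, mirroring the anchor rule: runs of stable nonzero sign with
    length >= min_run and mean |s| >= min_amplitude are anchors; adjacent
    anchors of opposite sign (not separated by a long zero run) yield a
    breakpoint.
    """

    def sgn(x: float) -> int:
        if x > 1e-9:
            return 1
        if x < -1e-9:
            return -1
        return 0

    runs = []
    start = 0
    for i in range(1, len(s) + 1):
        if i == len(s) or sgn(s[i]) != sgn(s[start]):
            runs.append((start, i, sgn(s[start])))
            start = i
    anchors = []
    long_zero = []
    for rs, re, sg in runs:
        if sg == 0 and re - rs >= min_run:
            long_zero.append((rs, re))
        if sg != 0 and re - rs >= min_run:
            amp = sum(abs(x) for x in s[rs:re]) / (re - rs)
            if amp >= min_amplitude:
                anchors.append((rs, re, sg))
    out = []
    for (a_s, a_e, a_sg), (b_s, b_e, b_sg) in zip(anchors, anchors[1:]):
        if a_sg == b_sg:
            continue
        if any(a_e <= zs and ze <= b_s for zs, ze in long_zero):
            continue
        out.append((a_e - 1, b_s))
    return out


def brute_numt_hits(
    nuc: str,
    mito: str,
    min_len: int = 50,
    min_identity: float = 0.8,
    k: int = 12,
    max_gap: int = 40,
) -> list[tuple[int, int]]:
    """Exhaustive seed-and-extend NUMT search (quadratic; tiny inputs only).

    Seeds are found by direct string comparison at every (nuclear, reference)
    offset pair on both strands; extension and chaining follow the published
    contract: ungapped growth until the trailing-30 identity drops below the
    threshold, trailing mismatches trimmed, hits >= min_len at >= the
    identity floor, same-strand hits within max_gap chained.  Returns sorted
    nuclear intervals.
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    ext = mito + mito[: min_len - 1]
    refs = [ext, "".join(comp[c] for c in reversed(ext))]
    intervals_by_strand: list[list[tuple[int, int]]] = [[], []]
    for si, ref in enumerate(refs):
        found: list[tuple[int, int]] = []
        for i in range(len(nuc) - k + 1):
            for j in range(len(ref) - k + 1):
                if nuc[i : i + k] != ref[j : j + k]:
                    continue
                if any(s <= i < e for s, e in found):
                    continue
                s, e = _brute_extend(nuc, ref, i, j, k, min_identity)
                matches = sum(
                    1 for t in range(e - s) if nuc[s + t] == ref[j - (i - s) + t]
                )
                if e - s >= min_len and matches / (e - s) >= min_identity:
                    found.append((s, e))
        intervals_by_strand[si] = sorted(found)
    merged: list[tuple[int, int]] = []
    for intervals in intervals_by_strand:
        chained: list[tuple[int, int]] = []
        for s, e in intervals:
            if chained and s - chained[-1][1] <= max_gap:
                chained[-1] = (chained[-1][0], max(chained[-1][1], e))
            else:
                chained.append((s, e))
        merged.extend(chained)
    return sorted(merged)


def _brute_extend(
    nuc: str, ref: str, i: int, j: int, k: int, min_identity: float, tail: int = 30
) -> tuple[int, int]:
    def direction(sign: int) -> int:
        outcomes = []
        t = 0
        while True:
            t += 1
            if sign > 0:
                ni, ri = i + k - 1 + t, j + k - 1 + t
            else:
                ni, ri = i - t, j - t
            if ni < 0 or ri < 0 or ni >= len(nuc) or ri >= len(ref):
                break
            outcomes.append(nuc[ni] == ref[ri] and nuc[ni] != "N")
            w = outcomes[-tail:]
            if sum(w) / len(w) < min_identity:
                break
        while outcomes and not outcomes[-1]:
            outcomes.pop()
        return len(outcomes)

    return i - direction(-1), i + k + direction(+1)
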