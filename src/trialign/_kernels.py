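"""Numba-compiled inner loops (Smith-Waterman fill + traceback).

Gap-cost convention: a contiguous run of g gap characters costs
``gap_open_extra + g * gap_extend`` (both negative), i.e. the first gap
character of a run costs ``gap_open_extra + gap_extend``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# transcript op codes
OP_MATCH = 0
OP_MISMATCH = 1
OP_INS = 2  # gap in subject: consumes a query symbol
OP_DEL = 3  # gap in query: consumes a subject symbol

_NEG = -(10**7)


@njit(cache=True, nogil=True)
def occ_count(bwt, occ_cp, occ_rate, symbol, i):
    """Occurrences of ``symbol`` in bwt[0:i] via checkpoint + tail scan."""
    blk = i // occ_rate
    cnt = occ_cp[blk, symbol]
    for k in range(blk * occ_rate, i):
        if bwt[k] == symbol:
            cnt += 1
    return cnt


@njit(cache=True, nogil=True)
def backward_step(bwt, occ_cp, occ_rate, counts, symbol, lo, hi):
    """One backward-search step; returns the new (lo, hi)."""
    c = counts[symbol]
    return (
        c + occ_count(bwt, occ_cp, occ_rate, symbol, lo),
        c + occ_count(bwt, occ_cp, occ_rate, symbol, hi),
    )


@njit(cache=True, nogil=True)
def sw_affine(q, s, sub, gap_extend, gap_open_extra):
    """Exact affine-gap Smith-Waterman over the full matrix (no X-drop).

    Returns (score, q_begin, q_end, s_begin, s_end, ops, n_ops) with
    half-open 0-based ranges; ``ops[:n_ops]`` is the transcript in
    alignment order.  The best cell is the first maximum in row-major
    scan order; traceback prefers diagonal, then subject-gap, then
    query-gap.
    """
    m = q.size
    n = s.size
    go = gap_open_extra + gap_extend  # first gap char of a run
    ge = gap_extend
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E = np.full((m + 1, n + 1), _NEG, dtype=np.int32)
    F = np.full((m + 1, n + 1), _NEG, dtype=np.int32)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            e = H[i - 1, j] + go
            e2 = E[i - 1, j] + ge
            if e2 > e:
                e = e2
            f = H[i, j - 1] + go
            f2 = F[i, j - 1] + ge
            if f2 > f:
                f = f2
            h = H[i - 1, j - 1] + sub[s[j - 1], qi]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            E[i, j] = e
            F[i, j] = f
            if h > best:
                best = h
                bi = i
                bj = j
    # traceback
    ops = np.empty(m + n, dtype=np.uint8)
    k = m + n
    i = bi
    j = bj
    state = 0  # 0 = H, 1 = E (subject gap), 2 = F (query gap)
    while True:
        if state == 0:
            if H[i, j] == 0:
                break
            d = H[i - 1, j - 1] + sub[s[j - 1], q[i - 1]]
            if H[i, j] == d:
                k -= 1
                ops[k] = OP_MATCH if q[i - 1] == s[j - 1] else OP_MISMATCH
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            k -= 1
            ops[k] = OP_INS
            if E[i, j] == H[i - 1, j] + go:
                state = 0
            i -= 1
        else:
            k -= 1
            ops[k] = OP_DEL
            if F[i, j] == H[i, j - 1] + go:
                state = 0
            j -= 1
    n_ops = m + n - k
    out_ops = ops[k : m + n].copy()
    return best, i, bi, j, bj, out_ops, n_ops


@njit(cache=True, nogil=True)
def gapless_extend(q, s, qb, qe, sb, se, sub, xdrop):
    """Ungapped extension of the seed region q[qb:qe] ~ s[sb:se] in both
    directions with an X-drop bound; returns the best total raw score."""
    score = 0
    for k in range(qe - qb):
        score += sub[s[sb + k], q[qb + k]]
    best = score
    # right extension
    run = 0
    best_right = 0
    k = 0
    while qe + k < q.size and se + k < s.size:
        run += sub[s[se + k], q[qe + k]]
        if run > best_right:
            best_right = run
        if best_right - run > xdrop:
            break
        k += 1
    # left extension
    run = 0
    best_left = 0
    k = 1
    while qb - k >= 0 and sb - k >= 0:
        run += sub[s[sb - k], q[qb - k]]
        if run > best_left:
            best_left = run
        if best_left - run > xdrop:
            break
        k += 1
    return best + best_left + best_right
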