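"""Affine-gap dynamic-programming alignment kernels (numba).

Scoring convention: a gap of length L costs ``gap_open + (L - 1) * gap_extend``
(the first gapped column pays the opening penalty only).

Operation codes in traceback output: 0 = diagonal (match/mismatch),
1 = gap in B (consumes A), 2 = gap in A (consumes B).
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = np.int32(-(10**9) // 2)

# traceback byte layout:
#   bits 0-1: H source (0 stop/origin, 1 diag, 2 E, 3 F)
#   bit 2   : E opened from H (else extended)
#   bit 3   : F opened from H (else extended)


@njit(cache=True)
def _score(a: np.uint8, b: np.uint8, match: np.int32, mismatch: np.int32) -> np.int32:
    if a == b and a < 4:
        return match
    return mismatch


@njit(cache=True)
def sw_local(a, b, match, mismatch, gap_open, gap_extend):
    """Best local alignment of a vs b.

    Returns (score, a_start, a_end, b_start, b_end, ops) where ops is the
    int8 operation array from alignment start to end.
    """
    la, lb = len(a), len(b)
    tb = np.zeros((la + 1, lb + 1), dtype=np.uint8)
    h_prev = np.zeros(lb + 1, dtype=np.int32)
    f_prev = np.full(lb + 1, NEG_INF, dtype=np.int32)
    h_cur = np.zeros(lb + 1, dtype=np.int32)
    f_cur = np.zeros(lb + 1, dtype=np.int32)

    best = np.int32(0)
    best_i = 0
    best_j = 0
    for i in range(1, la + 1):
        h_cur[0] = 0
        f_cur[0] = NEG_INF
        e = NEG_INF
        ai = a[i - 1]
        for j in range(1, lb + 1):
            flags = np.uint8(0)
            # E: gap in A (consume B), moving left->right
            e_open = h_cur[j - 1] + gap_open
            e_ext = e + gap_extend
            if e_open >= e_ext:
                e = e_open
                flags |= 4
            else:
                e = e_ext
            # F: gap in B (consume A), moving top->bottom
            f_open = h_prev[j] + gap_open
            f_ext = f_prev[j] + gap_extend
            if f_open >= f_ext:
                f = f_open
                flags |= 8
            else:
                f = f_ext
            f_cur[j] = f
            diag = h_prev[j - 1] + _score(ai, b[j - 1], match, mismatch)
            h = np.int32(0)
            src = np.uint8(0)
            if diag > h:
                h = diag
                src = 1
            if e > h:
                h = e
                src = 2
            if f > h:
                h = f
                src = 3
            h_cur[j] = h
            tb[i, j] = flags | src
            if h > best:
                best = h
                best_i = i
                best_j = j
        h_prev, h_cur = h_cur, h_prev
        f_prev, f_cur = f_cur, f_prev

    # traceback
    ops = np.empty(la + lb, dtype=np.int8)
    n_ops = 0
    i, j = best_i, best_j
    state = 0  # 0=H, 1=E, 2=F
    while i > 0 or j > 0:
        cell = tb[i, j]
        if state == 0:
            src = cell & 3
            if src == 0:
                break
            if src == 1:
                ops[n_ops] = 0
                n_ops += 1
                i -= 1
                j -= 1
            elif src == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            ops[n_ops] = 2
            n_ops += 1
            if cell & 4:
                state = 0
            j -= 1
        else:
            ops[n_ops] = 1
            n_ops += 1
            if cell & 8:
                state = 0
            i -= 1
    return best, i, best_i, j, best_j, ops[:n_ops][::-1].copy()


@njit(cache=True)
def sw_local_banded(a, b, match, mismatch, gap_open, gap_extend, d_lo, d_hi):
    """Local alignment restricted to diagonals d_lo <= j - i <= d_hi.

    Same return contract as :func:`sw_local`. Cells outside the band are
    treated as unreachable.
    """
    la, lb = len(a), len(b)
    tb = np.zeros((la + 1, lb + 1), dtype=np.uint8)
    h_prev = np.zeros(lb + 1, dtype=np.int32)
    f_prev = np.full(lb + 1, NEG_INF, dtype=np.int32)
    h_cur = np.zeros(lb + 1, dtype=np.int32)
    f_cur = np.zeros(lb + 1, dtype=np.int32)

    best = np.int32(0)
    best_i = 0
    best_j = 0
    for i in range(1, la + 1):
        j_lo = max(1, i + d_lo)
        j_hi = min(lb, i + d_hi)
        if j_lo > j_hi:
            continue
        h_cur[j_lo - 1] = 0
        f_cur[j_lo - 1] = NEG_INF
        e = NEG_INF
        ai = a[i - 1]
        for j in range(j_lo, j_hi + 1):
            flags = np.uint8(0)
            e_open = h_cur[j - 1] + gap_open
            e_ext = e + gap_extend
            if e_open >= e_ext:
                e = e_open
                flags |= 4
            else:
                e = e_ext
            if j < i + d_hi:  # row above has this column inside its band
                f_open = h_prev[j] + gap_open
                f_ext = f_prev[j] + gap_extend
            else:
                f_open = NEG_INF
                f_ext = NEG_INF
            if f_open >= f_ext:
                f = f_open
                flags |= 8
            else:
                f = f_ext
            f_cur[j] = f
            diag = h_prev[j - 1] + _score(ai, b[j - 1], match, mismatch)
            h = np.int32(0)
            src = np.uint8(0)
            if diag > h:
                h = diag
                src = 1
            if e > h:
                h = e
                src = 2
            if f > h:
                h = f
                src = 3
            h_cur[j] = h
            tb[i, j] = flags | src
            if h > best:
                best = h
                best_i = i
                best_j = j
        h_prev, h_cur = h_cur, h_prev
        f_prev, f_cur = f_cur, f_prev

    ops = np.empty(la + lb, dtype=np.int8)
    n_ops = 0
    i, j = best_i, best_j
    state = 0
    while i > 0 or j > 0:
        cell = tb[i, j]
        if state == 0:
            src = cell & 3
            if src == 0:
                break
            if src == 1:
                ops[n_ops] = 0
                n_ops += 1
                i -= 1
                j -= 1
            elif src == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            ops[n_ops] = 2
            n_ops += 1
            if cell & 4:
                state = 0
            j -= 1
        else:
            ops[n_ops] = 1
            n_ops += 1
            if cell & 8:
                state = 0
            i -= 1
    return best, i, best_i, j, best_j, ops[:n_ops][::-1].copy()


@njit(cache=True)
def nw_global(a, b, match, mismatch, gap_open, gap_extend):
    """Global alignment of a vs b. Returns (score, ops)."""
    la, lb = len(a), len(b)
    tb = np.zeros((la + 1, lb + 1), dtype=np.uint8)
    h_prev = np.empty(lb + 1, dtype=np.int32)
    f_prev = np.full(lb + 1, NEG_INF, dtype=np.int32)
    h_cur = np.empty(lb + 1, dtype=np.int32)
    f_cur = np.empty(lb + 1, dtype=np.int32)

    h_prev[0] = 0
    for j in range(1, lb + 1):
        h_prev[j] = gap_open + (j - 1) * gap_extend
        tb[0, j] = 2 | (4 if j == 1 else 0)
    for i in range(1, la + 1):
        h_cur[0] = gap_open + (i - 1) * gap_extend
        f_cur[0] = h_cur[0]
        tb[i, 0] = 3 | (8 if i == 1 else 0)
        e = NEG_INF
        ai = a[i - 1]
        for j in range(1, lb + 1):
            flags = np.uint8(0)
            e_open = h_cur[j - 1] + gap_open
            e_ext = e + gap_extend
            if e_open >= e_ext:
                e = e_open
                flags |= 4
            else:
                e = e_ext
            f_open = h_prev[j] + gap_open
            f_ext = f_prev[j] + gap_extend
            if f_open >= f_ext:
                f = f_open
                flags |= 8
            else:
                f = f_ext
            f_cur[j] = f
            diag = h_prev[j - 1] + _score(ai, b[j - 1], match, mismatch)
            h = diag
            src = np.uint8(1)
            if e > h:
                h = e
                src = 2
            if f > h:
                h = f
                src = 3
            h_cur[j] = h
            tb[i, j] = flags | src
        h_prev, h_cur = h_cur, h_prev
        f_prev, f_cur = f_cur, f_prev

    score = h_prev[lb]
    ops = np.empty(la + lb, dtype=np.int8)
    n_ops = 0
    i, j = la, lb
    state = 0
    while i > 0 or j > 0:
        cell = tb[i, j]
        if state == 0:
            src = cell & 3
            if src == 1:
                ops[n_ops] = 0
                n_ops += 1
                i -= 1
                j -= 1
            elif src == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            ops[n_ops] = 2
            n_ops += 1
            if cell & 4:
                state = 0
            j -= 1
        else:
            ops[n_ops] = 1
            n_ops += 1
            if cell & 8:
                state = 0
            i -= 1
    return score, ops[:n_ops][::-1].copy()
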