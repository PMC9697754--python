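"""Affine-gap global alignment kernel (Gotoh) over an arbitrary score matrix.

Shared by the structural aligner (TM-style distance scores), the sequence
seed alignment (BLOSUM62) and the progressive profile-profile aligner.
The kernel is numba-compiled; scoring matrices are built by the callers.

Tie-breaking is deterministic: diagonal (match) is preferred over a gap,
and a gap in the first input over a gap in the second.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = -1e30


@njit(cache=False)
def _gotoh_fill(S, gap_open, gap_extend):
    n, m = S.shape
    M = np.full((n + 1, m + 1), NEG_INF)
    X = np.full((n + 1, m + 1), NEG_INF)  # gap in B (consume A row i)
    Y = np.full((n + 1, m + 1), NEG_INF)  # gap in A (consume B column j)
    # traceback codes: 0=M from M, 1=M from X, 2=M from Y,
    #                  3=X open, 4=X extend, 5=Y open, 6=Y extend
    tb_m = np.zeros((n + 1, m + 1), dtype=np.int8)
    tb_x = np.zeros((n + 1, m + 1), dtype=np.int8)
    tb_y = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + gap_extend * (i - 1)
        tb_x[i, 0] = 1 if i == 1 else 0  # 1: opened from M, 0: extended
    for j in range(1, m + 1):
        Y[0, j] = gap_open + gap_extend * (j - 1)
        tb_y[0, j] = 1 if j == 1 else 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # M: diagonal; ties prefer M, then Y (gap in A), then X
            best = M[i - 1, j - 1]
            code = 0
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                code = 2
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                code = 1
            M[i, j] = best + S[i - 1, j - 1]
            tb_m[i, j] = code
            # X: gap in B, consume A residue i. open from M/Y vs extend X
            open_x = M[i - 1, j] + gap_open
            if Y[i - 1, j] + gap_open > open_x:
                open_x = Y[i - 1, j] + gap_open
                oc = 2
            else:
                oc = 1
            ext_x = X[i - 1, j] + gap_extend
            if open_x >= ext_x:
                X[i, j] = open_x
                tb_x[i, j] = oc
            else:
                X[i, j] = ext_x
                tb_x[i, j] = 0
            # Y: gap in A, consume B residue j
            open_y = M[i, j - 1] + gap_open
            if X[i, j - 1] + gap_open > open_y:
                open_y = X[i, j - 1] + gap_open
                oc2 = 2
            else:
                oc2 = 1
            ext_y = Y[i, j - 1] + gap_extend
            if open_y >= ext_y:
                Y[i, j] = open_y
                tb_y[i, j] = oc2
            else:
                Y[i, j] = ext_y
                tb_y[i, j] = 0
    return M, X, Y, tb_m, tb_x, tb_y


@njit(cache=False)
def _gotoh_traceback(S, M, X, Y, tb_m, tb_x, tb_y):
    n, m = S.shape
    # choose end state; ties prefer M then X then Y
    i, j = n, m
    state = 0
    best = M[n, m]
    if Y[n, m] > best:
        best = Y[n, m]
        state = 2
    if X[n, m] > best:
        best = X[n, m]
        state = 1
    pairs_a = np.empty(n + m, dtype=np.int64)
    pairs_b = np.empty(n + m, dtype=np.int64)
    k = 0
    while i > 0 or j > 0:
        if state == 0:
            prev = tb_m[i, j]
            pairs_a[k] = i - 1
            pairs_b[k] = j - 1
            k += 1
            i -= 1
            j -= 1
            state = prev
        elif state == 1:  # X consumed A residue i
            prev = tb_x[i, j]
            i -= 1
            if prev == 0:
                state = 1
            elif prev == 1:
                state = 0
            else:
                state = 2
        else:  # Y consumed B residue j
            prev = tb_y[i, j]
            j -= 1
            if prev == 0:
                state = 2
            elif prev == 1:
                state = 0
            else:
                state = 1
        if i == 0 and j == 0:
            break
        if i == 0 and state == 1:
            state = 2  # only Y moves remain
        if j == 0 and state == 2:
            state = 1
    return best, pairs_a[:k][::-1].copy(), pairs_b[:k][::-1].copy()


def gotoh_align(S: np.ndarray, gap_open: float, gap_extend: float):
    """Global affine-gap alignment maximizing sum of S over matched pairs.

    Returns ``(score, pairs)`` where ``pairs`` is an (k, 2) int array of
    matched (i, j) indices, strictly increasing in both columns.
    """
    S = np.ascontiguousarray(S, dtype=np.float64)
    if S.ndim != 2 or S.shape[0] == 0 or S.shape[1] == 0:
        raise ValueError("score matrix must be non-empty 2-D")
    M, X, Y, tm, tx, ty = _gotoh_fill(S, float(gap_open), float(gap_extend))
    score, ia, ib = _gotoh_traceback(S, M, X, Y, tm, tx, ty)
    return float(score), np.stack([ia, ib], axis=1)
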