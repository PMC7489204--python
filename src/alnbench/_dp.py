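"""Affine-gap dynamic-programming kernels (Gotoh three-state recurrences).

Compiled with numba.  Penalties are positive magnitudes; a gap of length L
costs ``gop + (L - 1) * gep``.  State 0 aligns a residue pair (diagonal),
state 1 consumes a residue of sequence 1 against a gap in sequence 2,
state 2 the converse.  Ties are broken deterministically with the
preference diagonal > gap-in-2 > gap-in-1, applied during the forward pass
by strict-improvement comparisons in that order.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1.0e30

# local-mode ptrM markers beyond predecessor states 0/1/2
_START = 3   # this cell's pair begins the alignment
_EMPTY = 4   # floored cell: best alignment ending here is empty


@njit(cache=False)
def global_affine(a, b, S, gop, gep):  # pragma: no cover - exercised via aligner
    n, m = a.size, b.size
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    ptrM = np.zeros((n + 1, m + 1), np.int8)
    ptrX = np.zeros((n + 1, m + 1), np.int8)
    ptrY = np.zeros((n + 1, m + 1), np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(gop + (i - 1) * gep)
        ptrX[i, 0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        Y[0, j] = -(gop + (j - 1) * gep)
        ptrY[0, j] = 0 if j == 1 else 2
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            best = M[i - 1, j - 1]
            st = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                st = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                st = 2
            M[i, j] = best + S[ai, b[j - 1]]
            ptrM[i, j] = st

            best = M[i - 1, j] - gop
            st = 0
            v = X[i - 1, j] - gep
            if v > best:
                best = v
                st = 1
            v = Y[i - 1, j] - gop
            if v > best:
                best = v
                st = 2
            X[i, j] = best
            ptrX[i, j] = st

            best = M[i, j - 1] - gop
            st = 0
            v = X[i, j - 1] - gop
            if v > best:
                best = v
                st = 1
            v = Y[i, j - 1] - gep
            if v > best:
                best = v
                st = 2
            Y[i, j] = best
            ptrY[i, j] = st

    score = M[n, m]
    state = 0
    if X[n, m] > score:
        score = X[n, m]
        state = 1
    if Y[n, m] > score:
        score = Y[n, m]
        state = 2

    cap = n if n < m else m
    pi = np.empty(cap, np.int64)
    pj = np.empty(cap, np.int64)
    cnt = 0
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            pi[cnt] = i - 1
            pj[cnt] = j - 1
            cnt += 1
            state = ptrM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            state = ptrX[i, j]
            i -= 1
        else:
            state = ptrY[i, j]
            j -= 1
    return score, pi[:cnt][::-1].copy(), pj[:cnt][::-1].copy()


@njit(cache=False)
def semiglobal_affine(a, b, S, gop, gep):  # pragma: no cover - exercised via aligner
    """Global alignment with unpenalized terminal gaps."""
    n, m = a.size, b.size
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    ptrM = np.zeros((n + 1, m + 1), np.int8)
    ptrX = np.zeros((n + 1, m + 1), np.int8)
    ptrY = np.zeros((n + 1, m + 1), np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = 0.0
        ptrX[i, 0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        Y[0, j] = 0.0
        ptrY[0, j] = 0 if j == 1 else 2
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            best = M[i - 1, j - 1]
            st = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                st = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                st = 2
            M[i, j] = best + S[ai, b[j - 1]]
            ptrM[i, j] = st

            # terminal column/row: extension of a trailing gap is free
            xgop, xgep = (0.0, 0.0) if j == m else (gop, gep)
            best = M[i - 1, j] - xgop
            st = 0
            v = X[i - 1, j] - xgep
            if v > best:
                best = v
                st = 1
            v = Y[i - 1, j] - xgop
            if v > best:
                best = v
                st = 2
            X[i, j] = best
            ptrX[i, j] = st

            ygop, ygep = (0.0, 0.0) if i == n else (gop, gep)
            best = M[i, j - 1] - ygop
            st = 0
            v = X[i, j - 1] - ygop
            if v > best:
                best = v
                st = 1
            v = Y[i, j - 1] - ygep
            if v > best:
                best = v
                st = 2
            Y[i, j] = best
            ptrY[i, j] = st

    score = M[n, m]
    state = 0
    if X[n, m] > score:
        score = X[n, m]
        state = 1
    if Y[n, m] > score:
        score = Y[n, m]
        state = 2

    cap = n if n < m else m
    pi = np.empty(cap, np.int64)
    pj = np.empty(cap, np.int64)
    cnt = 0
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            pi[cnt] = i - 1
            pj[cnt] = j - 1
            cnt += 1
            state = ptrM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            state = ptrX[i, j]
            i -= 1
        else:
            state = ptrY[i, j]
            j -= 1
    return score, pi[:cnt][::-1].copy(), pj[:cnt][::-1].copy()


@njit(cache=False)
def local_affine(a, b, S, gop, gep):  # pragma: no cover - exercised via aligner
    n, m = a.size, b.size
    M = np.zeros((n + 1, m + 1))
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    ptrM = np.full((n + 1, m + 1), _EMPTY, np.int8)
    ptrX = np.zeros((n + 1, m + 1), np.int8)
    ptrY = np.zeros((n + 1, m + 1), np.int8)
    best_score = 0.0
    bi, bj = 0, 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            prev = M[i - 1, j - 1]
            st = 0
            if X[i - 1, j - 1] > prev:
                prev = X[i - 1, j - 1]
                st = 1
            if Y[i - 1, j - 1] > prev:
                prev = Y[i - 1, j - 1]
                st = 2
            if st == 0 and ptrM[i - 1, j - 1] == _EMPTY:
                st = _START
            if prev <= 0.0:
                prev = 0.0
                st = _START
            v = prev + S[ai, b[j - 1]]
            if v < 0.0:
                M[i, j] = 0.0
                ptrM[i, j] = _EMPTY
            else:
                M[i, j] = v
                ptrM[i, j] = st
                if v > best_score:
                    best_score = v
                    bi, bj = i, j

            best = M[i - 1, j] - gop
            st = 0
            v = X[i - 1, j] - gep
            if v > best:
                best = v
                st = 1
            v = Y[i - 1, j] - gop
            if v > best:
                best = v
                st = 2
            X[i, j] = best
            ptrX[i, j] = st

            best = M[i, j - 1] - gop
            st = 0
            v = X[i, j - 1] - gop
            if v > best:
                best = v
                st = 1
            v = Y[i, j - 1] - gep
            if v > best:
                best = v
                st = 2
            Y[i, j] = best
            ptrY[i, j] = st

    cap = n if n < m else m
    pi = np.empty(cap, np.int64)
    pj = np.empty(cap, np.int64)
    cnt = 0
    if best_score <= 0.0:
        return 0.0, pi[:0], pj[:0]
    i, j = bi, bj
    state = 0
    while True:
        if state == 0:
            marker = ptrM[i, j]
            if marker == _EMPTY:
                break
            pi[cnt] = i - 1
            pj[cnt] = j - 1
            cnt += 1
            if marker == _START:
                break
            state = marker
            i -= 1
            j -= 1
        elif state == 1:
            state = ptrX[i, j]
            i -= 1
        else:
            state = ptrY[i, j]
            j -= 1
    return best_score, pi[:cnt][::-1].copy(), pj[:cnt][::-1].copy()
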