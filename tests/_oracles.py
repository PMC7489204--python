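"""Independent brute-force oracles used to validate the DP aligners.

Deliberately naive: plain-Python memoized recursion over edit operations
(global) and exhaustive maximization over substring pairs (local).  These
share no code with the package's Gotoh kernels.
"""

from __future__ import annotations

from functools import lru_cache


def global_score_oracle(a, b, S, gop, gep) -> float:
    """Optimal global affine score by recursion over remaining suffixes.

    State tracks the type of the previous column so an extended gap costs
    ``gep`` and any newly opened gap costs ``gop``; a gap of length L thus
    accumulates ``gop + (L - 1) * gep``.
    """
    a = tuple(a)
    b = tuple(b)
    n, m = len(a), len(b)

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, prev: int) -> float:
        if i == n and j == m:
            return 0.0
        best = float("-inf")
        if i < n and j < m:
            best = max(best, S[a[i], b[j]] + rec(i + 1, j + 1, 0))
        if i < n:
            best = max(best, -(gep if prev == 1 else gop) + rec(i + 1, j, 1))
        if j < m:
            best = max(best, -(gep if prev == 2 else gop) + rec(i, j + 1, 2))
        return best

    result = rec(0, 0, 0)
    rec.cache_clear()
    return result


def local_score_oracle(a, b, S, gop, gep) -> float:
    """Optimal local affine score: best global score over all substring pairs.

    Trailing/leading residues of a substring alignment can only lower its
    score, so the maximum over substrings equals the Smith-Waterman optimum;
    the empty alignment contributes the floor of 0.
    """
    a = tuple(a)
    b = tuple(b)
    best = 0.0
    for i1 in range(len(a)):
        for i2 in range(i1 + 1, len(a) + 1):
            for j1 in range(len(b)):
                for j2 in range(j1 + 1, len(b) + 1):
                    best = max(best, global_score_oracle(a[i1:i2], b[j1:j2], S, gop, gep))
    return best


def linear_gap_score_oracle(a, b, S, g) -> float:
    """Global optimum under a per-residue linear gap cost ``g`` (no state)."""
    a = tuple(a)
    b = tuple(b)
    n, m = len(a), len(b)
    prev = [-g * j for j in range(m + 1)]
    for i in range(1, n + 1):
        cur = [-g * i] + [0.0] * m
        for j in range(1, m + 1):
            cur[j] = max(prev[j - 1] + S[a[i - 1], b[j - 1]], prev[j] - g, cur[j - 1] - g)
        prev = cur
    return prev[m]
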