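"""Optimal pairwise alignment: global (Needleman-Wunsch) and local
(Smith-Waterman) dynamic programming with an affine gap penalty.

Conventions (documented because published optima shift slightly between
them):

* a gap of length L costs ``gop + (L - 1) * gep``;
* terminal gaps in global mode are penalized (classic end-to-end NW);
  pass ``free_end_gaps=True`` for semiglobal alignment;
* scores are real-valued throughout (extension penalties as small as 0.1
  are in the scanned grid);
* traceback ties break deterministically: diagonal > gap in sequence 2 >
  gap in sequence 1, applied top-down.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from . import _dp
from .alphabet import encode
from .core import PairAlignment
from .matrices import SubstitutionMatrix

Sequence = Union[str, np.ndarray]


@dataclass(frozen=True)
class GapPenalty:
    """Affine gap parameters: opening (gop) and extension (gep) magnitudes."""

    gop: float
    gep: float

    def __post_init__(self) -> None:
        if not (self.gop > 0 and self.gep > 0):
            raise ValueError(f"gap penalties must be positive, got {self!r}")

    def cost(self, length: int) -> float:
        """Cost of a single gap of the given length (0 for length 0)."""
        return self.gop + (length - 1) * self.gep if length > 0 else 0.0


@dataclass(frozen=True)
class AlignmentResult:
    alignment: PairAlignment
    score: float
    mode: str  # "local" | "global"


def _codes(s: Sequence) -> np.ndarray:
    if isinstance(s, str):
        return encode(s)
    arr = np.asarray(s, dtype=np.int8)
    if arr.size and (arr.min() < 0 or arr.max() >= 20):
        raise ValueError("residue codes out of range 0..19")
    return arr


def global_align(s1: Sequence, s2: Sequence, m: SubstitutionMatrix,
                 gp: GapPenalty, *, free_end_gaps: bool = False) -> AlignmentResult:
    """End-to-end optimum over all global alignments of two sequences."""
    a, b = _codes(s1), _codes(s2)
    if a.size == 0 or b.size == 0:
        raise ValueError("global alignment requires non-empty sequences")
    if free_end_gaps:
        score, pi, pj = _dp.semiglobal_affine(a, b, m.scores, float(gp.gop), float(gp.gep))
    else:
        score, pi, pj = _dp.global_affine(a, b, m.scores, float(gp.gop), float(gp.gep))
    return AlignmentResult(PairAlignment(pi, pj, a.size, b.size), float(score), "global")


def local_align(s1: Sequence, s2: Sequence, m: SubstitutionMatrix,
                gp: GapPenalty) -> AlignmentResult:
    """Maximal-scoring sub-alignment; the empty alignment (score 0) is allowed."""
    a, b = _codes(s1), _codes(s2)
    if a.size == 0 or b.size == 0:
        raise ValueError("local alignment requires non-empty sequences")
    score, pi, pj = _dp.local_affine(a, b, m.scores, float(gp.gop), float(gp.gep))
    return AlignmentResult(PairAlignment(pi, pj, a.size, b.size), float(score), "local")


def rescore(alignment: PairAlignment, s1: Sequence, s2: Sequence,
            m: SubstitutionMatrix, gp: GapPenalty, mode: str = "global") -> float:
    """Score an alignment from its pair list, independent of the DP tables.

    Matched pairs contribute their matrix scores; each maximal run of
    unpaired residues in either sequence is charged as one affine gap.  In
    global mode terminal gaps are charged too; in local mode only gaps
    between the first and last pair count.
    """
    a, b = _codes(s1), _codes(s2)
    if alignment.len1 != a.size or alignment.len2 != b.size:
        raise ValueError("alignment does not match the sequences")
    if alignment.n_pairs == 0:
        return 0.0 if mode == "local" else -(gp.cost(a.size) + gp.cost(b.size))
    total = float(np.sum(m.scores[a[alignment.i_idx], b[alignment.j_idx]]))
    di = np.diff(alignment.i_idx) - 1
    dj = np.diff(alignment.j_idx) - 1
    for gaps in (di, dj):
        for L in gaps[gaps > 0]:
            total -= gp.cost(int(L))
    if mode == "global":
        total -= gp.cost(int(alignment.i_idx[0]))
        total -= gp.cost(int(alignment.j_idx[0]))
        total -= gp.cost(int(a.size - 1 - alignment.i_idx[-1]))
        total -= gp.cost(int(b.size - 1 - alignment.j_idx[-1]))
    return total
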