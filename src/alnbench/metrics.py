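"""Alignment quality scoring against reference alignments.

Quality of an algorithmic alignment is measured by two set ratios over
residue-residue comparisons (gap columns are never comparisons):

* ``Accuracy  = I / R`` -- the fraction of reference pairs recovered;
* ``Confidence = I / A`` -- the fraction of algorithmic pairs that are correct;

where ``I`` is the number of index pairs shared by the two alignments,
``R`` the reference pair count and ``A`` the algorithmic pair count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import PairAlignment


@dataclass(frozen=True)
class QualityScore:
    """Accuracy/Confidence with the underlying counts.

    An empty algorithmic alignment (``A == 0``, possible in local mode) has
    Confidence defined as 0 and still participates in averages.
    """

    I: int
    R: int
    A: int

    def __post_init__(self) -> None:
        if not 0 <= self.I <= min(self.R, self.A if self.A else self.I):
            raise ValueError(f"inconsistent counts I={self.I}, R={self.R}, A={self.A}")

    @property
    def accuracy(self) -> float:
        return self.I / self.R if self.R else 0.0

    @property
    def confidence(self) -> float:
        return self.I / self.A if self.A else 0.0


def score_alignment(reference: PairAlignment, algorithmic: PairAlignment) -> QualityScore:
    """Count exact index-pair matches between reference and algorithmic alignments."""
    if (reference.len1, reference.len2) != (algorithmic.len1, algorithmic.len2):
        raise ValueError(
            "alignments refer to different sequences: "
            f"({reference.len1}, {reference.len2}) vs ({algorithmic.len1}, {algorithmic.len2})"
        )
    shared = reference.pair_set() & algorithmic.pair_set()
    return QualityScore(I=len(shared), R=reference.n_pairs, A=algorithmic.n_pairs)


def mean_quality(scores: Sequence[QualityScore]) -> tuple[float, float]:
    """Macro-averaged (mean accuracy, mean confidence) over pairs."""
    if not scores:
        raise ValueError("mean_quality of an empty score list")
    acc = float(np.mean([s.accuracy for s in scores]))
    conf = float(np.mean([s.confidence for s in scores]))
    return acc, conf


def identity_fraction(a: PairAlignment, s1, s2) -> float:
    """Fraction of aligned residue pairs with identical residues (0 if none)."""
    if len(s1) != a.len1 or len(s2) != a.len2:
        raise ValueError("sequences do not match the alignment's recorded lengths")
    if a.n_pairs == 0:
        return 0.0
    x1 = np.asarray([s1[i] for i in a.i_idx])
    x2 = np.asarray([s2[j] for j in a.j_idx])
    return float(np.mean(x1 == x2))


def indel_fraction(a: PairAlignment, s1=None, s2=None) -> float:
    """Gap positions / (pairs + gap positions) over the global alignment span.

    Gap positions are the unpaired residues of either sequence:
    ``(len1 - pairs) + (len2 - pairs)``.
    """
    if s1 is not None and (len(s1) != a.len1 or (s2 is not None and len(s2) != a.len2)):
        raise ValueError("sequences do not match the alignment's recorded lengths")
    gaps = (a.len1 - a.n_pairs) + (a.len2 - a.n_pairs)
    total = a.n_pairs + gaps
    return gaps / total if total else 0.0


def quality_report(scores: Sequence[QualityScore]) -> "list[dict]":
    """Per-pair rows (I, R, A, accuracy, confidence) for TSV export."""
    return [
        {"pair": k, "I": s.I, "R": s.R, "A": s.A,
         "accuracy": s.accuracy, "confidence": s.confidence}
        for k, s in enumerate(scores)
    ]
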