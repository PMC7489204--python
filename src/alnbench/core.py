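"""Shared alignment container used by the evolver, the aligners and metrics."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np


@dataclass(frozen=True)
class PairAlignment:
    """A pairwise alignment as an ordered list of matched residue-index pairs.

    ``i_idx[k]`` of sequence 1 is aligned to ``j_idx[k]`` of sequence 2
    (0-based); gap columns are implicit as the unpaired indices.  Both index
    arrays are strictly increasing (no crossings) and within the recorded
    sequence lengths.
    """

    i_idx: np.ndarray
    j_idx: np.ndarray
    len1: int
    len2: int

    def __post_init__(self) -> None:
        i = np.asarray(self.i_idx, dtype=np.int64)
        j = np.asarray(self.j_idx, dtype=np.int64)
        if i.shape != j.shape or i.ndim != 1:
            raise ValueError("index arrays must be 1-D and of equal length")
        if i.size:
            if np.any(np.diff(i) <= 0) or np.any(np.diff(j) <= 0):
                raise ValueError("alignment indices must be strictly increasing")
            if i[0] < 0 or j[0] < 0 or i[-1] >= self.len1 or j[-1] >= self.len2:
                raise ValueError("alignment indices out of sequence bounds")
        object.__setattr__(self, "i_idx", i)
        object.__setattr__(self, "j_idx", j)
        self.i_idx.setflags(write=False)
        self.j_idx.setflags(write=False)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[int, int]], len1: int, len2: int) -> "PairAlignment":
        pairs = list(pairs)
        i = np.array([p[0] for p in pairs], dtype=np.int64)
        j = np.array([p[1] for p in pairs], dtype=np.int64)
        return cls(i, j, len1, len2)

    @classmethod
    def from_gapped(cls, row1: str, row2: str, gap: str = "-") -> "PairAlignment":
        """Build from two equal-length gapped strings."""
        if len(row1) != len(row2):
            raise ValueError("gapped rows must have equal length")
        pairs, i, j = [], 0, 0
        for a, b in zip(row1, row2):
            if a != gap and b != gap:
                pairs.append((i, j))
            if a != gap:
                i += 1
            if b != gap:
                j += 1
        return cls.from_pairs(pairs, i, j)

    @property
    def n_pairs(self) -> int:
        return int(self.i_idx.size)

    def pairs(self) -> list[tuple[int, int]]:
        return list(zip(self.i_idx.tolist(), self.j_idx.tolist()))

    def pair_set(self) -> set[tuple[int, int]]:
        return set(self.pairs())

    def to_gapped(self, s1: Sequence[str], s2: Sequence[str], gap: str = "-",
                  span: str = "global") -> tuple[str, str]:
        """Render as two gapped strings.

        ``span="global"`` covers the full sequences (leading/trailing
        unpaired residues become terminal gaps); ``span="local"`` covers
        only the region from the first to the last matched pair.
        """
        if len(s1) != self.len1 or len(s2) != self.len2:
            raise ValueError("sequences do not match the recorded lengths")
        if self.n_pairs == 0:
            if span == "local":
                return "", ""
            return str(s1) + gap * self.len2, gap * self.len1 + str(s2)
        if span == "local":
            lo1, hi1 = int(self.i_idx[0]), int(self.i_idx[-1]) + 1
            lo2, hi2 = int(self.j_idx[0]), int(self.j_idx[-1]) + 1
        else:
            lo1, hi1, lo2, hi2 = 0, self.len1, 0, self.len2
        out1, out2 = [], []
        i, j = lo1, lo2
        for pi, pj in zip(self.i_idx, self.j_idx):
            while i < pi:
                out1.append(s1[i]); out2.append(gap); i += 1
            while j < pj:
                out1.append(gap); out2.append(s2[j]); j += 1
            out1.append(s1[i]); out2.append(s2[j]); i += 1; j += 1
        while i < hi1:
            out1.append(s1[i]); out2.append(gap); i += 1
        while j < hi2:
            out1.append(gap); out2.append(s2[j]); j += 1
        return "".join(out1), "".join(out2)
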