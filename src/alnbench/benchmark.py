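"""Grid evaluation, optimum selection, ranking and correlation reports.

The experiment evaluates each substitution matrix on a simulated test set
over a grid of affine gap penalties, records the macro-averaged Accuracy
and Confidence per cell, and selects the cell maximizing
``min(Accuracy, Confidence)`` -- the worst-case quality criterion used to
pick the published optima.  Matrices are then ranked by the mean of the two
optimal quality values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .aligner import GapPenalty, global_align, local_align
from .core import PairAlignment
from .evolver import TestSet, reference_alignment
from .matrices import SubstitutionMatrix, matrix_correlation
from .metrics import mean_quality, score_alignment

#: GOP values scanned by default (full integer sweep of the studied range).
DEFAULT_GOP = tuple(float(g) for g in range(3, 31))
#: GEP values scanned by default (the values appearing in the studied optima).
DEFAULT_GEP = (0.1, 0.2, 0.5, 1.0, 2.0, 3.0, 4.0, 8.0)


@dataclass(frozen=True)
class PenaltyGrid:
    gop_values: tuple[float, ...] = DEFAULT_GOP
    gep_values: tuple[float, ...] = DEFAULT_GEP

    def __post_init__(self) -> None:
        if not self.gop_values or not self.gep_values:
            raise ValueError("penalty grid must be non-empty")
        object.__setattr__(self, "gop_values", tuple(float(g) for g in self.gop_values))
        object.__setattr__(self, "gep_values", tuple(float(g) for g in self.gep_values))

    def cells(self) -> list[tuple[float, float]]:
        return [(gop, gep) for gop in self.gop_values for gep in self.gep_values]

    @classmethod
    def compact(cls) -> "PenaltyGrid":
        """A coarser sweep (GOP step 3) for desk-scale runs."""
        return cls(tuple(float(g) for g in range(3, 31, 3)),
                   (0.1, 0.5, 1.0, 2.0, 4.0, 8.0))


@dataclass(frozen=True)
class GridResult:
    """Mean quality per (gop, gep) cell for one matrix/mode/test set."""

    matrix_name: str
    mode: str
    testset_id: str
    cells: dict[tuple[float, float], tuple[float, float]] = field(repr=False)

    @property
    def optimum(self) -> tuple[float, float, float, float]:
        """(gop, gep, accuracy, confidence) maximizing min(acc, conf)."""
        return select_optimum(self)


def _align_fn(mode: str):
    if mode == "local":
        return local_align
    if mode == "global":
        return global_align
    raise ValueError(f"mode must be 'local' or 'global', got {mode!r}")


def evaluate_cell(pairs: Sequence[tuple], references: Sequence[PairAlignment],
                  m: SubstitutionMatrix, mode: str, gop: float, gep: float) -> tuple[float, float]:
    """Mean (accuracy, confidence) of one grid cell."""
    align = _align_fn(mode)
    gp = GapPenalty(gop, gep)
    scores = []
    for (s1, s2), ref in zip(pairs, references):
        result = align(s1, s2, m, gp)
        scores.append(score_alignment(ref, result.alignment))
    return mean_quality(scores)


def evaluate_grid(ts: TestSet, m: SubstitutionMatrix, mode: str,
                  grid: PenaltyGrid | None = None, *, n_jobs: int = 1) -> GridResult:
    """Fill every grid cell by aligning all pairs of the test set.

    Cells are independent work units; with ``n_jobs > 1`` they are computed
    in parallel (joblib) and merged in grid order, so results are identical
    regardless of execution order.
    """
    grid = grid or PenaltyGrid()
    _align_fn(mode)  # validate early
    pairs = [(p.s1, p.s2) for p in ts.pairs]
    references = ts.references()
    cell_list = grid.cells()
    if n_jobs > 1:
        from joblib import Parallel, delayed

        values = Parallel(n_jobs=n_jobs)(
            delayed(evaluate_cell)(pairs, references, m, mode, gop, gep)
            for gop, gep in cell_list
        )
    else:
        values = [evaluate_cell(pairs, references, m, mode, gop, gep)
                  for gop, gep in cell_list]
    cells = dict(zip(cell_list, values))
    return GridResult(matrix_name=m.name, mode=mode,
                      testset_id=f"pam{ts.pam}/n{ts.n}/seed{ts.seed}", cells=cells)


def select_optimum(gr: GridResult) -> tuple[float, float, float, float]:
    """Argmax of min(mean accuracy, mean confidence) over the grid.

    Ties break towards smaller gop, then smaller gep.
    """
    if not gr.cells:
        raise ValueError("empty grid result")
    best = None
    for (gop, gep), (acc, conf) in gr.cells.items():
        key = (-min(acc, conf), gop, gep)
        if best is None or key < best[0]:
            best = (key, (gop, gep, acc, conf))
    return best[1]


def rank_matrices(results: Iterable[GridResult]) -> pd.DataFrame:
    """Rank by the mean of optimal Accuracy and Confidence, descending.

    All results must share the same test set and mode; the returned frame
    has columns matrix, gop, gep, accuracy, confidence, mean_quality.
    """
    results = list(results)
    if not results:
        raise ValueError("no grid results to rank")
    keys = {(r.testset_id, r.mode) for r in results}
    if len(keys) > 1:
        raise ValueError(f"cannot rank across different test sets/modes: {sorted(keys)}")
    rows = []
    for r in results:
        gop, gep, acc, conf = select_optimum(r)
        rows.append({"matrix": r.matrix_name, "gop": gop, "gep": gep,
                     "accuracy": acc, "confidence": conf,
                     "mean_quality": (acc + conf) / 2.0})
    df = pd.DataFrame(rows).sort_values(
        ["mean_quality", "matrix"], ascending=[False, True], kind="mergesort"
    )
    return df.reset_index(drop=True)


def local_global_ratio(local: GridResult, global_: GridResult) -> tuple[float, float]:
    """(global/local accuracy ratio, confidence ratio) at the respective optima.

    A zero local value yields ``inf`` (unbounded marker).
    """
    if local.matrix_name != global_.matrix_name or local.testset_id != global_.testset_id:
        raise ValueError("ratio requires the same matrix and test set")
    _, _, lacc, lconf = select_optimum(local)
    _, _, gacc, gconf = select_optimum(global_)
    racc = gacc / lacc if lacc else float("inf")
    rconf = gconf / lconf if lconf else float("inf")
    return racc, rconf


def correlation_report(matrices: Sequence[SubstitutionMatrix]) -> pd.DataFrame:
    """All-pairs Pearson correlation table (symmetric, unit diagonal)."""
    if len(matrices) < 2:
        raise ValueError("correlation report needs at least two matrices")
    names = [m.name for m in matrices]
    r = np.eye(len(matrices))
    for i in range(len(matrices)):
        for j in range(i + 1, len(matrices)):
            r[i, j] = r[j, i] = matrix_correlation(matrices[i], matrices[j])
    return pd.DataFrame(r, index=names, columns=names)


# --- reference-alignment ingestion from curated MSAs ------------------------

def pairs_from_msa(path, fmt: str = "fasta", max_pairs: int | None = None,
                   seed: int = 0) -> list[tuple[str, str, PairAlignment]]:
    """Extract annotated sequence pairs from a reference multiple alignment.

    Reads a BAliBASE-style curated MSA (``fmt`` is any ``Bio.AlignIO``
    format name; "fasta" for aligned FASTA, "msf" for GCG MSF) and induces
    the reference pairwise alignment of every sequence pair: columns where
    both rows are ungapped become matched index pairs.  ``max_pairs``
    subsamples pairs reproducibly.  This is the external-data path; the
    simulated test sets are the primary benchmark surface.
    """
    from itertools import combinations

    from Bio import AlignIO

    msa = AlignIO.read(str(path), fmt)
    rows = [(rec.id, str(rec.seq).upper()) for rec in msa]
    combos = list(combinations(range(len(rows)), 2))
    if max_pairs is not None and len(combos) > max_pairs:
        rng = np.random.default_rng(seed)
        combos = [combos[k] for k in sorted(rng.choice(len(combos), max_pairs, replace=False))]
    out = []
    for i, j in combos:
        row1, row2 = rows[i][1], rows[j][1]
        aln = PairAlignment.from_gapped(row1.replace(".", "-"), row2.replace(".", "-"))
        s1 = row1.replace(".", "").replace("-", "")
        s2 = row2.replace(".", "").replace("-", "")
        out.append((s1, s2, aln))
    return out
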