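"""Substitution score matrices: loading, writing, generation, comparison.

A :class:`SubstitutionMatrix` is a symmetric 20x20 table of real-valued
alignment scores over the standard amino-acid alphabet (log-odds units;
half-bits for most bundled tables).  Named classics (PAM, BLOSUM, Gonnet)
are available through :func:`get_matrix`; arbitrary tables in the NCBI /
EMBOSS square text format load with :func:`load_matrix`.

The PAM series is special: scores at any distance can be *generated* from
the bundled PAM1 probability table as rounded Dayhoff log-odds
(``log(P^n[a,b] / f_b)``), which is how the published tables were derived.
Generated and published tables may differ by +-1 from rounding lineage.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np

from .alphabet import ALPHABET, N_RESIDUES, AminoFrequencies, dayhoff_frequencies
from .pam import _pam_power, _check_distance

_SYMMETRY_TOL = 1e-6


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A named symmetric residue-pair score table in ALPHABET order."""

    name: str
    scores: np.ndarray
    metadata: str = ""

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if s.shape != (N_RESIDUES, N_RESIDUES):
            raise ValueError("substitution matrix must be 20x20")
        if not np.all(np.isfinite(s)):
            raise ValueError("substitution matrix entries must be finite")
        if np.abs(s - s.T).max() > 1e-9:
            raise ValueError(f"matrix {self.name!r} is not symmetric")
        object.__setattr__(self, "scores", s)
        self.scores.setflags(write=False)

    def score(self, a: str, b: str) -> float:
        return float(self.scores[ALPHABET.index(a), ALPHABET.index(b)])

    def min(self) -> float:
        return float(self.scores.min())

    def max(self) -> float:
        return float(self.scores.max())


def load_matrix(source, name: str | None = None) -> SubstitutionMatrix:
    """Load a matrix from NCBI/EMBOSS square text format.

    ``source`` may be a path or an open text stream.  Extra columns such as
    ``B``, ``Z``, ``X`` and ``*`` are dropped; the 20-standard-residue
    submatrix is returned.  Asymmetry up to 1e-6 is averaged away; larger
    asymmetry raises.  A missing standard residue raises naming it.
    """
    from Bio.Align import substitution_matrices

    if hasattr(source, "read"):
        text = source.read()
        stream_name = getattr(source, "name", "<stream>")
    else:
        with open(source) as fh:
            text = fh.read()
        stream_name = str(source)
    try:
        arr = substitution_matrices.read(io.StringIO(text))
    except Exception as exc:
        raise ValueError(f"cannot parse substitution matrix {stream_name}: {exc}") from exc
    present = set(arr.alphabet)
    missing = [aa for aa in ALPHABET if aa not in present]
    if missing:
        raise ValueError(
            f"matrix {stream_name} is missing standard residue(s): {', '.join(missing)}"
        )
    idx = [arr.alphabet.index(aa) for aa in ALPHABET]
    scores = np.asarray(arr, dtype=float)[np.ix_(idx, idx)]
    asym = np.abs(scores - scores.T).max()
    if asym > _SYMMETRY_TOL:
        raise ValueError(f"matrix {stream_name} is asymmetric (max |s_ij - s_ji| = {asym:g})")
    scores = (scores + scores.T) / 2.0
    return SubstitutionMatrix(name=name or stream_name, scores=scores, metadata=f"loaded from {stream_name}")


def write_matrix(matrix: SubstitutionMatrix, destination) -> None:
    """Write in NCBI square format; round-trips exactly through load_matrix."""
    integral = np.all(matrix.scores == np.round(matrix.scores))

    def fmt(x: float) -> str:
        # repr is the shortest decimal that round-trips the float exactly
        return f"{int(x)}" if integral else repr(float(x))

    lines = [f"# {matrix.name}"]
    if matrix.metadata:
        lines += [f"# {line}" for line in matrix.metadata.splitlines()]
    width = max(6, max(len(fmt(x)) for x in matrix.scores.ravel()) + 1)
    lines.append(" " + "".join(f"{aa:>{width}}" for aa in ALPHABET))
    for i, aa in enumerate(ALPHABET):
        lines.append(aa + "".join(f"{fmt(x):>{width}}" for x in matrix.scores[i]))
    text = "\n".join(lines) + "\n"
    if hasattr(destination, "write"):
        destination.write(text)
    else:
        with open(destination, "w") as fh:
            fh.write(text)


def positive_shift(matrix: SubstitutionMatrix) -> SubstitutionMatrix:
    """Shift all entries by the smallest constant making the minimum positive.

    The shift is ``1 - floor(min)`` for a non-positive minimum (so an
    integer table stays integral with new minimum 1) and 0 for an
    all-positive table.  Score *differences*, and hence alignment optima
    under a fixed gap cost, are preserved only in ungapped columns -- this
    is the construction behind the Gonnet_p variant.
    """
    lo = matrix.min()
    shift = 0.0 if lo > 0 else 1.0 - math.floor(lo)
    if shift == 0.0:
        return matrix
    return SubstitutionMatrix(
        name=matrix.name + "_p",
        scores=matrix.scores + shift,
        metadata=(matrix.metadata + "\n" if matrix.metadata else "") + f"shifted by +{shift:g}",
    )


def matrix_correlation(m1: SubstitutionMatrix, m2: SubstitutionMatrix) -> float:
    """Pearson correlation over the 210 unique entries of two matrices.

    Uses the upper triangle including the diagonal (symmetric matrices;
    off-diagonal entries would otherwise be double-counted).  Raises for a
    constant matrix, whose correlation is undefined.
    """
    iu = np.triu_indices(N_RESIDUES)
    x, y = m1.scores[iu], m2.scores[iu]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation is undefined for a constant matrix")
    return float(np.corrcoef(x, y)[0, 1])


def pam_log_odds(distance: int, *, bits_per_unit: float | None = None,
                 freqs: AminoFrequencies | None = None) -> SubstitutionMatrix:
    """Generate an integer PAM score matrix at any distance from PAM1.

    Scores are ``round(log2(P^n[a,b] / f_b) / bits_per_unit)`` after
    symmetrizing the log-odds (exact symmetry holds analytically by the
    reversibility of the PAM chain; float renormalization breaks it at the
    1e-12 level).  ``bits_per_unit`` defaults to the scale of the published
    series: half-bits below distance 170, third-bits at and above (the
    classic PAM250 is in 10*log10 units, i.e. third-bits).
    """
    d = _check_distance(distance)
    if d == 0:
        raise ValueError("log-odds scores are undefined at distance 0 (singular odds)")
    if freqs is None:
        freqs = dayhoff_frequencies()
    if bits_per_unit is None:
        bits_per_unit = 0.5 if d < 170 else 1.0 / 3.0
    P = _pam_power(d)
    odds = P / freqs.f[None, :]
    log_odds = np.log2(odds)
    log_odds = (log_odds + log_odds.T) / 2.0
    scores = np.round(log_odds / bits_per_unit)
    return SubstitutionMatrix(
        name=f"PAM{d}",
        scores=scores,
        metadata=f"generated from PAM1 powering, {bits_per_unit:g} bits per unit",
    )


# --- named registry ---------------------------------------------------------

#: Registry names served from biopython's bundled canonical NCBI tables.
_BIOPYTHON_NAMES = {
    "PAM30": "PAM30",
    "PAM250": "PAM250",
    "BLOSUM45": "BLOSUM45",
    "BLOSUM50": "BLOSUM50",
    "BLOSUM62": "BLOSUM62",
    "GONNET250": "GONNET1992",
}

#: PAM distances generated on demand from the bundled PAM1 table.
_GENERATED_PAM = {"PAM60": 60, "PAM120": 120}


def available_matrices() -> list[str]:
    """Names resolvable by :func:`get_matrix`."""
    return sorted([*_BIOPYTHON_NAMES, *_GENERATED_PAM, "GONNET250_P"])


def get_matrix(name: str) -> SubstitutionMatrix:
    """Resolve a matrix by registry name (case-insensitive).

    ``Gonnet_p`` / ``GONNET250_P`` is the positively shifted Gonnet table.
    """
    key = name.upper()
    if key in ("GONNET_P", "GONNET250_P"):
        return positive_shift(get_matrix("GONNET250"))
    if key in _GENERATED_PAM:
        return pam_log_odds(_GENERATED_PAM[key])
    if key in _BIOPYTHON_NAMES:
        from Bio.Align import substitution_matrices

        arr = substitution_matrices.load(_BIOPYTHON_NAMES[key])
        idx = [arr.alphabet.index(aa) for aa in ALPHABET]
        scores = np.asarray(arr, dtype=float)[np.ix_(idx, idx)]
        scores = (scores + scores.T) / 2.0
        return SubstitutionMatrix(name=key, scores=scores,
                                  metadata=f"biopython table {_BIOPYTHON_NAMES[key]}")
    raise KeyError(
        f"unknown matrix {name!r}; known names: {', '.join(available_matrices())}"
    )
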