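"""The 20-letter amino-acid alphabet and background frequency tables.

Every array-valued object in this package is indexed by the classical
Dayhoff residue ordering ``ARNDCQEGHILKMFPSTWYV`` (the row/column order of
the original PAM tables).  :data:`ALPHABET` is the single source of truth
for that ordering.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import numpy as np

#: Package-wide residue ordering (Dayhoff order).
ALPHABET: str = "ARNDCQEGHILKMFPSTWYV"

#: Residue one-letter code -> index into :data:`ALPHABET`.
INDEX: dict[str, int] = {aa: i for i, aa in enumerate(ALPHABET)}

N_RESIDUES: int = 20


def encode(sequence: str) -> np.ndarray:
    """Encode a residue string as an int8 index array.

    Raises ``ValueError`` naming the first symbol outside the alphabet.
    """
    try:
        return np.fromiter(
            (INDEX[aa] for aa in sequence), dtype=np.int8, count=len(sequence)
        )
    except KeyError as exc:
        raise ValueError(f"symbol {exc.args[0]!r} is not a standard amino acid") from None


def decode(codes: Iterable[int]) -> str:
    """Inverse of :func:`encode`."""
    return "".join(ALPHABET[c] for c in codes)


@dataclass(frozen=True)
class AminoFrequencies:
    """A background amino-acid composition.

    Parameters
    ----------
    f : numpy.ndarray
        Probabilities in :data:`ALPHABET` order; strictly positive and
        summing to one (validated to 1e-9 after construction).
    """

    f: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.f, dtype=float)
        if f.shape != (N_RESIDUES,):
            raise ValueError(f"expected {N_RESIDUES} frequencies, got shape {f.shape}")
        if not np.all(f > 0):
            raise ValueError("all frequencies must be strictly positive")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError(f"frequencies must sum to 1 (got {f.sum():.12f})")
        object.__setattr__(self, "f", f)
        self.f.setflags(write=False)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float], *, normalize: bool = False) -> "AminoFrequencies":
        f = np.array([mapping[aa] for aa in ALPHABET], dtype=float)
        if normalize:
            f = f / f.sum()
        return cls(f)

    def __getitem__(self, aa: str) -> float:
        return float(self.f[INDEX[aa]])

    def as_dict(self) -> dict[str, float]:
        return {aa: float(x) for aa, x in zip(ALPHABET, self.f)}


def _read_data_table(name: str) -> list[list[str]]:
    text = resources.files("alnbench.data").joinpath(name).read_text()
    rows = []
    for line in text.splitlines():
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        rows.append(line.rstrip("\n").split("\t"))
    return rows


def dayhoff_frequencies() -> AminoFrequencies:
    """The bundled Dayhoff (1978) amino-acid composition, renormalized."""
    rows = _read_data_table("dayhoff_freqs.tsv")
    mapping = {aa: float(v) for aa, v in rows}
    return AminoFrequencies.from_mapping(mapping, normalize=True)


def dayhoff_pam1_raw() -> np.ndarray:
    """The bundled PAM1 table exactly as printed (x 1e4, columns = original).

    Returned as floats with rows = replacement residue, columns = original
    residue, both in :data:`ALPHABET` order.  Most callers want
    :func:`alnbench.pam.pam_probability` instead, which orients and
    normalizes this table.
    """
    rows = _read_data_table("dayhoff_pam1.tsv")
    header = rows[0]
    # first cell of the header row is empty (corner of the table)
    symbols = [s for s in header if s]
    if "".join(symbols) != ALPHABET:
        raise ValueError("bundled PAM1 header does not match the package alphabet")
    body = rows[1:]
    m = np.zeros((N_RESIDUES, N_RESIDUES), dtype=float)
    for r, row in enumerate(body):
        if row[0] != ALPHABET[r]:
            raise ValueError(f"bundled PAM1 row {r} labelled {row[0]!r}")
        m[r] = [float(v) for v in row[1:]]
    return m
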