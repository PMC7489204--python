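"""The PAM evolutionary model: probability matrices, identity curves.

One PAM (point accepted mutation) is the evolutionary distance at which 1%
of residues have undergone an accepted substitution.  The model is a
discrete Markov chain on the 20 residues whose one-step transition matrix
is the Dayhoff PAM1 table; distance ``n`` corresponds to the n-th matrix
power.  Because back- and convergent substitutions hide part of the
accepted mutations, the observable sequence identity decays slower than
``0.99**n``; :func:`expected_identity` gives the exact expected fraction of
identical positions between an ancestor and a descendant at a given
distance, and :func:`pam_from_identity` inverts that curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.interpolate import PchipInterpolator

from .alphabet import N_RESIDUES, AminoFrequencies, dayhoff_frequencies, dayhoff_pam1_raw

#: Largest tabulated distance of the identity<->PAM correspondence.  An
#: observed identity below the curve's value here is reported as the
#: right-censored bound "> 830" (the expected identity at 830 PAM is ~7%,
#: barely above the random-match floor).
PAM_TABLE_MAX: int = 830


@dataclass(frozen=True)
class PamProbabilityMatrix:
    """Row-stochastic residue transition table at a given PAM distance.

    ``P[a, b]`` is the probability that an ancestral residue ``a`` is
    observed as ``b`` after ``distance`` PAM of evolution.
    """

    distance: float
    P: np.ndarray

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        if P.shape != (N_RESIDUES, N_RESIDUES):
            raise ValueError("PAM probability matrix must be 20x20")
        if np.any(P < 0) or np.any(P > 1):
            raise ValueError("transition probabilities must lie in [0, 1]")
        if not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("rows of a PAM probability matrix must sum to 1")
        object.__setattr__(self, "P", P)
        self.P.setflags(write=False)


@lru_cache(maxsize=1)
def _pam1_row_stochastic() -> np.ndarray:
    """PAM1 oriented ancestor -> descendant and exactly renormalized."""
    raw = dayhoff_pam1_raw()  # rows = replacement, columns = original
    cols = raw.sum(axis=0)
    p = (raw / cols).T  # rows = original residue, now exactly stochastic
    p.setflags(write=False)
    return p


@lru_cache(maxsize=None)
def _pam_power(distance: int) -> np.ndarray:
    if distance == 0:
        m = np.eye(N_RESIDUES)
    elif distance == 1:
        m = _pam1_row_stochastic().copy()
    else:
        half = _pam_power(distance // 2)
        m = half @ half
        if distance % 2:
            m = m @ _pam1_row_stochastic()
        # cancel float drift accumulated over repeated products
        m = m / m.sum(axis=1, keepdims=True)
    m.setflags(write=False)
    return m


def pam_probability(distance: int) -> PamProbabilityMatrix:
    """The PAM1 matrix raised to the ``distance`` power.

    ``distance`` must be a non-negative integer (matrix powers of the
    one-step table); rows are renormalized to cancel float drift.
    """
    d = _check_distance(distance)
    return PamProbabilityMatrix(distance=float(d), P=_pam_power(d).copy())


def _check_distance(distance) -> int:
    d = float(distance)
    if d < 0 or d != int(d):
        raise ValueError(f"PAM distance must be a non-negative integer, got {distance!r}")
    return int(d)


def expected_identity(distance: int, freqs: AminoFrequencies | None = None) -> float:
    """Expected ancestor/descendant identity fraction at a PAM distance.

    ``sum_a f_a * P^distance[a, a]``: the probability that a position drawn
    from the background composition shows the same residue after evolving.
    Strictly decreasing in ``distance``; equals 1 at distance 0 and decays
    towards the random-match floor ``sum f_a^2``.
    """
    if freqs is None:
        freqs = dayhoff_frequencies()
    P = _pam_power(_check_distance(distance))
    return float(freqs.f @ np.diag(P))


def random_identity(freqs: AminoFrequencies) -> float:
    """Expected identity of two unrelated sequences: ``sum_i f_i**2``.

    For the Dayhoff composition this is 0.0601, the asymptotic floor of the
    identity-versus-distance curve.
    """
    return float(np.dot(freqs.f, freqs.f))


@lru_cache(maxsize=4)
def _identity_table(freqs_key: bytes) -> tuple[np.ndarray, np.ndarray]:
    f = np.frombuffer(freqs_key, dtype=float)
    ds = np.arange(PAM_TABLE_MAX + 1)
    ids = np.empty(ds.shape)
    P = np.eye(N_RESIDUES)
    one = _pam1_row_stochastic()
    for d in ds:
        ids[d] = f @ np.diag(P)
        P = P @ one
    return ds.astype(float), ids


def pam_from_identity(identity: float, freqs: AminoFrequencies | None = None) -> float:
    """Invert the expected-identity curve: identity fraction -> PAM distance.

    Monotone (PCHIP) interpolation of the tabulated curve on distances
    0..830; identities below the tabulated floor are right-censored and
    returned as ``inf`` (render as "> 830").  Raises for identities outside
    ``(0, 1]``.
    """
    if not 0.0 < identity <= 1.0:
        raise ValueError(f"identity must lie in (0, 1], got {identity!r}")
    if freqs is None:
        freqs = dayhoff_frequencies()
    ds, ids = _identity_table(freqs.f.tobytes())
    if identity >= ids[0]:
        return 0.0
    if identity < ids[-1]:
        return float("inf")
    # ids is strictly decreasing; interpolate distance as a function of id
    interp = PchipInterpolator(ids[::-1], ds[::-1])
    return float(interp(identity))


def format_pam(pam: float) -> str:
    """Render a (possibly right-censored) PAM estimate as the tables do."""
    if np.isinf(pam):
        return f"> {PAM_TABLE_MAX}"
    return f"{pam:.2f}"
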