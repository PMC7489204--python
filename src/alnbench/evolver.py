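"""Divergent-evolution sequence simulator with known reference alignments.

A test pair is produced by drawing a random ancestor from the Dayhoff
background composition and evolving two descendants from it independently,
each in two stages:

1. *Indels.*  Scanning the ancestor left to right, each position triggers
   at most one event with probability ``indel_probability(pam)``; the event
   is an insertion before the position or a deletion starting at it (50/50).
   Event lengths follow a truncated Zipf law; inserted residues are drawn
   from the background composition and positions inside a deleted block are
   skipped (they receive no further event checks).
2. *Substitutions.*  Every surviving ancestral position is passed through
   the PAM1 transition row once per cycle, for ``pam`` cycles.  Inserted
   residues are never mutated.

Each descendant carries a position map (ancestor index -> descendant index,
or -1 for deleted), and the *reference alignment* of the two descendants
matches exactly the positions that survive in both -- the ground truth
against which algorithmic alignments are scored.

Randomness is counter-based: the master seed and the pair index feed a
``numpy.random.SeedSequence`` spawn key, and each pair derives three
independent child streams (ancestor, descendant 1, descendant 2), so test
sets are reproducible and independent of generation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .alphabet import ALPHABET, N_RESIDUES, AminoFrequencies, dayhoff_frequencies, decode
from .core import PairAlignment
from .pam import _pam1_row_stochastic, _check_distance, pam_from_identity

DELETED = -1

#: Default Zipf exponent and truncation for indel lengths.
ZIPF_EXPONENT = 1.7
ZIPF_MAX_LEN = 100

#: Default ancestor length in residues (typical polypeptide chain).
DEFAULT_LENGTH = 200


def indel_probability(pam: float) -> float:
    """Per-position probability of an indel event at distance ``pam``.

    ``0.0224 - 0.0219 * exp(-0.01168 * pam)``: close to zero at small
    distances, saturating at 0.0224.  Indels accumulate more slowly than
    substitutions, which is why distant homologs keep a recognizable gap
    structure long after point identity has decayed.
    """
    if pam < 0:
        raise ValueError(f"PAM distance must be non-negative, got {pam!r}")
    return 0.0224 - 0.0219 * math.exp(-0.01168 * pam)


@lru_cache(maxsize=16)
def _zipf_cdf(exponent: float, max_len: int) -> np.ndarray:
    if exponent <= 1.0:
        raise ValueError(f"Zipf exponent must exceed 1, got {exponent!r}")
    if max_len < 1 or max_len != int(max_len):
        raise ValueError(f"max_len must be a positive integer, got {max_len!r}")
    lengths = np.arange(1, int(max_len) + 1, dtype=float)
    pmf = lengths ** (-float(exponent))
    pmf /= pmf.sum()
    return np.cumsum(pmf)


def sample_indel_length(rng: np.random.Generator, exponent: float = ZIPF_EXPONENT,
                        max_len: int = ZIPF_MAX_LEN) -> int:
    """Draw one indel length from Zipf(exponent) truncated at ``max_len``."""
    cdf = _zipf_cdf(float(exponent), int(max_len))
    return int(np.searchsorted(cdf, rng.random())) + 1


def generate_ancestor(length: int, freqs: AminoFrequencies, rng: np.random.Generator) -> np.ndarray:
    """i.i.d. residue codes drawn from ``freqs`` (length >= 1)."""
    if length < 1:
        raise ValueError("ancestor length must be at least 1")
    return rng.choice(N_RESIDUES, size=length, p=freqs.f).astype(np.int8)


@dataclass(frozen=True)
class EvolvedPair:
    """Ancestor, two independently evolved descendants, and position maps.

    ``map1[k]`` (resp. ``map2[k]``) is the index in descendant 1 (resp. 2)
    of ancestor position ``k``, or :data:`DELETED`.
    """

    ancestor: np.ndarray
    s1: np.ndarray
    s2: np.ndarray
    map1: np.ndarray
    map2: np.ndarray
    pam: int

    @property
    def seq1(self) -> str:
        return decode(self.s1)

    @property
    def seq2(self) -> str:
        return decode(self.s2)


def _two_checks_stage1(anc_len, p_event, rng, exponent, max_len):
    """Alternative indel semantics: independent insertion and deletion checks."""
    skeleton, k = [], 0
    while k < anc_len:
        if rng.random() < p_event:
            for _ in range(sample_indel_length(rng, exponent, max_len)):
                skeleton.append(DELETED - 1)  # insertion marker, replaced below
        if rng.random() < p_event:
            k += sample_indel_length(rng, exponent, max_len)
            continue
        skeleton.append(k)
        k += 1
    return skeleton


def mutate_descendant(ancestor: np.ndarray, pam: int, rng: np.random.Generator,
                      freqs: AminoFrequencies | None = None, *,
                      zipf_exponent: float = ZIPF_EXPONENT,
                      zipf_max_len: int = ZIPF_MAX_LEN,
                      two_checks: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Evolve one descendant; returns (sequence codes, ancestor->descendant map).

    ``two_checks=True`` switches to the alternative indel semantics with
    independent insertion and deletion Bernoulli draws per position (kept
    for sensitivity analysis; the default single-check semantics is the
    calibrated one).
    """
    pam = _check_distance(pam)
    if freqs is None:
        freqs = dayhoff_frequencies()
    anc_len = len(ancestor)
    p_event = indel_probability(pam)

    # Stage 1: left-to-right scan; build a skeleton of source indices where
    # -2 marks an inserted residue and k >= 0 a surviving ancestor position.
    INSERT = -2
    if two_checks:
        skeleton = [INSERT if x == DELETED - 1 else x
                    for x in _two_checks_stage1(anc_len, p_event, rng, zipf_exponent, zipf_max_len)]
    else:
        skeleton = []
        k = 0
        while k < anc_len:
            if rng.random() < p_event:
                length = sample_indel_length(rng, zipf_exponent, zipf_max_len)
                if rng.random() < 0.5:  # insertion before position k
                    skeleton.extend([INSERT] * length)
                    skeleton.append(k)
                    k += 1
                else:  # deletion starting at position k, truncated at the end
                    k += length
                continue
            skeleton.append(k)
            k += 1

    src = np.array(skeleton, dtype=np.int64)
    amap = np.full(anc_len, DELETED, dtype=np.int64)
    surviving = src >= 0
    amap[src[surviving]] = np.nonzero(surviving)[0]

    seq = np.empty(len(src), dtype=np.int8)
    n_ins = int((~surviving).sum())
    if n_ins:
        seq[~surviving] = rng.choice(N_RESIDUES, size=n_ins, p=freqs.f)

    # Stage 2: pam cycles of the PAM1 transition on ancestral positions only.
    states = ancestor[src[surviving]].astype(np.int64)
    if states.size:
        cum = np.cumsum(_pam1_row_stochastic(), axis=1)
        for _ in range(pam):
            u = rng.random(states.size)
            states = (cum[states] < u[:, None]).sum(axis=1)
    seq[surviving] = states.astype(np.int8)
    return seq, amap


def evolve_pair(pam: int, length: int = DEFAULT_LENGTH,
                rng: np.random.Generator | None = None,
                freqs: AminoFrequencies | None = None, **kwargs) -> EvolvedPair:
    """One ancestor and two independently mutated descendants.

    When ``rng`` is a Generator the three substreams (ancestor, descendant
    1, descendant 2) are spawned from it; pass a Generator built from a
    SeedSequence for reproducibility.
    """
    if rng is None:
        rng = np.random.default_rng()
    ss = rng.bit_generator.seed_seq
    child_rngs = [np.random.default_rng(s) for s in ss.spawn(3)]
    if freqs is None:
        freqs = dayhoff_frequencies()
    ancestor = generate_ancestor(length, freqs, child_rngs[0])
    s1, map1 = mutate_descendant(ancestor, pam, child_rngs[1], freqs, **kwargs)
    s2, map2 = mutate_descendant(ancestor, pam, child_rngs[2], freqs, **kwargs)
    return EvolvedPair(ancestor=ancestor, s1=s1, s2=s2, map1=map1, map2=map2, pam=int(pam))


def reference_alignment(pair: EvolvedPair) -> PairAlignment:
    """Match positions of the two descendants sharing an ancestral origin."""
    both = (pair.map1 != DELETED) & (pair.map2 != DELETED)
    i, j = pair.map1[both], pair.map2[both]
    if i.size and (np.any(np.diff(i) <= 0) or np.any(np.diff(j) <= 0)):
        raise ValueError("corrupt EvolvedPair: position maps are not monotone")
    return PairAlignment(i, j, len(pair.s1), len(pair.s2))


def sequential_alignment(pair: EvolvedPair, which: int) -> PairAlignment:
    """Ancestor-versus-descendant alignment (descendant ``which`` in {1, 2})."""
    amap = pair.map1 if which == 1 else pair.map2
    seq = pair.s1 if which == 1 else pair.s2
    keep = amap != DELETED
    anc_idx = np.nonzero(keep)[0]
    return PairAlignment(anc_idx, amap[keep], len(pair.ancestor), len(seq))


@dataclass(frozen=True)
class TestSet:
    """A reproducible collection of evolved pairs at one PAM distance."""

    pam: int
    seed: int
    pairs: list[EvolvedPair] = field(repr=False)

    @property
    def n(self) -> int:
        return len(self.pairs)

    def references(self) -> list[PairAlignment]:
        return [reference_alignment(p) for p in self.pairs]


def generate_test_set(pam: int, n: int, length: int = DEFAULT_LENGTH,
                      seed: int = 0, freqs: AminoFrequencies | None = None,
                      **kwargs) -> TestSet:
    """``n`` independent evolved pairs; pair ``k`` uses spawn key (k,)."""
    if n < 1:
        raise ValueError("a test set needs at least one pair")
    pairs = []
    for k in range(n):
        ss = np.random.SeedSequence(entropy=seed, spawn_key=(k,))
        pairs.append(evolve_pair(pam, length, np.random.default_rng(ss), freqs, **kwargs))
    return TestSet(pam=int(pam), seed=int(seed), pairs=pairs)


def testset_statistics(ts: TestSet) -> dict:
    """Mean identity/indel statistics of a test set, as the summary tables report.

    ``id`` is (identical paired residues) / (paired residues); ``indel`` is
    (gap positions) / (pairs + gap positions).  Sequential values compare
    the ancestor with each descendant; divergent values compare the two
    descendants through the reference alignment.  ``pam_id`` inverts the
    expected-identity curve at the mean divergent identity.
    """
    from .metrics import identity_fraction, indel_fraction

    seq_id = {1: [], 2: []}
    seq_indel = {1: [], 2: []}
    div_id, div_indel = [], []
    for pair in ts.pairs:
        for which, seq in ((1, pair.s1), (2, pair.s2)):
            aln = sequential_alignment(pair, which)
            seq_id[which].append(identity_fraction(aln, pair.ancestor, seq))
            seq_indel[which].append(indel_fraction(aln))
        ref = reference_alignment(pair)
        div_id.append(identity_fraction(ref, pair.s1, pair.s2))
        div_indel.append(indel_fraction(ref))
    mean_div_id = float(np.mean(div_id))
    return {
        "pam": ts.pam,
        "n": ts.n,
        "sequential_id": (float(np.mean(seq_id[1])), float(np.mean(seq_id[2]))),
        "sequential_id_mean": float(np.mean(seq_id[1] + seq_id[2])),
        "sequential_indel_mean": float(np.mean(seq_indel[1] + seq_indel[2])),
        "divergent_id": mean_div_id,
        "divergent_indel": float(np.mean(div_indel)),
        "pam_id": pam_from_identity(mean_div_id),
    }


# --- writers ----------------------------------------------------------------

def write_test_set(ts: TestSet, out_dir) -> None:
    """Write pairs.fasta, ref.afa (gapped reference) and ref_pairs.tsv."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "pairs.fasta", "w") as fa, \
         open(out / "ref.afa", "w") as afa, \
         open(out / "ref_pairs.tsv", "w") as tsv:
        tsv.write("pair\ti\tj\n")
        for k, pair in enumerate(ts.pairs):
            ref = reference_alignment(pair)
            fa.write(f">pair{k}|s1 pam={ts.pam}\n{pair.seq1}\n")
            fa.write(f">pair{k}|s2 pam={ts.pam}\n{pair.seq2}\n")
            row1, row2 = ref.to_gapped(pair.seq1, pair.seq2)
            afa.write(f">pair{k}|s1\n{row1}\n>pair{k}|s2\n{row2}\n")
            for i, j in ref.pairs():
                tsv.write(f"pair{k}\t{i}\t{j}\n")
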