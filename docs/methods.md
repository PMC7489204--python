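# Methods

## The evolutionary model

Sequences live in the 20-letter amino-acid alphabet, ordered
`ARNDCQEGHILKMFPSTWYV` throughout the package. Substitution dynamics
follow the classical Dayhoff PAM chain: a 20×20 one-step
mutation-probability table (PAM1) whose frequency-weighted diagonal is
0.99, i.e. one accepted point mutation per hundred residues per step.
Distance *n* in PAM units corresponds to the *n*-th matrix power of PAM1.
The bundled PAM1 table and amino-acid background frequencies are the
Dayhoff (1978) values, stored as TSV package data; the table is
renormalized column-wise on load to cancel the rounding of the printed
probabilities (entries are integers ×10⁻⁴), and its internal consistency
is checked in the test suite via column sums, detailed balance
(f_j·M_ij ≈ f_i·M_ji) and the 1-PAM diagonal property.

Two derived curves matter downstream:

- **expected_identity(d)** = Σ_a f_a · P^d[a,a], the probability that a
  position drawn from the background shows the same residue after *d* PAM.
  It decays from 1 towards the random-match floor Σ f_a² ≈ 0.0601 (the
  value for the Dayhoff composition). Back- and convergent substitutions
  make this decay much slower than 0.99^d: 30 PAM still shows ~75%
  identity, 250 PAM ~20%.
- **pam_from_identity(id)**, its numeric inverse. The curve is tabulated
  by powering PAM1 to 830 PAM and inverted with monotone (PCHIP)
  interpolation; identities below the 830-PAM value (~0.066) are reported
  as the right-censored bound "> 830" (`inf` in code). We invert the
  extended curve directly rather than extrapolating a short printed table
  polynomially, because powering is exact and monotone at any distance.

## The divergent-evolution simulator

A test pair is built from one ancestor (default 200 residues, i.i.d. from
the Dayhoff background) and two descendants evolved *independently* at the
same PAM distance. Each descendant is produced in two stages.

**Stage 1 — indels.** Scanning ancestor positions left to right, each
position triggers at most one event with probability

    P(indel) = 0.0224 − 0.0219·exp(−0.01168·PAM)

(≈ 0.0005 at PAM 0, saturating at 0.0224). An event is an insertion
before the position or a deletion starting at it, with equal probability.
Lengths are Zipf-distributed, P(L) ∝ L^(−1.7), truncated at 100 residues;
inserted residues are drawn from the background; deletions truncate at the
sequence end; neither inserted residues nor deleted blocks receive further
event checks. An alternative semantics with two independent Bernoulli
checks per position (insertion *and* deletion) is available behind
`two_checks=True` for sensitivity analysis.

**Stage 2 — substitutions.** Every surviving ancestral position is passed
through the PAM1 transition row once per cycle, for PAM cycles. Inserted
residues are never mutated.

Each descendant carries a position map (ancestor index → descendant index
or deleted); the **reference alignment** of a pair matches exactly the
positions surviving in both descendants, composed through the two maps.
The identity fraction of an alignment is (identical pairs)/(pairs); the
indel fraction is (unpaired residues)/(pairs + unpaired residues) over the
global span.

### Calibration of the indel sub-model

The event-probability formula fixes how *often* indels occur but not how
*long* they are; the Zipf exponent follows the classical empirical indel
-length studies (≈1.7), leaving the truncation as the only free parameter.
We calibrated it once against the simulator's published summary behaviour
— a sequential (ancestor/descendant) indel fraction of ≈0.033 at PAM 30
and divergent indel fractions of ≈0.066/0.107/0.147 at PAM 30/60/120 —
which the combination (exponent 1.7, truncation 100; mean event length
5.26) reproduces to within ~0.01 across the board. Truncating at 50
instead depresses all indel fractions by ~20%. Both parameters remain
configurable per call. The identity statistics are insensitive to this
choice because substitutions and indels are independent processes and
identity is measured over paired positions only.

### Randomness and reproducibility

One master seed defines a test set. Pair *k* uses
`numpy.random.SeedSequence(entropy=seed, spawn_key=(k,))`, from which
three child streams are spawned (ancestor, descendant 1, descendant 2).
Test sets are therefore reproducible bit-for-bit, order-independent, and a
prefix of a larger set equals the smaller set with the same seed.

## Aligners

Global (Needleman–Wunsch) and local (Smith–Waterman) optima are computed
by the three-state Gotoh recurrences, compiled with numba. Conventions,
each of which can shift published-style optima by small offsets:

- a gap of length L costs `GOP + (L−1)·GEP`; scores are real-valued
  (GEP down to 0.1 is meaningful);
- terminal gaps in global mode are penalized (end-to-end alignment,
  matching the simulator's end-to-end references); a `free_end_gaps`
  switch provides semiglobal alignment;
- adjacent gaps in opposite sequences are two separate gaps (each pays an
  opening);
- tie-breaks are deterministic: diagonal > gap in sequence 2 > gap in
  sequence 1 during the forward pass, first-occurrence (row-major) choice
  of the local maximum cell, and continuation preferred over a fresh local
  start only when strictly positive.

The suite validates both modes against brute-force oracles (affine-state
recursion for global; exhaustive substring enumeration for local) on short
random pairs, checks the linear-gap special case GOP = GEP against a
stateless DP, and re-scores every returned alignment from its pair list to
confirm score/alignment consistency to 1e-6.

## Quality metrics and the benchmark procedure

Accuracy = I/R and Confidence = I/A over residue–residue comparisons; gap
columns are never comparisons. An empty local alignment has A = 0 and
Confidence defined as 0, and such pairs stay in the averages (sets of
distant pairs genuinely contain total misses, which is part of the
signal). Averages over a test set are macro-averages (per-pair means),
not pooled counts. Note the direction implied by the definitions: harsh
local penalties shrink algorithmic alignments, so A < R and Confidence
exceeds Accuracy on distant test sets.

The default penalty grid is GOP ∈ {3, 4, …, 30} × GEP ∈ {0.1, 0.2, 0.5,
1, 2, 3, 4, 8}; cells are independent and may be computed in parallel,
with results identical regardless of execution order. The optimum of a
grid maximizes min(Accuracy, Confidence), ties broken toward smaller GOP
then smaller GEP; matrices are ranked by the mean of the two optimal
values; the global/local ratio divides the global optimum by the local
optimum per metric (∞ marks a zero local value).

## Matrices

The registry serves PAM30, PAM250, BLOSUM45/50/62 and Gonnet250 from
biopython's canonical tables. PAM60 and PAM120, which biopython does not
ship, are generated from the bundled PAM1: score(a,b) =
round(log₂(P^d[a,b]/f_b)/s) with s = ½ bit (third-bits at distance ≥ 170,
matching the scale of the classical published series). Generated and
historically published tables can differ by ±1 from rounding lineage; the
generated PAM250 correlates with the published one at r > 0.97.
`Gonnet_p` adds the smallest integer constant making all Gonnet250 entries
positive (shift = 1 − floor(min)), preserving score differences. Any
other matrix loads from NCBI/EMBOSS square text format (ambiguity columns
dropped, asymmetry beyond 1e-6 rejected, missing residues reported by
name); the writer uses shortest-round-trip number formatting so
write→load is bit-exact.

Matrix correlation is Pearson's r over the 210 unique entries (upper
triangle including the diagonal) — off-diagonal entries of a symmetric
table would otherwise be double-counted — and is undefined (raises) for a
constant matrix.

## Problem sizes and tolerances

The published-scale statistics (identity/indel fractions, inferred PAM)
use 1000-pair sets of 200-residue sequences, where the standard error of a
mean identity is ~0.001; the suite asserts them to ±0.01 (±5 PAM for
inferred distances, ±0.006 for the convention-sensitive indel fraction).
Alignment-quality values at fixed penalty cells are checked on 300-pair
sets (SE ≈ 0.002–0.01 depending on the regime) to ±0.005 in the
high-identity regime and ±0.03–0.04 on distant sets; the global/local
ratio, whose error compounds, to ±0.8. Grid-optimum searches in tests use
a coarsened grid (GOP step 3), which can only under-estimate optima and
leaves the tested orderings unchanged.

## What the simulation does and does not show

The generator emulates the homogeneous Dayhoff process: every position
evolves identically and independently, insertions never mutate afterwards,
and indel placement is uniform. Real proteins violate all three —
site-specific rates, conserved cores versus variable loops, structure
-preserving constraints — so absolute Accuracy/Confidence values here
transfer to real data only qualitatively. The benchmark's comparative
statements (long-distance matrices dominate on distant pairs and lose
nothing on close pairs; global alignment is far more forgiving of a
mismatched matrix than local) are the robust outputs. Curated reference
MSAs can be ingested through `benchmark.pairs_from_msa` (aligned FASTA or
MSF) as an external-data path, but no claims about specific curated
benchmark numbers are made: reference-pair sampling schemes differ between
studies and are not reproducible from our side.

Known limitations: the DP kernels are full-matrix (O(nm) memory, no
banding or linear-space variants); only symmetric 20-letter matrices are
supported; the PAM(indel) column of divergent summary statistics (inverse
of the indel-accumulation curve) is not implemented — only PAM(id) is;
and the two-checks indel semantics is provided but uncalibrated.
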