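"""Divergent-evolution simulator: events, maps, reference alignments."""

import numpy as np
import pytest
from scipy import stats

from alnbench import (
    EvolvedPair,
    evolve_pair,
    generate_ancestor,
    generate_test_set,
    identity_fraction,
    indel_probability,
    mutate_descendant,
    reference_alignment,
    sample_indel_length,
)
from alnbench.evolver import DELETED, sequential_alignment, write_test_set
from alnbench.pam import _pam1_row_stochastic


class TestIndelProbability:
    def test_zero_distance(self):
        assert indel_probability(0) == pytest.approx(0.0005, abs=1e-12)

    def test_pam30(self):
        assert indel_probability(30) == pytest.approx(0.0224 - 0.0219 * np.exp(-0.3504), rel=1e-12)
        assert indel_probability(30) == pytest.approx(0.006973, abs=1e-6)

    def test_saturation(self):
        assert indel_probability(1e4) == pytest.approx(0.0224, abs=1e-6)

    def test_monotone_increasing(self):
        ps = [indel_probability(d) for d in range(0, 500, 25)]
        assert all(a < b for a, b in zip(ps, ps[1:]))

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            indel_probability(-1)


class TestIndelLength:
    def test_degenerate_support(self, rng):
        assert all(sample_indel_length(rng, max_len=1) == 1 for _ in range(50))

    def test_zipf_goodness_of_fit(self):
        rng = np.random.default_rng(7)
        max_len, expo, n = 50, 1.7, 200_000
        draws = np.array([sample_indel_length(rng, expo, max_len) for _ in range(n)])
        expected_pmf = np.arange(1, max_len + 1, dtype=float) ** -expo
        expected_pmf /= expected_pmf.sum()
        # pool the sparse tail so every chi-square bin has decent mass
        edges = [1, 2, 3, 4, 5, 7, 10, 15, 25, max_len + 1]
        obs = np.array([((draws >= lo) & (draws < hi)).sum() for lo, hi in zip(edges, edges[1:])])
        exp = np.array([expected_pmf[lo - 1:hi - 1].sum() * n for lo, hi in zip(edges, edges[1:])])
        chi2 = ((obs - exp) ** 2 / exp).sum()
        assert chi2 < stats.chi2.ppf(0.999, df=len(obs) - 1)

    def test_larger_exponent_gives_shorter_indels(self):
        rng = np.random.default_rng(8)
        mean_17 = np.mean([sample_indel_length(rng, 1.7) for _ in range(20_000)])
        mean_25 = np.mean([sample_indel_length(rng, 2.5) for _ in range(20_000)])
        assert mean_25 < mean_17

    @pytest.mark.parametrize("kwargs", [{"exponent": 1.0}, {"exponent": 0.5}, {"max_len": 0}])
    def test_invalid_parameters_rejected(self, rng, kwargs):
        with pytest.raises(ValueError):
            sample_indel_length(rng, **kwargs)


class TestAncestor:
    def test_minimal_length(self, dayhoff):
        assert generate_ancestor(1, dayhoff, np.random.default_rng(0)).size == 1
        with pytest.raises(ValueError):
            generate_ancestor(0, dayhoff, np.random.default_rng(0))

    def test_deterministic_under_fixed_seed(self, dayhoff):
        a = generate_ancestor(200, dayhoff, np.random.default_rng(42))
        b = generate_ancestor(200, dayhoff, np.random.default_rng(42))
        np.testing.assert_array_equal(a, b)

    def test_composition_matches_frequencies(self, dayhoff):
        rng = np.random.default_rng(9)
        n = 100_000
        codes = generate_ancestor(n, dayhoff, rng)
        counts = np.bincount(codes, minlength=20)
        se = np.sqrt(dayhoff.f * (1 - dayhoff.f) / n)
        assert np.all(np.abs(counts / n - dayhoff.f) < 3 * se)


class TestMutateDescendant:
    def test_zero_distance_is_identity(self, dayhoff):
        # at PAM 0 the substitution stage is skipped and the indel
        # probability is 5e-4; this seed draws no events
        anc = generate_ancestor(200, dayhoff, np.random.default_rng(5))
        seq, amap = mutate_descendant(anc, 0, np.random.default_rng(5), dayhoff)
        np.testing.assert_array_equal(seq, anc)
        np.testing.assert_array_equal(amap, np.arange(200))

    def test_single_cycle_marginal_matches_pam1_row(self, dayhoff):
        rng = np.random.default_rng(11)
        n = 100_000
        anc = np.zeros(n, dtype=np.int8)  # all alanine
        seq, amap = mutate_descendant(anc, 1, rng, dayhoff)
        surviving = amap != DELETED
        outcomes = seq[amap[surviving]]
        emp = np.bincount(outcomes, minlength=20) / surviving.sum()
        row = _pam1_row_stochastic()[0]
        se = np.sqrt(row * (1 - row) / surviving.sum())
        assert np.all(np.abs(emp - row) <= 3 * se + 1e-9)

    def test_conservation_of_length(self, dayhoff):
        rng = np.random.default_rng(12)
        anc = generate_ancestor(200, dayhoff, rng)
        for pam in (30, 120):
            seq, amap = mutate_descendant(anc, pam, rng, dayhoff)
            surviving = int((amap != DELETED).sum())
            inserted = len(seq) - surviving
            assert inserted >= 0
            # inserted positions are exactly the complement of the map image
            image = set(amap[amap != DELETED].tolist())
            assert len(image) == surviving
            assert len(set(range(len(seq))) - image) == inserted
            assert len(seq) == surviving + inserted

    def test_map_is_monotone(self, dayhoff):
        rng = np.random.default_rng(13)
        anc = generate_ancestor(300, dayhoff, rng)
        _, amap = mutate_descendant(anc, 120, rng, dayhoff)
        kept = amap[amap != DELETED]
        assert np.all(np.diff(kept) > 0)

    def test_two_checks_variant_runs(self, dayhoff):
        rng = np.random.default_rng(14)
        anc = generate_ancestor(200, dayhoff, rng)
        seq, amap = mutate_descendant(anc, 60, rng, dayhoff, two_checks=True)
        kept = amap[amap != DELETED]
        assert np.all(np.diff(kept) > 0)
        assert len(seq) >= kept.size


class TestEvolvePair:
    def test_bitwise_deterministic(self):
        ss = np.random.SeedSequence(entropy=99, spawn_key=(0,))
        p1 = evolve_pair(60, 200, np.random.default_rng(ss))
        p2 = evolve_pair(60, 200, np.random.default_rng(np.random.SeedSequence(entropy=99, spawn_key=(0,))))
        np.testing.assert_array_equal(p1.s1, p2.s1)
        np.testing.assert_array_equal(p1.s2, p2.s2)
        np.testing.assert_array_equal(p1.map1, p2.map1)

    def test_branches_are_independent(self):
        ts = generate_test_set(60, 500, seed=21)
        id1 = [identity_fraction(sequential_alignment(p, 1), p.ancestor, p.s1) for p in ts.pairs]
        id2 = [identity_fraction(sequential_alignment(p, 2), p.ancestor, p.s2) for p in ts.pairs]
        r = np.corrcoef(id1, id2)[0, 1]
        assert abs(r) < 0.1


class TestReferenceAlignment:
    def test_no_event_pair_aligns_everything(self, dayhoff):
        anc = generate_ancestor(50, dayhoff, np.random.default_rng(3))
        ident = np.arange(50)
        pair = EvolvedPair(anc, anc.copy(), anc.copy(), ident.copy(), ident.copy(), 0)
        ref = reference_alignment(pair)
        assert ref.n_pairs == 50
        assert ref.pairs() == [(i, i) for i in range(50)]

    def test_hand_composed_deletions(self):
        # ancestor of length 4; descendant 1 deleted position 2, descendant 2
        # deleted position 3: only positions 0 and 1 survive in both
        anc = np.array([0, 0, 0, 0], dtype=np.int8)
        s1 = np.array([0, 0, 0], dtype=np.int8)
        s2 = np.array([0, 0, 0], dtype=np.int8)
        map1 = np.array([0, 1, DELETED, 2])
        map2 = np.array([0, 1, 2, DELETED])
        ref = reference_alignment(EvolvedPair(anc, s1, s2, map1, map2, 0))
        assert ref.pairs() == [(0, 0), (1, 1)]

    def test_pair_count_bounded_by_sequence_lengths(self):
        ts = generate_test_set(120, 30, seed=17)
        for p in ts.pairs:
            ref = reference_alignment(p)
            assert ref.n_pairs <= min(len(p.s1), len(p.s2))


class TestTestSet:
    def test_single_pair_set_reproduces_evolve_pair(self):
        ts = generate_test_set(60, 1, seed=5)
        ss = np.random.SeedSequence(entropy=5, spawn_key=(0,))
        direct = evolve_pair(60, 200, np.random.default_rng(ss))
        np.testing.assert_array_equal(ts.pairs[0].s1, direct.s1)
        np.testing.assert_array_equal(ts.pairs[0].s2, direct.s2)

    def test_pairs_are_order_independent(self):
        big = generate_test_set(30, 5, seed=5)
        small = generate_test_set(30, 3, seed=5)
        for k in range(3):
            np.testing.assert_array_equal(big.pairs[k].s1, small.pairs[k].s1)

    def test_divergent_identity_matches_sequential_at_double_distance(self):
        # internal-consistency property of divergent evolution: two branches
        # of 30 PAM separate the descendants like 60 PAM of sequential
        # evolution (published: 0.5793 vs 0.5792)
        ts30 = generate_test_set(30, 200, seed=31)
        ts60 = generate_test_set(60, 200, seed=32)
        div30 = np.mean([identity_fraction(reference_alignment(p), p.s1, p.s2) for p in ts30.pairs])
        seq60 = np.mean(
            [identity_fraction(sequential_alignment(p, w), p.ancestor, getattr(p, f"s{w}"))
             for p in ts60.pairs for w in (1, 2)]
        )
        se = 0.035 / np.sqrt(200)  # per-pair spread of the identity fraction
        assert abs(div30 - seq60) < 2 * np.sqrt(2) * se

    def test_writers_emit_consistent_files(self, tmp_path):
        ts = generate_test_set(60, 3, seed=4)
        write_test_set(ts, tmp_path)
        fasta = (tmp_path / "pairs.fasta").read_text().splitlines()
        assert sum(1 for line in fasta if line.startswith(">")) == 6
        afa = (tmp_path / "ref.afa").read_text().splitlines()
        # gapped rows of each pair must have equal length
        rows = [line for line in afa if not line.startswith(">")]
        for k in range(0, len(rows), 2):
            assert len(rows[k]) == len(rows[k + 1])
        tsv = (tmp_path / "ref_pairs.tsv").read_text().splitlines()
        assert tsv[0] == "pair\ti\tj"
        assert len(tsv) - 1 == sum(reference_alignment(p).n_pairs for p in ts.pairs)
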