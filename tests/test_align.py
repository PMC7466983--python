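import numpy as np
import pytest

from evofoot.align import (
    AlignParams, align_species, build_kmer_index, chain_and_extend, find_seeds,
)
from evofoot.seqio import SeqRecord, reverse_complement

from conftest import random_dna
from oracles import (
    brute_force_kmer_hits, mutate_with_divergence, smith_waterman_identity_positions,
    ungapped_identity_positions,
)


class TestKmerIndex:
    def test_palindromic_8mer_both_strands(self):
        index = build_kmer_index(SeqRecord("t", "ACGTACGT"), k=8)
        assert index["ACGTACGT"] == [(0, "+"), (0, "-")]

    def test_forward_kmer_count(self, rng):
        seq = random_dna(rng, 100)
        index = build_kmer_index(SeqRecord("t", seq), k=9)
        n_fwd = sum(1 for hits in index.values() for p, s in hits if s == "+")
        assert n_fwd == 100 - 8

    def test_poly_a_single_key(self):
        index = build_kmer_index(SeqRecord("t", "A" * 20), k=9)
        fwd = [p for p, s in index["AAAAAAAAA"] if s == "+"]
        assert fwd == list(range(12))

    def test_k_longer_than_sequence(self):
        with pytest.raises(ValueError):
            build_kmer_index(SeqRecord("t", "ACGT"), k=5)

    def test_n_kmers_omitted(self):
        index = build_kmer_index(SeqRecord("t", "ACGTNACGTACGT"), k=4)
        assert not any("N" in k for k in index)


class TestFindSeeds:
    def test_self_match_single_diagonal(self, rng):
        seq = random_dna(rng, 80)
        rec = SeqRecord("t", seq)
        seeds = find_seeds(rec, build_kmer_index(rec, 11), 11)
        plus = [s for s in seeds if s.strand == "+"]
        assert all(s.ref_pos == s.test_pos for s in plus)
        assert len(plus) == 80 - 10

    def test_revcomp_all_minus(self, rng):
        seq = random_dna(rng, 80)
        ref = SeqRecord("r", seq)
        index = build_kmer_index(SeqRecord("t", reverse_complement(seq)), 11)
        seeds = find_seeds(ref, index, 11)
        assert seeds and all(s.strand == "-" for s in seeds)

    def test_matches_brute_force(self, rng):
        for _ in range(3):
            a, b = random_dna(rng, 200), random_dna(rng, 200)
            # plant some shared material so the hit set is non-trivial
            b = b[:50] + a[20:60] + b[90:]
            ref, test = SeqRecord("r", a), SeqRecord("t", b)
            seeds = find_seeds(ref, build_kmer_index(test, 9), 9)
            got = {(s.ref_pos, s.test_pos, s.strand) for s in seeds}
            assert got == brute_force_kmer_hits(a, b, 9)


class TestChainAndExtend:
    def _chains(self, ref, test, params=None):
        params = params or AlignParams()
        seeds = []
        for k in params.k_values:
            seeds += find_seeds(ref, build_kmer_index(test, k), k, params.max_kmer_hits)
        return chain_and_extend(seeds, ref, test, params)

    def test_exact_copy_single_block(self, ref300):
        test = SeqRecord("t", ref300.residues)
        chains = self._chains(ref300, test)
        assert len(chains) == 1
        assert len(chains[0].blocks) == 1
        assert chains[0].score == 300
        b = chains[0].blocks[0]
        assert (b.ref_start, b.ref_end, b.test_start, b.test_end) == (0, 300, 0, 300)

    def test_central_deletion_flanking_blocks(self, ref300):
        test = SeqRecord("t", ref300.residues[:120] + ref300.residues[170:])
        (chain,) = self._chains(ref300, test)
        first, last = chain.blocks[0], chain.blocks[-1]
        # flanks aligned on their true diagonals; exact interior junction
        # placement may vary where the fill DP finds equal-scoring paths
        assert (first.ref_start, first.test_start) == (0, 0)
        assert (last.ref_end, last.test_end) == (300, 250)
        assert last.ref_start - last.test_start == 50
        marks = align_species(ref300, test).conserved
        assert marks[:112].all() and marks[178:].all()
        assert marks[120:170].sum() <= 10  # deleted bases mostly unmarked

    def test_inverted_segment_reported_on_minus(self, ref300):
        s = ref300.residues
        test = SeqRecord("t", s[:120] + reverse_complement(s[120:180]) + s[180:])
        chains = self._chains(ref300, test)
        strands = {c.strand for c in chains}
        assert strands == {"+", "-"}
        minus = next(c for c in chains if c.strand == "-")
        assert minus.ref_start >= 110 and minus.ref_end <= 190
        plus = next(c for c in chains if c.strand == "+")
        assert plus.ref_start == 0 and plus.ref_end == 300

    def test_block_invariants(self, rng):
        for _ in range(5):
            s = random_dna(rng, 250)
            t = mutate_with_divergence(s, 0.08, 2, rng)
            for chain in self._chains(SeqRecord("r", s), SeqRecord("t", t)):
                prev_end = -1
                for b in chain.blocks:
                    assert b.ref_end - b.ref_start == b.test_end - b.test_start
                    assert b.ref_start >= prev_end
                    prev_end = b.ref_end
                if chain.strand == "+":
                    starts = [b.test_start for b in chain.blocks]
                    assert starts == sorted(starts)
                else:
                    starts = [b.test_start for b in chain.blocks]
                    assert starts == sorted(starts, reverse=True)


class TestAlignSpecies:
    def test_self_all_marked(self, ref300):
        res = align_species(ref300, SeqRecord("t", ref300.residues))
        assert res.conserved.all()

    def test_unrelated_nothing_marked(self, ref300, rng):
        res = align_species(ref300, SeqRecord("t", random_dna(rng, 300)))
        assert not res.conserved.any()

    def test_strand_symmetry(self, rng):
        for _ in range(5):
            s = random_dna(rng, 220)
            t = mutate_with_divergence(s, 0.1, 1, rng)
            ref = SeqRecord("r", s)
            fwd = align_species(ref, SeqRecord("t", t)).conserved
            rev = align_species(ref, SeqRecord("t", reverse_complement(t))).conserved
            assert (fwd == rev).all()

    def test_matches_local_dp_oracle_with_indels(self, rng):
        agree = 0
        for _ in range(20):
            s = random_dna(rng, 180)
            t = mutate_with_divergence(s, float(rng.uniform(0.03, 0.1)), int(rng.integers(0, 3)), rng)
            mine = set(np.nonzero(align_species(SeqRecord("r", s), SeqRecord("t", t)).conserved)[0])
            if mine == smith_waterman_identity_positions(s, t):
                agree += 1
        assert agree >= 18

    def test_matches_ungapped_identity_at_low_divergence(self, rng):
        for _ in range(5):
            s = random_dna(rng, 200)
            t = mutate_with_divergence(s, 0.04, 0, rng)
            mine = set(np.nonzero(align_species(SeqRecord("r", s), SeqRecord("t", t)).conserved)[0])
            assert mine == ungapped_identity_positions(s, t)

    def test_marked_bases_lie_in_chain_blocks(self, rng):
        s = random_dna(rng, 250)
        t = mutate_with_divergence(s, 0.12, 2, rng)
        res = align_species(SeqRecord("r", s), SeqRecord("t", t))
        in_blocks = np.zeros(250, dtype=bool)
        for c in res.chains:
            for b in c.blocks:
                in_blocks[b.ref_start : b.ref_end] = True
        assert not (res.conserved & ~in_blocks).any()

    @pytest.mark.parametrize("field,values", [
        ("min_block_len", [6, 9, 15]),
        ("min_chain_matches", [20, 40, 80]),
    ])
    def test_threshold_monotonicity(self, rng, field, values):
        s = random_dna(rng, 300)
        t = mutate_with_divergence(s, 0.15, 2, rng)
        counts = []
        prev_marks = None
        for v in values:
            params = AlignParams(**{field: v})
            marks = align_species(SeqRecord("r", s), SeqRecord("t", t), params).conserved
            if prev_marks is not None:
                assert not (marks & ~prev_marks).any()
            prev_marks = marks
            counts.append(int(marks.sum()))
        assert counts == sorted(counts, reverse=True)

    def test_params_validation(self):
        with pytest.raises(ValueError):
            AlignParams(k_values=())
        with pytest.raises(ValueError):
            AlignParams(k_values=(3,))
        with pytest.raises(ValueError):
            AlignParams(max_chain_gap=0)
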