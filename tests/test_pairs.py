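"""Pair scanner: detection criteria, orientation, triplets, oracle parity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cisnat.intervals import OTHER_BIOTYPE
from cisnat.pairs import (
    FIVE_PRIME,
    THREE_PRIME,
    brute_force_pairs,
    classify_orientation,
    find_candidate_pairs,
    find_triplet_sets,
    make_pair_id,
)

from conftest import make_gene, random_genome


class TestDetectionCriteria:
    def test_basic_antisense_overlap(self):
        genes = [make_gene("A", 100, 500, "+"), make_gene("B", 450, 900, "-")]
        (pair,) = find_candidate_pairs(genes)
        assert (pair.overlap.start, pair.overlap.end) == (450, 500)
        assert pair.overlap_length == 50
        assert pair.pair_id == make_pair_id("A", "B")

    def test_21bp_overlap_rejected_22_accepted(self):
        # the >21 nt rule is strict: exactly 21 bp fails, 22 passes
        genes21 = [make_gene("A", 100, 500, "+"), make_gene("B", 479, 900, "-")]
        genes22 = [make_gene("A", 100, 500, "+"), make_gene("B", 478, 900, "-")]
        assert find_candidate_pairs(genes21) == []
        (pair,) = find_candidate_pairs(genes22)
        assert pair.overlap_length == 22

    def test_same_strand_overlap_excluded(self):
        genes = [make_gene("A", 100, 500, "+"), make_gene("B", 300, 900, "+")]
        assert find_candidate_pairs(genes) == []

    def test_non_coding_partner_excluded(self):
        genes = [
            make_gene("A", 100, 500, "+"),
            make_gene("B", 200, 900, "-", biotype=OTHER_BIOTYPE),
        ]
        assert find_candidate_pairs(genes) == []

    def test_different_chromosomes_never_pair(self):
        genes = [
            make_gene("A", 100, 500, "+"),
            make_gene("B", 100, 500, "-", chrom="Chr2"),
        ]
        assert find_candidate_pairs(genes) == []

    def test_empty_input(self):
        assert find_candidate_pairs([]) == []

    def test_each_pair_emitted_once_and_sorted(self):
        genes = [
            make_gene("C", 100, 1000, "+"),
            make_gene("B", 900, 2000, "-"),
            make_gene("A", 1900, 3000, "+"),
        ]
        pairs = find_candidate_pairs(genes)
        assert [p.pair_id for p in pairs] == ["B|C", "A|B"]
        assert len({p.pair_id for p in pairs}) == 2


class TestOrientation:
    def test_convergent_is_three_prime(self):
        a, b = make_gene("A", 100, 500, "+"), make_gene("B", 450, 900, "-")
        assert classify_orientation(a, b) == (THREE_PRIME, False)

    def test_divergent_is_five_prime(self):
        a, b = make_gene("A", 100, 500, "-"), make_gene("B", 450, 900, "+")
        assert classify_orientation(a, b) == (FIVE_PRIME, False)

    def test_containment_nearest_ends_rule(self):
        # 3' ends are 600 apart, 5' ends 400 apart -> five_prime
        a, b = make_gene("A", 100, 900, "+"), make_gene("B", 300, 500, "-")
        assert classify_orientation(a, b) == (FIVE_PRIME, True)

    def test_containment_near_three_prime_end(self):
        a, b = make_gene("A", 100, 900, "+"), make_gene("B", 700, 880, "-")
        assert classify_orientation(a, b) == (THREE_PRIME, True)

    def test_identical_spans_tie_break(self):
        a, b = make_gene("A", 100, 500, "+"), make_gene("B", 100, 500, "-")
        assert classify_orientation(a, b) == (THREE_PRIME, True)

    def test_argument_order_irrelevant(self):
        a, b = make_gene("A", 100, 500, "+"), make_gene("B", 450, 900, "-")
        assert classify_orientation(a, b) == classify_orientation(b, a)

    def test_rejects_same_strand(self):
        a, b = make_gene("A", 100, 500, "+"), make_gene("B", 450, 900, "+")
        with pytest.raises(ValueError):
            classify_orientation(a, b)


class TestTriplets:
    def test_two_linked_pairs_form_one_set(self):
        genes = [
            make_gene("A", 100, 1000, "+"),
            make_gene("B", 900, 2000, "-"),
            make_gene("C", 1900, 3000, "+"),
        ]
        pairs = find_candidate_pairs(genes)
        (trip,) = find_triplet_sets(pairs)
        assert set(trip.gene_ids) == {"A", "B", "C"}
        assert trip.gene_ids[1] == "B"
        assert set(trip.pair_ids) == {"A|B", "B|C"}

    def test_disjoint_pairs_yield_no_sets(self):
        genes = [
            make_gene("A", 100, 1000, "+"),
            make_gene("B", 900, 2000, "-"),
            make_gene("C", 5000, 6000, "+"),
            make_gene("D", 5900, 7000, "-"),
        ]
        assert find_triplet_sets(find_candidate_pairs(genes)) == []

    def test_four_gene_chain_yields_two_overlapping_sets(self):
        genes = [
            make_gene("A", 100, 1000, "+"),
            make_gene("B", 900, 2000, "-"),
            make_gene("C", 1900, 3000, "+"),
            make_gene("D", 2900, 4000, "-"),
        ]
        pairs = find_candidate_pairs(genes)
        trips = find_triplet_sets(pairs)
        assert {frozenset(t.gene_ids) for t in trips} == {
            frozenset("ABC"), frozenset("BCD")
        }


class TestProperties:
    def test_orientation_partitions_pairs(self, default_dataset):
        pairs = find_candidate_pairs(default_dataset.genes)
        n3 = sum(p.orientation_class == THREE_PRIME for p in pairs)
        n5 = sum(p.orientation_class == FIVE_PRIME for p in pairs)
        assert n3 + n5 == len(pairs)

    def test_output_invariant_under_input_permutation(self):
        rng = np.random.default_rng(7)
        genes = random_genome(rng, 60)
        baseline = find_candidate_pairs(genes)
        shuffled = list(genes)
        rng.shuffle(shuffled)
        assert find_candidate_pairs(shuffled) == baseline

    def test_sweep_matches_brute_force_on_random_genomes(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            genes = random_genome(rng, int(rng.integers(2, 120)))
            assert find_candidate_pairs(genes) == brute_force_pairs(genes)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.integers(0, 2000),
                st.integers(1, 600),
                st.sampled_from("+-"),
                st.booleans(),
            ),
            min_size=0,
            max_size=25,
        )
    )
    def test_sweep_matches_brute_force_hypothesis(self, raw):
        genes = [
            make_gene(
                f"H{i:03d}", start, start + length, strand,
                biotype="protein_coding" if coding else OTHER_BIOTYPE,
            )
            for i, (start, length, strand, coding) in enumerate(raw)
        ]
        assert find_candidate_pairs(genes) == brute_force_pairs(genes)
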