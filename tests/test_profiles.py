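"""Profile construction against hand tallies, and the conservation index."""

import math
import random

import numpy as np
import pytest

from sapgo.errors import IntegrityError
from sapgo.io_formats import ProteinRecord, VariantRecord
from sapgo.profiles import (
    AlignmentRecord,
    build_profile,
    conservation_index,
    hits_from_aligned_fasta,
    profile_features,
    read_alignment_hits,
    saturation_scale,
    write_alignment_hits,
)
from sapgo.residues import AA_INDEX

QUERY = ProteinRecord("q", "ACDEFG")

# Hand-tallied oracle alignment: hit3 fails the E-value cut; hit2 carries a
# subject gap at query position 3 and an X at position 5; hit4 has a
# subject-insertion column projected away.
HIT1 = AlignmentRecord("h1", 1e-12, 1, 6, "ACDEFG", "ACDEFG")
HIT2 = AlignmentRecord("h2", 1e-15, 2, 5, "CDEF", "C-EX")
HIT3 = AlignmentRecord("h3", 1e-8, 1, 6, "ACDEFG", "ACDEFG")
HIT4 = AlignmentRecord("h4", 1e-10, 1, 3, "A-CD", "AGVD")

# (position, {residue: count}, depth) computed by hand, query row included.
HAND_TALLY = [
    (1, {"A": 3}, 3),
    (2, {"C": 3, "V": 1}, 4),
    (3, {"D": 3}, 3),
    (4, {"E": 3}, 3),
    (5, {"F": 2}, 2),
    (6, {"G": 2}, 2),
]


class TestBuildProfile:
    def test_query_only_profile(self):
        prof = build_profile(QUERY, [])
        assert prof.n_all == 1
        for i, aa in enumerate(QUERY.sequence, start=1):
            assert prof.frequency(i, aa) == 1.0
            assert prof.n_pos[i - 1] == 1

    def test_e_value_strictly_below_threshold(self):
        # E = 1e-8 is NOT lower than 1e-9, so the hit is excluded.
        prof = build_profile(QUERY, [HIT3])
        assert prof.n_all == 1

    def test_hand_tally_oracle(self):
        prof = build_profile(QUERY, [HIT1, HIT2, HIT3, HIT4])
        assert prof.n_all == 4
        for pos, counts, depth in HAND_TALLY:
            assert prof.n_pos[pos - 1] == depth
            for aa, count in counts.items():
                assert prof.frequency(pos, aa) == pytest.approx(count / depth)
            # nothing else observed at this column
            assert prof.frequencies[pos - 1].sum() == pytest.approx(1.0)

    def test_hit_order_permutation_invariance(self):
        hits = [HIT1, HIT2, HIT4]
        rng = random.Random(0)
        prof_ref = build_profile(QUERY, hits)
        for _ in range(5):
            shuffled = hits[:]
            rng.shuffle(shuffled)
            prof = build_profile(QUERY, shuffled)
            np.testing.assert_array_equal(prof.frequencies, prof_ref.frequencies)
            np.testing.assert_array_equal(prof.n_pos, prof_ref.n_pos)

    def test_adding_query_identical_hit_shifts_depth_not_argmax(self):
        hits = [HIT1, HIT2, HIT4]
        prof = build_profile(QUERY, hits)
        clone = AlignmentRecord("self", 1e-30, 1, 6, QUERY.sequence, QUERY.sequence)
        prof2 = build_profile(QUERY, hits + [clone])
        assert prof2.n_all == prof.n_all + 1
        np.testing.assert_array_equal(prof2.n_pos, prof.n_pos + 1)
        np.testing.assert_array_equal(
            prof2.frequencies.argmax(axis=1), prof.frequencies.argmax(axis=1)
        )

    def test_inconsistent_hit_is_integrity_error(self):
        bad = AlignmentRecord("bad", 1e-20, 1, 3, "AAA", "AAA")  # query is ACD
        with pytest.raises(IntegrityError, match="disagrees"):
            build_profile(QUERY, [bad])


class TestConservationIndex:
    def test_single_residue_column_is_one(self):
        prof = build_profile(QUERY, [HIT1])
        assert conservation_index(prof, 1) == pytest.approx(1.0)

    def test_uniform_column_is_zero(self):
        freqs = np.full((1, 20), 0.05)
        from sapgo.profiles import SequenceProfile

        prof = SequenceProfile(
            frequencies=freqs, n_pos=np.array([20]), n_all=20
        )
        assert conservation_index(prof, 1) == pytest.approx(0.0, abs=1e-12)

    def test_hand_entropy_three_quarters_column(self):
        # Column {C: 0.75, V: 0.25} at query position 2 of the oracle profile.
        prof = build_profile(QUERY, [HIT1, HIT2, HIT4])
        h = -(0.75 * math.log2(0.75) + 0.25 * math.log2(0.25))
        assert h == pytest.approx(0.8113, abs=1e-4)  # hand value, bits
        assert conservation_index(prof, 2) == pytest.approx(1 - h / math.log2(20))

    def test_relabeling_invariance(self):
        from sapgo.profiles import SequenceProfile

        base = np.zeros((2, 20))
        base[0, AA_INDEX["A"]] = 0.75
        base[0, AA_INDEX["V"]] = 0.25
        base[1, AA_INDEX["W"]] = 0.75  # same multiset, different residues
        base[1, AA_INDEX["G"]] = 0.25
        prof = SequenceProfile(frequencies=base, n_pos=np.array([4, 4]), n_all=4)
        assert conservation_index(prof, 1) == pytest.approx(conservation_index(prof, 2))

    def test_zero_depth_column_defined_as_zero(self):
        from sapgo.profiles import SequenceProfile

        prof = SequenceProfile(
            frequencies=np.zeros((1, 20)), n_pos=np.array([0]), n_all=1
        )
        assert conservation_index(prof, 1) == 0.0


class TestProfileFeatures:
    def test_query_only_case(self):
        prof = build_profile(QUERY, [])
        feats = profile_features(prof, VariantRecord("q", "A", 1, "V"))
        assert feats.f_wt == 1.0
        assert feats.f_mut == 0.0
        assert feats.ci == pytest.approx(1.0)

    def test_oracle_column_frequencies(self):
        prof = build_profile(QUERY, [HIT1, HIT2, HIT4])
        feats = profile_features(prof, VariantRecord("q", "C", 2, "V"))
        assert feats.f_wt == pytest.approx(0.75)
        assert feats.f_mut == pytest.approx(0.25)

    def test_saturation_scaling_midpoint(self):
        assert saturation_scale(100.0, 100.0) == pytest.approx(0.5)
        assert saturation_scale(0.0) == 0.0

    def test_feature_order_is_fixed(self):
        prof = build_profile(QUERY, [HIT1, HIT2, HIT4])
        feats = profile_features(prof, VariantRecord("q", "C", 2, "V"))
        assert feats.as_tuple() == (
            feats.f_mut,
            feats.f_wt,
            feats.n_pos_scaled,
            feats.n_all_scaled,
            feats.ci,
        )


class TestHitReaders:
    def test_tabular_roundtrip(self):
        hits = [HIT1, HIT2, HIT4]
        assert read_alignment_hits(write_alignment_hits(hits)) == hits

    def test_aligned_fasta_projection(self):
        text = ">q\nAC-DEF\n>s1\nACWDEG\n"
        query, hits = hits_from_aligned_fasta(text)
        assert query.sequence == "ACDEF"
        (hit,) = hits
        assert hit.q_aln == "ACDEF"
        assert hit.s_aln == "ACDEG"  # the W sits in a query-gap column
        prof = build_profile(query, hits)
        assert prof.n_all == 2
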