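"""Scoring matrix, alignment surface and DAS profile computation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dastm import (BACKGROUND_FREQUENCIES, DEFAULT_SHARPENING, KYTE_DOOLITTLE,
                   ConfigurationError, GeneratorParams, HydrophobicityScale,
                   PairScoreMatrix, ParameterError, SequenceRecord,
                   alignment_surface, build_pair_matrix, cross_weighted_profile,
                   cumulative_profile, das_profile, synth_library,
                   synth_tm_protein)
from dastm.core import AlignmentSurface

from conftest import (TOY_LETTERS, brute_cross_weighted, brute_das_profile,
                      brute_surface)


class TestPairScoreMatrix:
    def test_symmetric_nonnegative_background_mean_one(self, matrix):
        assert np.allclose(matrix.table, matrix.table.T)
        assert (matrix.table >= 0).all()
        assert matrix.background_mean() == pytest.approx(1.0, abs=1e-9)

    def test_two_letter_toy_normalization(self):
        # n = (0, 1), uniform background: the only nonzero cell must carry
        # the whole mean, so c * 1/4 = 1 and M(hydrophobic, hydrophobic) = 4.
        m = build_pair_matrix(
            HydrophobicityScale("toy2", {"L": 1.0, "S": 0.0}),
            {"L": 0.5, "S": 0.5})
        assert m.score("L", "L") == pytest.approx(4.0, abs=1e-12)
        assert m.score("L", "S") == 0.0
        assert m.background_mean() == pytest.approx(1.0, abs=1e-12)

    def test_entry_matches_direct_formula(self, matrix):
        lo, hi = min(KYTE_DOOLITTLE.values()), max(KYTE_DOOLITTLE.values())
        n = {a: ((v - lo) / (hi - lo)) ** DEFAULT_SHARPENING
             for a, v in KYTE_DOOLITTLE.items()}
        nbar = sum(BACKGROUND_FREQUENCIES[a] * n[a] for a in n)
        c = 1.0 / nbar ** 2
        assert matrix.score("I", "L") == pytest.approx(
            c * n["I"] * n["L"], abs=1e-12)

    def test_ambiguity_letters_score_at_background_mean(self, matrix):
        lo, hi = min(KYTE_DOOLITTLE.values()), max(KYTE_DOOLITTLE.values())
        n = {a: ((v - lo) / (hi - lo)) ** DEFAULT_SHARPENING
             for a, v in KYTE_DOOLITTLE.items()}
        nbar = sum(BACKGROUND_FREQUENCIES[a] * n[a] for a in n)
        assert matrix.score("X", "L") == pytest.approx(
            matrix.score("L", "L") / n["L"] * nbar, rel=1e-9)
        assert matrix.score("X", "X") == pytest.approx(1.0, abs=1e-9)

    def test_missing_residue_rejected(self):
        partial = {a: v for a, v in KYTE_DOOLITTLE.items() if a != "W"}
        with pytest.raises(ConfigurationError, match="missing"):
            build_pair_matrix(HydrophobicityScale("partial", partial))

    def test_degenerate_scale_rejected(self):
        flat = {a: 1.0 for a in KYTE_DOOLITTLE}
        with pytest.raises(ConfigurationError, match="degenerate"):
            build_pair_matrix(HydrophobicityScale("flat", flat))

    def test_text_round_trip(self, matrix):
        again = PairScoreMatrix.from_text(matrix.to_text())
        for a in "ILSKX":
            for b in "ILSKX":
                assert again.score(a, b) == pytest.approx(
                    matrix.score(a, b), rel=1e-12)


class TestAlignmentSurface:
    def test_homopolymer_window_one_is_constant(self, matrix):
        q = SequenceRecord("q", "AAAA")
        surf = alignment_surface(q, q, matrix, window=1)
        assert np.allclose(surf.scores, matrix.score("A", "A"))

    def test_matches_brute_force_triple_loop(self, matrix, rng):
        letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(5):
            q = "".join(rng.choice(letters, 5))
            r = "".join(rng.choice(letters, 5))
            surf = alignment_surface(SequenceRecord("q", q),
                                     SequenceRecord("r", r), matrix, window=3)
            assert np.allclose(surf.scores, brute_surface(q, r, matrix, 3),
                               atol=1e-12)

    def test_swap_transposes(self, matrix, rng):
        letters = np.array(list("ILVSKDE"))
        q = SequenceRecord("q", "".join(rng.choice(letters, 7)))
        r = SequenceRecord("r", "".join(rng.choice(letters, 11)))
        s_qr = alignment_surface(q, r, matrix, 5).scores
        s_rq = alignment_surface(r, q, matrix, 5).scores
        assert np.allclose(s_qr, s_rq.T, atol=1e-12)

    @pytest.mark.parametrize("window", [0, 2, -3])
    def test_even_or_nonpositive_window_rejected(self, matrix, window):
        q = SequenceRecord("q", "MKTL")
        with pytest.raises(ParameterError):
            alignment_surface(q, q, matrix, window)


class TestProfiles:
    def test_constant_surface_gives_constant_profile(self):
        surf = AlignmentSurface(np.full((4, 6), 2.5), 3)
        assert np.allclose(cumulative_profile(surf).values, 2.5)
        assert np.allclose(cumulative_profile(surf, "reference").values, 2.5)

    def test_cumulative_matches_brute_means(self, rng):
        s = rng.random((4, 6))
        surf = AlignmentSurface(s, 3)
        assert np.allclose(cumulative_profile(surf).values,
                           [sum(row) / 6 for row in s], atol=1e-12)
        assert np.allclose(cumulative_profile(surf, "reference").values,
                           [sum(s[:, j]) / 4 for j in range(6)], atol=1e-12)

    def test_profile_lengths_follow_axis(self, rng):
        surf = AlignmentSurface(rng.random((4, 6)), 3)
        assert len(cumulative_profile(surf, "query")) == 4
        assert len(cumulative_profile(surf, "reference")) == 6

    def test_cross_weighted_single_column_concentrates(self):
        s = np.zeros((5, 4))
        s[:, 2] = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert np.allclose(cross_weighted_profile(
            AlignmentSurface(s, 1)).values, s[:, 2])

    def test_all_zero_surface_gives_zero_profile(self):
        prof = cross_weighted_profile(AlignmentSurface(np.zeros((3, 4)), 1))
        assert np.all(prof.values == 0.0)

    def test_cross_weighted_matches_brute_oracle(self, rng):
        s = rng.random((6, 8))
        got = cross_weighted_profile(AlignmentSurface(s, 3)).values
        assert np.allclose(got, brute_cross_weighted(s.tolist()), atol=1e-12)


class TestDasProfile:
    def test_single_member_equals_cross_weighted(self, matrix):
        q = SequenceRecord("q", "MKTLLILVAAGG")
        ref = SequenceRecord("r", "LLLLVVVIIFFA")
        expected = cross_weighted_profile(
            alignment_surface(q, ref, matrix, 5)).values
        got = das_profile(q, [ref], matrix, 5).values
        assert np.allclose(got, expected, atol=1e-15)

    def test_identical_copies_equal_single_member(self, matrix):
        q = SequenceRecord("q", "MKTLLILVAAGG")
        seq = "LLLLVVVIIFFA"
        copies = [SequenceRecord(f"r{i}", seq) for i in range(5)]
        single = das_profile(q, copies[:1], matrix, 5).values
        assert np.allclose(das_profile(q, copies, matrix, 5).values,
                           single, atol=1e-12)

    def test_self_comparison_excluded_by_id(self, matrix, small_library):
        member = small_library.members[0]
        with_self = das_profile(member, small_library.members, matrix, 15)
        without = das_profile(member, small_library.members[1:], matrix, 15)
        assert np.allclose(with_self.values, without.values, atol=1e-15)

    def test_empty_after_self_exclusion_rejected(self, matrix):
        q = SequenceRecord("q", "MKTL")
        with pytest.raises(ConfigurationError, match="empty"):
            das_profile(q, [SequenceRecord("q", "LLLL")], matrix, 3)

    def test_compositional_oracle_mean_of_member_profiles(self, matrix,
                                                          small_library):
        q, _ = synth_tm_protein(GeneratorParams(seed=11), 2, record_id="q")
        per_member = [
            cross_weighted_profile(
                alignment_surface(q, m, matrix, 15)).values
            for m in sorted(small_library.members, key=lambda m: m.id)
        ]
        got = das_profile(q, small_library.members, matrix, 15).values
        assert np.allclose(got, np.mean(per_member, axis=0), atol=1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.text(alphabet=TOY_LETTERS, min_size=1, max_size=8))
    def test_matches_brute_force_on_toy_sequences(self, toy_matrix, seq):
        members = [SequenceRecord("m1", "LLLLSASS"),
                   SequenceRecord("m2", "SALLLLAS")]
        got = das_profile(SequenceRecord("q", seq), members,
                          toy_matrix, 3).values
        oracle = brute_das_profile("q", seq, members, toy_matrix, 3)
        assert np.allclose(got, oracle, atol=1e-10)


class TestPipelineProperties:
    def test_homopolymer_monotone_in_hydrophobicity(self, matrix,
                                                    small_library):
        lo, hi = min(KYTE_DOOLITTLE.values()), max(KYTE_DOOLITTLE.values())
        order = sorted(KYTE_DOOLITTLE, key=KYTE_DOOLITTLE.get)
        prev = None
        for letter in order:
            q = SequenceRecord("q", letter * 30)
            d = das_profile(q, small_library.members, matrix, 15).values
            if prev is not None:
                assert np.all(d >= prev - 1e-12)
            prev = d

    def test_poly_leu_exceeds_poly_ser(self, matrix, small_library):
        d_leu = das_profile(SequenceRecord("q", "L" * 30),
                            small_library.members, matrix, 15).values
        d_ser = das_profile(SequenceRecord("q", "S" * 30),
                            small_library.members, matrix, 15).values
        assert np.all(d_leu[5:25] > d_ser[5:25])

    def test_matrix_scaling_scales_profile_linearly(self, matrix,
                                                    small_library):
        q = SequenceRecord("q", "MKTLLILVAAGGDDKKLLVV")
        base = das_profile(q, small_library.members, matrix, 7).values
        scaled = das_profile(q, small_library.members,
                             matrix.scaled(3.0), 7).values
        assert np.allclose(scaled, 3.0 * base, rtol=1e-12)
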