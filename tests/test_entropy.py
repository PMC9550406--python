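"""Entropy/information-content profiles and the PSSM-style IE features."""

import numpy as np
import pytest

from entrosite import (
    PositionProfile,
    Segment,
    build_profile,
    difference_profile,
    encode_ie,
    entropy,
    information_content,
)
from entrosite.entropy import profile_to_frame
from entrosite.simulate import default_motif, generate

from .conftest import make_set


def profile_from_rows(rows):
    """PositionProfile straight from probability rows (counts irrelevant)."""
    probs = np.asarray(rows, dtype=float)
    return PositionProfile(
        probs=probs, counts=np.zeros_like(probs), pseudocount=0.0, n_sequences=0
    )


class TestBuildProfile:
    def test_pure_column_without_pseudocount(self):
        segset = make_set(["A"] * 10, [1] * 5 + [0] * 5)
        profile = build_profile(segset, pseudocount=0)
        assert profile.probs[0].tolist() == [1.0, 0.0, 0.0, 0.0]

    def test_add_one_smoothing_arithmetic(self):
        segset = make_set(["A"] * 10, [1] * 5 + [0] * 5)
        profile = build_profile(segset, pseudocount=1)
        assert profile.probs[0, 0] == pytest.approx(11 / 14)
        assert profile.probs[0, 1] == pytest.approx(1 / 14)

    def test_uniform_sampling_concentrates_near_quarter(self, rng):
        lut = np.array(list("ACGT"))
        seqs = ["".join(row) for row in lut[rng.integers(0, 4, size=(1000, 20))]]
        profile = build_profile(make_set(seqs, [1] * 500 + [0] * 500), pseudocount=0)
        assert np.all(np.abs(profile.probs - 0.25) < 0.05)

    def test_n_bases_excluded_from_counts(self):
        profile = build_profile(make_set(["AN", "AN", "AA", "AC"], [1, 1, 0, 0]), 0)
        assert profile.counts[1].sum() == 2  # two N's dropped at position 1

    def test_empty_set_errors(self):
        with pytest.raises(ValueError, match="empty"):
            build_profile([], pseudocount=1)

    def test_all_n_column_without_pseudocount_errors(self):
        with pytest.raises(ValueError, match="zero effective count"):
            build_profile(make_set(["AN", "CN"], [1, 0]), pseudocount=0)

    def test_rows_sum_to_one(self, rng):
        segset = generate(default_motif(), 30, 30, seed=1)
        profile = build_profile(segset, pseudocount=0.5)
        assert np.allclose(profile.probs.sum(axis=1), 1.0, atol=1e-12)


class TestEntropy:
    @pytest.mark.parametrize(
        "row,expected",
        [
            ((0.25, 0.25, 0.25, 0.25), 2.0),
            ((1.0, 0.0, 0.0, 0.0), 0.0),
            ((0.5, 0.5, 0.0, 0.0), 1.0),
        ],
    )
    def test_closed_forms(self, row, expected):
        assert entropy(profile_from_rows([row]))[0] == pytest.approx(expected)

    def test_bounded_between_0_and_2_bits(self, rng):
        raw = rng.random((50, 4))
        profile = profile_from_rows(raw / raw.sum(axis=1, keepdims=True))
        h = entropy(profile)
        assert np.all(h >= 0.0) and np.all(h <= 2.0)

    def test_pseudocount_pulls_entropy_toward_uniform(self):
        segset = make_set(["AAAA", "AAAC", "AACC"], [1, 1, 0])
        h = [entropy(build_profile(segset, pc)) for pc in (0.0, 0.5, 1.0, 5.0)]
        for weaker, stronger in zip(h, h[1:]):
            assert np.all(stronger >= weaker - 1e-12)


class TestInformationContent:
    def test_degenerate_row_gives_2_bits_on_its_base(self):
        ie = information_content(profile_from_rows([(0.0, 1.0, 0.0, 0.0)]))
        assert ie.ic[0].tolist() == [0.0, 2.0, 0.0, 0.0]

    def test_uniform_row_gives_zero(self):
        ie = information_content(profile_from_rows([(0.25,) * 4]))
        assert np.allclose(ie.ic, 0.0)

    def test_half_half_row(self):
        ie = information_content(profile_from_rows([(0.5, 0.5, 0.0, 0.0)]))
        assert ie.ic[0].tolist() == [0.5, 0.5, 0.0, 0.0]

    def test_ic_row_sums_equal_2_minus_entropy(self, rng):
        raw = rng.random((40, 4)) + 1e-3
        profile = profile_from_rows(raw / raw.sum(axis=1, keepdims=True))
        ie = information_content(profile)
        assert np.allclose(ie.ic.sum(axis=1), 2.0 - ie.entropy, atol=1e-12)


class TestDifferenceProfile:
    def test_identical_profiles_give_zero_track(self):
        p = profile_from_rows([(0.4, 0.3, 0.2, 0.1)] * 5)
        assert np.allclose(difference_profile(p, p).delta_entropy, 0.0)

    def test_conserved_positive_vs_uniform_negative(self):
        pos = profile_from_rows([(1.0, 0.0, 0.0, 0.0)])
        neg = profile_from_rows([(0.25,) * 4])
        assert difference_profile(pos, neg).delta_entropy[0] == pytest.approx(2.0)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="lengths differ"):
            difference_profile(
                profile_from_rows([(0.25,) * 4]), profile_from_rows([(0.25,) * 4] * 2)
            )

    def test_motif_window_dominates_track_on_synthetic_data(self):
        segset = generate(default_motif(dominant=0.85), 600, 600, seed=7)
        track = difference_profile(
            build_profile(segset.positives()), build_profile(segset.negatives())
        ).delta_entropy
        window = np.arange(47, 54)
        assert track[window].mean() > np.delete(track, window).mean() + 0.1


class TestEncodeIE:
    def test_fully_conserved_positive_profile_scores_2_everywhere(self):
        rows = [(1.0, 0.0, 0.0, 0.0)] * 4
        pos = information_content(profile_from_rows(rows))
        neg = information_content(profile_from_rows([(0.25,) * 4] * 4))
        vec = encode_ie(Segment("s", "AAAA", 1), pos, neg)
        assert vec[:4].tolist() == [2.0] * 4
        assert vec[4:].tolist() == [0.0] * 4

    def test_hand_computed_three_position_toy(self):
        rows = [(1.0, 0.0, 0.0, 0.0), (0.5, 0.5, 0.0, 0.0), (0.25,) * 4]
        pos = information_content(profile_from_rows(rows))
        neg = information_content(profile_from_rows([(0.25,) * 4] * 3))
        vec = encode_ie(Segment("s", "AAT", 1), pos, neg)
        # per-row ic of the observed base: 1*(2-0)=2, 0.5*(2-1)=0.5, 0.25*0=0
        assert vec[:3] == pytest.approx([2.0, 0.5, 0.0])

    def test_n_positions_contribute_zero(self):
        rows = [(1.0, 0.0, 0.0, 0.0)] * 2
        pos = neg = information_content(profile_from_rows(rows))
        vec = encode_ie(Segment("s", "AN", 1), pos, neg)
        assert vec.tolist() == [2.0, 0.0, 2.0, 0.0]

    def test_length_mismatch_errors(self):
        ie = information_content(profile_from_rows([(0.25,) * 4] * 3))
        with pytest.raises(ValueError, match="does not match"):
            encode_ie(Segment("s", "ACGT", 1), ie, ie)

    def test_profiles_are_immutable_after_build(self):
        segset = make_set(["ACGT", "ACGA"], [1, 0])
        profile = build_profile(segset, 1)
        ie = information_content(profile)
        before = profile.probs.copy()
        encode_ie(Segment("x", "TTTT", 0), ie, ie)
        assert np.array_equal(profile.probs, before)
        with pytest.raises(ValueError):
            profile.probs[0, 0] = 0.9


def test_profile_frame_has_positions_probabilities_and_entropy():
    frame = profile_to_frame(profile_from_rows([(0.25,) * 4, (1, 0, 0, 0)]))
    assert list(frame.columns) == ["position", "p_A", "p_C", "p_G", "p_T", "H"]
    assert frame["position"].tolist() == [1, 2]  # reported 1-based
    assert frame["H"].tolist() == pytest.approx([2.0, 0.0])
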