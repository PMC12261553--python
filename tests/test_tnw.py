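"""Temporal alignment: closed forms, oracle equivalence, NW reduction."""

import math
import random

import numpy as np

import pytest
from hypothesis import given
from hypothesis import strategies as st

from palliseq import (
    TNWParams,
    brute_force_score,
    normalized_similarity,
    pairwise_similarity_matrix,
    tnw_align,
)
from palliseq.datasets import PALLIATIVE_SERVICES
from conftest import make_seq

DEFAULTS = TNWParams()


def random_sequence(rng, pid, max_len=4):
    k = rng.randint(1, max_len)
    events = tuple(rng.sample(PALLIATIVE_SERVICES, k))
    gaps = (0,) + tuple(rng.randint(0, 200) for _ in range(k - 1))
    return make_seq(pid, events, gaps)


@st.composite
def sequences(draw, max_len=4):
    k = draw(st.integers(1, max_len))
    events = tuple(
        draw(
            st.lists(
                st.sampled_from(PALLIATIVE_SERVICES),
                min_size=k, max_size=k, unique=True,
            )
        )
    )
    gaps = (0,) + tuple(
        draw(st.lists(st.integers(0, 365), min_size=k - 1, max_size=k - 1))
    )
    return make_seq("h", events, gaps)


class TestClosedForms:
    def test_identical_singletons_score_match_plus_full_bonus(self):
        a = make_seq("a", ("PPC",))
        assert tnw_align(a, a, DEFAULTS).score == pytest.approx(1.25)

    def test_empty_vs_two_elements_pays_two_gaps(self):
        b = make_seq("b", ("PPC", "SPHC"), (0, 95))
        result = tnw_align(None, b, DEFAULTS)
        assert result.score == pytest.approx(-1.4)
        assert result.aligned_pairs == ((None, 0), (None, 1))

    def test_empty_vs_empty_scores_zero(self):
        result = tnw_align(None, None, DEFAULTS)
        assert result.score == 0.0
        assert result.aligned_pairs == ()

    def test_shared_prefix_distinct_second_symbol(self):
        a = make_seq("a", ("PPC", "SPHC"), (0, 95))
        b = make_seq("b", ("PPC", "IPC"), (0, 50))
        assert tnw_align(a, b, DEFAULTS).score == pytest.approx(0.15)

    def test_same_symbols_different_timing(self):
        a = make_seq("a", ("PPC", "SPHC"), (0, 95))
        b = make_seq("b", ("PPC", "SPHC"), (0, 35))
        expected = 1.25 + 1.0 + 0.25 * math.exp(-60 / 30)
        assert tnw_align(a, b, DEFAULTS).score == pytest.approx(expected)

    def test_traceback_reconstructs_score(self):
        a = make_seq("a", ("PPC", "SPHC", "HOSPICE"), (0, 40, 10))
        b = make_seq("b", ("SPHC", "IPC"), (0, 7))
        result = tnw_align(a, b, DEFAULTS)
        total = 0.0
        for i, j in result.aligned_pairs:
            if i is None or j is None:
                total -= DEFAULTS.gap
            else:
                total += DEFAULTS.pair_score(
                    a.events[i], a.gaps[i], b.events[j], b.gaps[j]
                )
        assert total == pytest.approx(result.score)


class TestOracle:
    def test_dynamic_program_equals_exhaustive_enumeration(self):
        rng = random.Random(1234)
        for trial in range(250):
            a = random_sequence(rng, "a")
            b = random_sequence(rng, "b")
            assert tnw_align(a, b, DEFAULTS).score == pytest.approx(
                brute_force_score(a, b, DEFAULTS)
            ), (a, b)

    def test_reduces_to_classic_needleman_wunsch_without_temporal_term(self):
        from Bio.Align import PairwiseAligner

        params = TNWParams(temporal_weight=0.0)
        aligner = PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = params.match
        aligner.mismatch_score = params.mismatch
        aligner.gap_score = -params.gap
        letters = {"PPC": "P", "SPHC": "S", "IPC": "I", "HOSPICE": "H"}
        rng = random.Random(99)
        for trial in range(100):
            a = random_sequence(rng, "a")
            b = random_sequence(rng, "b")
            expected = aligner.score(
                "".join(letters[e] for e in a.events),
                "".join(letters[e] for e in b.events),
            )
            assert tnw_align(a, b, params).score == pytest.approx(expected)


class TestProperties:
    @given(sequences(), sequences())
    def test_score_is_symmetric(self, a, b):
        assert tnw_align(a, b, DEFAULTS).score == pytest.approx(
            tnw_align(b, a, DEFAULTS).score
        )

    @given(sequences(), sequences(), st.floats(0.1, 3.0))
    def test_larger_gap_penalty_never_raises_score(self, a, b, bump):
        low = tnw_align(a, b, DEFAULTS).score
        stiff = TNWParams(gap=DEFAULTS.gap + bump)
        assert tnw_align(a, b, stiff).score <= low + 1e-9

    def test_identical_gap_vectors_earn_full_bonus_per_match(self):
        a = make_seq("a", ("PPC", "SPHC", "IPC"), (0, 30, 12))
        b = make_seq("b", ("PPC", "SPHC", "IPC"), (0, 30, 12))
        score = tnw_align(a, b, DEFAULTS).score
        assert score == pytest.approx(3 * (DEFAULTS.match + DEFAULTS.temporal_weight))

    def test_bonus_vanishes_for_distant_timing(self):
        near = tnw_align(
            make_seq("a", ("PPC", "SPHC"), (0, 10)),
            make_seq("b", ("PPC", "SPHC"), (0, 10)),
            DEFAULTS,
        ).score
        far = tnw_align(
            make_seq("a", ("PPC", "SPHC"), (0, 0)),
            make_seq("b", ("PPC", "SPHC"), (0, 365)),
            DEFAULTS,
        ).score
        assert near == pytest.approx(2.5)
        assert far == pytest.approx(2.25 + 0.25 * math.exp(-365 / 30), abs=1e-6)


class TestNormalizedSimilarity:
    @given(sequences())
    def test_self_similarity_is_one(self, a):
        assert normalized_similarity(a, a, DEFAULTS) == pytest.approx(1.0)

    @given(sequences(), sequences())
    def test_similarity_symmetric_and_bounded(self, a, b):
        sab = normalized_similarity(a, b, DEFAULTS)
        assert sab == pytest.approx(normalized_similarity(b, a, DEFAULTS))
        assert 0 < sab <= 1 + 1e-12

    def test_shared_prefix_pair_value(self):
        # raw score 0.15, both self-scores 2.5 at defaults
        a = make_seq("a", ("PPC", "SPHC"), (0, 95))
        b = make_seq("b", ("PPC", "IPC"), (0, 50))
        assert normalized_similarity(a, b, DEFAULTS) == pytest.approx(
            math.exp(0.15 - 2.5)
        )

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            normalized_similarity(make_seq("a", ("PPC",)), None, DEFAULTS)


class TestSimilarityMatrix:
    def test_identical_pair_gives_all_ones(self):
        a = make_seq("a", ("PPC",))
        b = make_seq("b", ("PPC",))
        S = pairwise_similarity_matrix([a, b], DEFAULTS)
        assert np.allclose(S.values, 1.0)

    def test_matrix_matches_single_pair_calls(self):
        seqs = [
            make_seq("a", ("PPC", "SPHC"), (0, 95)),
            make_seq("b", ("PPC", "IPC"), (0, 50)),
            make_seq("c", ("HOSPICE",)),
        ]
        S = pairwise_similarity_matrix(seqs, DEFAULTS)
        for i, x in enumerate(seqs):
            for j, y in enumerate(seqs):
                if i != j:
                    assert S.iloc[i, j] == pytest.approx(
                        normalized_similarity(x, y, DEFAULTS)
                    )
        assert (S.values == S.values.T).all()

    def test_fewer_than_two_sequences_rejected(self):
        with pytest.raises(ValueError):
            pairwise_similarity_matrix([make_seq("a", ("PPC",))], DEFAULTS)
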