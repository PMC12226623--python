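"""Zero-shot sentiment scoring and session aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from psilopred.lexicon import DEFAULT_LABELS, CircumplexLabel
from psilopred.sentiment import (
    InvalidSessionError,
    LexiconBackend,
    SentimentError,
    SentimentScore,
    classify_zero_shot,
    score_utterance,
    session_sentiment,
)
from psilopred.transcripts import PARTICIPANT, THERAPIST, Utterance

LABEL_NAMES = [l.label_text for l in DEFAULT_LABELS]


class FixedBackend:
    def __init__(self, weights):
        self._weights = list(weights)

    def weights(self, text, candidate_labels):
        return self._weights[: len(candidate_labels)]


def utt(role, idx=0, text="x"):
    return Utterance(role, text, 0, idx)


class TestClassifyZeroShot:
    def test_equal_weights_normalize(self, mock_backend):
        p = classify_zero_shot("hello", ["a", "b", "c", "d"], mock_backend([1, 1, 1, 1]))
        assert np.allclose(p, 0.25)

    def test_proportional_normalization(self, mock_backend):
        p = classify_zero_shot("hello", ["a", "b", "c"], mock_backend([2, 1, 1]))
        assert np.allclose(p, [0.5, 0.25, 0.25])
        assert abs(p.sum() - 1.0) < 1e-9

    def test_empty_premise_and_labels(self, mock_backend):
        with pytest.raises(SentimentError, match="empty premise"):
            classify_zero_shot("  ", ["a"], mock_backend([1]))
        with pytest.raises(SentimentError, match="label"):
            classify_zero_shot("hello", [], mock_backend([]))

    def test_lexicon_backend_favors_matching_label(self):
        backend = LexiconBackend()
        p = classify_zero_shot("I feel wonderful", ["happy", "sad"], backend)
        assert p[0] > p[1]

    def test_lexicon_counts_repeats(self):
        backend = LexiconBackend()
        w1 = backend.weights("happy", ["happy"])
        w2 = backend.weights("happy happy happy", ["happy"])
        assert w2[0] == w1[0] + 2


class TestScoreUtterance:
    def test_point_mass_recovers_anchor(self, mock_backend):
        weights = [0.0] * 8
        weights[LABEL_NAMES.index("happy")] = 1.0
        s = score_utterance("some text", DEFAULT_LABELS, mock_backend(weights))
        assert s.valence == pytest.approx(1.0)
        assert s.arousal == pytest.approx(0.0)

    def test_uniform_over_symmetric_labels_is_origin(self, mock_backend):
        s = score_utterance("text", DEFAULT_LABELS, mock_backend([1] * 8))
        assert s.valence == pytest.approx(0.0, abs=1e-12)
        assert s.arousal == pytest.approx(0.0, abs=1e-12)

    def test_convex_combination(self, mock_backend):
        labels = (
            CircumplexLabel("pos", 1.0, 0.0),
            CircumplexLabel("act", 0.0, 1.0),
            CircumplexLabel("neg", -1.0, 0.0),
            CircumplexLabel("deact", 0.0, -1.0),
        )
        s = score_utterance("text", labels, mock_backend([1, 1, 0, 0]))
        assert (s.valence, s.arousal) == (pytest.approx(0.5), pytest.approx(0.5))

    def test_degenerate_label_set_rejected(self, mock_backend):
        labels = (CircumplexLabel("a", 0.5, 0.5), CircumplexLabel("b", 0.5, 0.5))
        with pytest.raises(SentimentError, match="degenerate|span"):
            score_utterance("text", labels, mock_backend([1, 1]))

    def test_label_set_must_span_both_axes(self, mock_backend):
        labels = (CircumplexLabel("a", 0.9, 0.1), CircumplexLabel("b", 0.5, -0.1))
        with pytest.raises(SentimentError, match="valence"):
            score_utterance("text", labels, mock_backend([1, 1]))

    @given(st.lists(st.floats(0.01, 10.0), min_size=8, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_score_in_convex_hull_of_anchors(self, weights):
        s = score_utterance("text", DEFAULT_LABELS, FixedBackend(weights))
        # hull of the 8 unit-circle anchors is inside the unit disc
        assert np.hypot(s.valence, s.arousal) <= 1.0 + 1e-9

    @given(st.lists(st.floats(0.01, 10.0), min_size=8, max_size=8), st.permutations(range(8)))
    @settings(max_examples=30, deadline=None)
    def test_label_order_irrelevant(self, weights, perm):
        s1 = score_utterance("text", DEFAULT_LABELS, FixedBackend(weights))
        labels_p = tuple(DEFAULT_LABELS[i] for i in perm)
        weights_p = [weights[i] for i in perm]
        s2 = score_utterance("text", labels_p, FixedBackend(weights_p))
        assert s1.valence == pytest.approx(s2.valence, abs=1e-12)
        assert s1.arousal == pytest.approx(s2.arousal, abs=1e-12)

    def test_lexicon_monotonic_in_positive_terms(self):
        backend = LexiconBackend()
        base = "The session was hard and I cried"
        v0 = score_utterance(base, DEFAULT_LABELS, backend).valence
        v1 = score_utterance(base + " but now I am happy", DEFAULT_LABELS, backend).valence
        assert v1 >= v0


class TestSessionSentiment:
    def test_constant_scores(self):
        scored = [(utt(PARTICIPANT, i), SentimentScore(0.5, 0.2, i)) for i in range(5)]
        scored += [(utt(THERAPIST, i + 5), SentimentScore(0.1, 0.0, i + 5)) for i in range(5)]
        s = session_sentiment(scored, min_utterances=5)
        assert s.participant_valence == pytest.approx(0.5)
        assert s.participant_arousal == pytest.approx(0.2)
        assert s.n_utterances_participant == 5

    def test_symmetric_scores_average_to_zero(self):
        pts = [(1, 0), (0, 1), (-1, 0), (0, -1)]
        scored = [(utt(PARTICIPANT, i), SentimentScore(v, a, i)) for i, (v, a) in enumerate(pts)]
        scored += [(utt(THERAPIST, 4 + i), SentimentScore(0, 0, 4 + i)) for i in range(4)]
        s = session_sentiment(scored, min_utterances=4)
        assert s.participant_valence == pytest.approx(0.0)
        assert s.participant_arousal == pytest.approx(0.0)

    def test_matches_brute_force_mean(self, rng):
        vals = rng.uniform(-1, 1, size=(10, 2))
        tvals = rng.uniform(-1, 1, size=(10, 2))
        scored = [(utt(PARTICIPANT, i), SentimentScore(v, a, i)) for i, (v, a) in enumerate(vals)]
        scored += [
            (utt(THERAPIST, 10 + i), SentimentScore(v, a, 10 + i))
            for i, (v, a) in enumerate(tvals)
        ]
        s = session_sentiment(scored)
        assert s.participant_valence == pytest.approx(sum(v for v, _ in vals) / 10)
        assert s.therapist_arousal == pytest.approx(sum(a for _, a in tvals) / 10)

    def test_order_invariance(self, rng):
        vals = rng.uniform(-1, 1, size=(12, 2))
        scored = [(utt(PARTICIPANT, i), SentimentScore(v, a, i)) for i, (v, a) in enumerate(vals)]
        scored += [(utt(THERAPIST, 12 + i), SentimentScore(0.1, 0.1, 12 + i)) for i in range(6)]
        s1 = session_sentiment(scored)
        s2 = session_sentiment(list(reversed(scored)))
        assert s1 == s2

    def test_too_few_utterances_flags_session(self):
        scored = [(utt(PARTICIPANT, i), SentimentScore(0, 0, i)) for i in range(3)]
        scored += [(utt(THERAPIST, 3 + i), SentimentScore(0, 0, 3 + i)) for i in range(9)]
        with pytest.raises(InvalidSessionError, match="participant"):
            session_sentiment(scored, min_utterances=5)
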