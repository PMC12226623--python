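"""Two-dimensional utterance sentiment from a pluggable zero-shot classifier.

An utterance is scored by (1) obtaining a probability distribution over a
set of circumplex emotion labels from a zero-shot classification backend and
(2) taking the probability-weighted centroid of the labels' (valence,
arousal) anchors.  Session sentiment is the unweighted mean of utterance
scores per speaker role.

Backends implement a single method::

    weights(text, candidate_labels) -> sequence of non-negative weights

The reference backend wraps an NLI zero-shot classifier (optional,
``transformers`` required); the deterministic :class:`LexiconBackend` counts
matched lexicon terms per label with Laplace smoothing and is what the test
suite and synthetic generator use.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Protocol, Sequence

import numpy as np

from .lexicon import LEXICON, CircumplexLabel, DEFAULT_LABELS
from .transcripts import PARTICIPANT, THERAPIST, SessionTranscript, Utterance

DEFAULT_HYPOTHESIS_TEMPLATE = "This statement expresses {label}."


class SentimentError(ValueError):
    """Invalid input to the sentiment layer."""


class InvalidSessionError(SentimentError):
    """Session does not meet the minimum-utterance requirement for modelling."""


class ZeroShotBackend(Protocol):
    def weights(self, text: str, candidate_labels: Sequence[str]) -> Sequence[float]:
        ...


@dataclass(frozen=True)
class SentimentScore:
    valence: float
    arousal: float
    utterance_index: int


@dataclass(frozen=True)
class SessionSentiment:
    """Per-speaker session means of utterance valence and arousal."""

    participant_valence: float
    participant_arousal: float
    therapist_valence: float
    therapist_arousal: float
    n_utterances_participant: int
    n_utterances_therapist: int


class LexiconBackend:
    """Deterministic backend: weight = matched lexicon terms + Laplace 1.

    Term matching is case-insensitive on word boundaries and counts
    occurrences, so repeated terms add weight.
    """

    def __init__(self, lexicon: Mapping[str, Iterable[str]] = LEXICON) -> None:
        self._patterns = {
            label: re.compile(
                r"\b(?:" + "|".join(re.escape(t) for t in terms) + r")\b",
                re.IGNORECASE,
            )
            for label, terms in lexicon.items()
        }

    def weights(self, text: str, candidate_labels: Sequence[str]) -> list[float]:
        out = []
        for label in candidate_labels:
            pattern = self._patterns.get(label)
            n = len(pattern.findall(text)) if pattern is not None else 0
            out.append(float(n + 1))
        return out


class NLIZeroShotBackend:
    """Zero-shot NLI backend (BART-MNLI style); requires ``transformers``.

    Weights are entailment probabilities for the hypothesis built from each
    candidate label.  Optional plug-in: nothing in the package requires it.
    """

    def __init__(
        self,
        model_name: str = "facebook/bart-large-mnli",
        hypothesis_template: str = DEFAULT_HYPOTHESIS_TEMPLATE,
    ) -> None:
        try:
            from transformers import pipeline  # type: ignore
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "NLIZeroShotBackend requires the optional 'transformers' "
                "dependency (pip install psilopred[nli])"
            ) from exc
        self._pipe = pipeline("zero-shot-classification", model=model_name)
        self._template = hypothesis_template

    def weights(self, text: str, candidate_labels: Sequence[str]) -> list[float]:  # pragma: no cover
        res = self._pipe(
            text,
            candidate_labels=list(candidate_labels),
            hypothesis_template=self._template,
            multi_label=True,
        )
        by_label = dict(zip(res["labels"], res["scores"]))
        return [float(by_label[l]) for l in candidate_labels]


def classify_zero_shot(
    text: str,
    candidate_labels: Sequence[str],
    backend: ZeroShotBackend,
) -> np.ndarray:
    """Probability distribution over ``candidate_labels`` for ``text``.

    The backend's non-negative weights are normalized to sum to one; order
    matches ``candidate_labels``.
    """
    if not text or not text.strip():
        raise SentimentError("empty premise")
    if not candidate_labels:
        raise SentimentError("empty candidate label set")
    w = np.asarray(backend.weights(text, candidate_labels), dtype=float)
    if w.shape != (len(candidate_labels),):
        raise SentimentError("backend returned wrong number of weights")
    if np.any(w < 0) or not np.all(np.isfinite(w)):
        raise SentimentError("backend weights must be finite and non-negative")
    total = w.sum()
    if total <= 0:
        raise SentimentError("backend weights sum to zero")
    return w / total


def _check_label_set(labels: Sequence[CircumplexLabel]) -> None:
    if len(labels) < 2:
        raise SentimentError("need at least two labels")
    anchors = np.array([(l.valence_anchor, l.arousal_anchor) for l in labels])
    if np.allclose(anchors, anchors[0]):
        raise SentimentError("degenerate label set: all anchors identical")
    for axis, name in ((0, "valence"), (1, "arousal")):
        if not (anchors[:, axis].max() > 0 and anchors[:, axis].min() < 0):
            raise SentimentError(
                f"label set must span the {name} axis with positive and "
                "negative anchors"
            )


def score_utterance(
    utterance: Utterance | str,
    label_set: Sequence[CircumplexLabel] = DEFAULT_LABELS,
    backend: ZeroShotBackend | None = None,
    utterance_index: int | None = None,
) -> SentimentScore:
    """Probability-weighted centroid of label anchors for one utterance."""
    _check_label_set(label_set)
    backend = backend if backend is not None else LexiconBackend()
    if isinstance(utterance, Utterance):
        text = utterance.text
        idx = utterance.utterance_index
    else:
        text = utterance
        idx = utterance_index if utterance_index is not None else 0
    p = classify_zero_shot(text, [l.label_text for l in label_set], backend)
    valence = float(np.dot(p, [l.valence_anchor for l in label_set]))
    arousal = float(np.dot(p, [l.arousal_anchor for l in label_set]))
    return SentimentScore(valence, arousal, idx)


def score_transcript(
    transcript: SessionTranscript,
    label_set: Sequence[CircumplexLabel] = DEFAULT_LABELS,
    backend: ZeroShotBackend | None = None,
) -> list[tuple[Utterance, SentimentScore]]:
    """Score every segmented utterance of a session."""
    backend = backend if backend is not None else LexiconBackend()
    return [
        (u, score_utterance(u, label_set, backend)) for u in transcript.utterances
    ]


def session_sentiment(
    scored: Iterable[tuple[Utterance, SentimentScore]],
    min_utterances: int = 5,
) -> SessionSentiment:
    """Unweighted per-role means of utterance valence and arousal.

    Raises :class:`InvalidSessionError` when either role has fewer than
    ``min_utterances`` scored utterances — such sessions are excluded from
    modelling because their means are unstable.
    """
    by_role: dict[str, list[SentimentScore]] = {PARTICIPANT: [], THERAPIST: []}
    for utt, score in scored:
        by_role[utt.speaker_role].append(score)
    for role in (PARTICIPANT, THERAPIST):
        if len(by_role[role]) < min_utterances:
            raise InvalidSessionError(
                f"role {role!r} has {len(by_role[role])} scored utterances, "
                f"fewer than the required {min_utterances}"
            )
    p = np.array([(s.valence, s.arousal) for s in by_role[PARTICIPANT]])
    t = np.array([(s.valence, s.arousal) for s in by_role[THERAPIST]])
    return SessionSentiment(
        participant_valence=float(p[:, 0].mean()),
        participant_arousal=float(p[:, 1].mean()),
        therapist_valence=float(t[:, 0].mean()),
        therapist_arousal=float(t[:, 1].mean()),
        n_utterances_participant=len(by_role[PARTICIPANT]),
        n_utterances_therapist=len(by_role[THERAPIST]),
    )
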