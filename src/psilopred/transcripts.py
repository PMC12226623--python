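"""Reading and segmenting speaker-labelled dialog transcripts.

A session transcript is an ordered list of speaker turns (participant or
therapist).  Each turn is segmented into *utterances* — sentences delimited
by terminal punctuation — which are the unit the sentiment model scores.

Two on-disk dialects are supported:

* TSV: one turn per line, ``ROLE<TAB>text`` with ``ROLE`` in ``{P, T}``
  (mapping configurable).
* JSON: ``{"session_id": ..., "participant_id": ...,
  "turns": [{"role": "participant"|"therapist", "text": ...}, ...]}``.

``write_transcript`` emits the JSON dialect and round-trips bit-exactly
through ``read_transcript``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Literal, Mapping

PARTICIPANT = "participant"
THERAPIST = "therapist"
ROLES = (PARTICIPANT, THERAPIST)

DEFAULT_TSV_ROLE_MAP: Mapping[str, str] = {"P": PARTICIPANT, "T": THERAPIST}

#: Abbreviations whose trailing period must not end a sentence.
ABBREVIATIONS = frozenset(
    {"mr", "mrs", "ms", "dr", "prof", "st", "etc", "e.g", "i.e", "vs", "approx"}
)

_BRACKET_RE = re.compile(r"\[[^\]]*\]")  # non-verbal annotations, e.g. [laughs]
_WS_RE = re.compile(r"\s+")
# sentence terminator: run of . ! ? or ellipsis, kept with the sentence
_SENT_RE = re.compile(r"[^.!?…]*[.!?…]+(?:['\"])?|[^.!?…]+$")


class TranscriptError(ValueError):
    """Malformed transcript input."""


@dataclass(frozen=True)
class Turn:
    """One contiguous stretch of speech by a single speaker."""

    speaker_role: str
    text: str
    index: int

    def __post_init__(self) -> None:
        if self.speaker_role not in ROLES:
            raise TranscriptError(f"unknown speaker role {self.speaker_role!r}")
        if not self.text.strip():
            raise TranscriptError(f"turn {self.index} has empty text")


@dataclass(frozen=True)
class Utterance:
    """A sentence-level unit within a turn; what the sentiment model scores."""

    speaker_role: str
    text: str
    turn_index: int
    utterance_index: int


@dataclass
class SessionTranscript:
    session_id: str
    participant_id: str
    turns: list[Turn] = field(default_factory=list)
    utterances: list[Utterance] = field(default_factory=list)


def normalize_text(text: str) -> str:
    """Strip bracketed annotations and collapse whitespace runs."""
    text = _BRACKET_RE.sub(" ", text)
    return _WS_RE.sub(" ", text).strip()


def _split_sentences(text: str) -> list[str]:
    """Split on terminal punctuation (. ! ? …) with an abbreviation guard."""
    pieces = [m.group(0).strip() for m in _SENT_RE.finditer(text)]
    pieces = [p for p in pieces if p]
    # re-join fragments whose terminator belongs to a guarded abbreviation
    merged: list[str] = []
    for piece in pieces:
        if merged:
            prev_word = merged[-1].rstrip(".").rsplit(None, 1)[-1].lower()
            if merged[-1].endswith(".") and prev_word in ABBREVIATIONS:
                merged[-1] = merged[-1] + " " + piece
                continue
        merged.append(piece)
    return merged


def read_transcript(
    source: str | Path | IO[str],
    dialect: Literal["tsv", "json"] = "json",
    *,
    role_map: Mapping[str, str] = DEFAULT_TSV_ROLE_MAP,
    session_id: str = "",
    participant_id: str = "",
) -> SessionTranscript:
    """Parse a transcript file or stream into a :class:`SessionTranscript`.

    Utterances are left empty; call :func:`segment_utterances` next.
    """
    if hasattr(source, "read"):
        raw = source.read()  # type: ignore[union-attr]
        name = getattr(source, "name", "<stream>")
    else:
        path = Path(source)
        raw = path.read_text(encoding="utf-8")
        name = str(path)
        if not session_id:
            session_id = path.stem
        if not participant_id:
            participant_id = path.stem

    if dialect == "tsv":
        turns: list[Turn] = []
        for lineno, line in enumerate(raw.splitlines(), start=1):
            if not line.strip():
                continue
            label, sep, text = line.partition("\t")
            label = label.strip()
            if not sep or label not in role_map:
                raise TranscriptError(
                    f"{name}: line {lineno}: unknown speaker label {label!r}"
                )
            text = normalize_text(text)
            if not text:
                raise TranscriptError(f"{name}: line {lineno}: empty turn text")
            turns.append(Turn(role_map[label], text, index=len(turns)))
        if not turns:
            raise TranscriptError(f"{name}: no turns")
        return SessionTranscript(session_id or name, participant_id or name, turns)

    if dialect == "json":
        doc = json.loads(raw)
        raw_turns = doc.get("turns", [])
        if not raw_turns:
            raise TranscriptError(f"{name}: no turns")
        turns = []
        for i, t in enumerate(raw_turns):
            role = t.get("role", "")
            if role not in ROLES:
                raise TranscriptError(
                    f"{name}: turn {i}: unknown speaker label {role!r}"
                )
            text = normalize_text(t.get("text", ""))
            if not text:
                raise TranscriptError(f"{name}: turn {i}: empty turn text")
            turns.append(Turn(role, text, index=i))
        return SessionTranscript(
            str(doc.get("session_id", session_id)),
            str(doc.get("participant_id", participant_id)),
            turns,
        )

    raise ValueError(f"unknown dialect {dialect!r}")


def write_transcript(transcript: SessionTranscript, target: str | Path | IO[str]) -> None:
    """Serialize to the JSON dialect; re-readable bit-exactly."""
    doc = {
        "session_id": transcript.session_id,
        "participant_id": transcript.participant_id,
        "turns": [{"role": t.speaker_role, "text": t.text} for t in transcript.turns],
    }
    payload = json.dumps(doc, ensure_ascii=False, indent=1)
    if hasattr(target, "write"):
        target.write(payload)  # type: ignore[union-attr]
    else:
        Path(target).write_text(payload, encoding="utf-8")


def segment_utterances(
    transcript: SessionTranscript, min_tokens: int = 1
) -> SessionTranscript:
    """Split every turn into sentence utterances, dropping short ones.

    Utterances with fewer than ``min_tokens`` whitespace tokens are removed;
    indices are contiguous from 0 in session order.  Idempotent on its output.
    """
    if not transcript.turns:
        raise TranscriptError("transcript has no turns")
    utterances: list[Utterance] = []
    for turn in transcript.turns:
        for sent in _split_sentences(normalize_text(turn.text)):
            if len(sent.split()) < min_tokens:
                continue
            utterances.append(
                Utterance(
                    speaker_role=turn.speaker_role,
                    text=sent,
                    turn_index=turn.index,
                    utterance_index=len(utterances),
                )
            )
    out = SessionTranscript(
        transcript.session_id, transcript.participant_id, list(transcript.turns)
    )
    out.utterances = utterances
    return out


def utterances_by_role(
    transcript: SessionTranscript,
) -> dict[str, list[Utterance]]:
    by_role: dict[str, list[Utterance]] = {PARTICIPANT: [], THERAPIST: []}
    for u in transcript.utterances:
        by_role[u.speaker_role].append(u)
    return by_role
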