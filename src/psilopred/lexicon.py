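"""Default circumplex label set and the deterministic lexicon backend data.

The eight emotion labels sit at 45° intervals on the unit circle of the
valence/arousal circumplex.  Each label carries a small synonym list used by
the deterministic lexicon backend (and, symmetrically, by the synthetic
transcript generator, so generated language scores where it was planted).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import yaml

_R = math.sqrt(2.0) / 2.0


@dataclass(frozen=True)
class CircumplexLabel:
    """A candidate emotion label with its (valence, arousal) anchor."""

    label_text: str
    valence_anchor: float
    arousal_anchor: float

    def __post_init__(self) -> None:
        r = math.hypot(self.valence_anchor, self.arousal_anchor)
        if r > 1.0 + 1e-9:
            raise ValueError(
                f"anchor for {self.label_text!r} lies outside the unit circle"
            )


#: Canonical Russell-circumplex label set: 8 anchors at 45° spacing.
DEFAULT_LABELS: tuple[CircumplexLabel, ...] = (
    CircumplexLabel("happy", 1.0, 0.0),
    CircumplexLabel("excited", _R, _R),
    CircumplexLabel("tense", 0.0, 1.0),
    CircumplexLabel("distressed", -_R, _R),
    CircumplexLabel("sad", -1.0, 0.0),
    CircumplexLabel("bored", -_R, -_R),
    CircumplexLabel("calm", 0.0, -1.0),
    CircumplexLabel("content", _R, -_R),
)

#: Term lists for the lexicon backend; every word belongs to exactly one label.
LEXICON: Mapping[str, tuple[str, ...]] = {
    "happy": (
        "happy", "glad", "joyful", "cheerful", "delighted", "pleased",
        "grateful", "wonderful", "hopeful", "good",
    ),
    "excited": (
        "excited", "thrilled", "exhilarated", "energized", "elated",
        "euphoric", "inspired", "lively", "eager", "animated",
    ),
    "tense": (
        "tense", "anxious", "nervous", "restless", "agitated", "jittery",
        "wired", "uneasy", "apprehensive", "alert",
    ),
    "distressed": (
        "distressed", "upset", "frightened", "panicked", "anguished",
        "overwhelmed", "desperate", "terrified", "alarmed", "shaken",
    ),
    "sad": (
        "sad", "unhappy", "miserable", "gloomy", "sorrowful", "down",
        "heartbroken", "hopeless", "grieving", "bad",
    ),
    "bored": (
        "bored", "tired", "dull", "listless", "weary", "drained", "numb",
        "flat", "sluggish", "indifferent",
    ),
    "calm": (
        "calm", "still", "quiet", "composed", "restful", "gentle", "steady",
        "placid", "unhurried", "grounded",
    ),
    "content": (
        "content", "peaceful", "satisfied", "serene", "relaxed",
        "comfortable", "settled", "soothed", "mellow", "tranquil",
    ),
}


def load_label_set(path: str | Path) -> tuple[CircumplexLabel, ...]:
    """Load a label set from YAML/JSON: list of {label, valence, arousal}."""
    path = Path(path)
    raw = path.read_text(encoding="utf-8")
    doc = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
    return tuple(
        CircumplexLabel(str(d["label"]), float(d["valence"]), float(d["arousal"]))
        for d in doc
    )


def dump_label_set(labels: Sequence[CircumplexLabel], path: str | Path) -> None:
    doc = [
        {"label": l.label_text, "valence": l.valence_anchor, "arousal": l.arousal_anchor}
        for l in labels
    ]
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=1), encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(doc), encoding="utf-8")
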