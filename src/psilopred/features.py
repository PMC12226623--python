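"""Assembly of the six-predictor feature row for the responder models.

Each retained participant contributes one row: the four session-sentiment
means (therapist/participant × valence/arousal), the PCA-weighted EBI
summary, and the treatment arm (1, 10 or 25 mg) encoded as two indicator
columns with 1 mg as the reference level — seven slope parameters in total.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .sentiment import SessionSentiment

DOSES = (1, 10, 25)

#: Design-matrix column order (after the intercept).
FEATURE_COLUMNS = (
    "therapist_arousal",
    "therapist_valence",
    "participant_arousal",
    "participant_valence",
    "ebi_summary",
    "dose_10",
    "dose_25",
)


class FeatureError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureRow:
    participant_id: str
    therapist_arousal: float
    therapist_valence: float
    participant_arousal: float
    participant_valence: float
    ebi_summary: float
    dose_mg: int

    def __post_init__(self) -> None:
        if self.dose_mg not in DOSES:
            raise FeatureError(
                f"{self.participant_id}: dose {self.dose_mg} not in {DOSES}"
            )
        for name in (
            "therapist_arousal",
            "therapist_valence",
            "participant_arousal",
            "participant_valence",
        ):
            v = getattr(self, name)
            if not (-1.0 <= v <= 1.0):
                raise FeatureError(
                    f"{self.participant_id}: {name} {v} outside [-1, 1]"
                )


def encode_dose(dose_mg: int) -> tuple[int, int]:
    """Treatment arm as two indicators; reference level 1 mg → (0, 0)."""
    if dose_mg == 1:
        return (0, 0)
    if dose_mg == 10:
        return (1, 0)
    if dose_mg == 25:
        return (0, 1)
    raise FeatureError(f"dose {dose_mg} not in {DOSES}")


def feature_vector(row: FeatureRow) -> list[float]:
    """Row values in :data:`FEATURE_COLUMNS` order (no intercept)."""
    d10, d25 = encode_dose(row.dose_mg)
    return [
        row.therapist_arousal,
        row.therapist_valence,
        row.participant_arousal,
        row.participant_valence,
        row.ebi_summary,
        float(d10),
        float(d25),
    ]


def assemble_features(
    sentiments: Mapping[str, SessionSentiment],
    ebi_summaries: Mapping[str, float],
    doses: Mapping[str, int],
    labels: Mapping[str, Optional[bool]],
) -> tuple[list[FeatureRow], list[bool], pd.DataFrame]:
    """Join per-participant components into model rows.

    Participants missing any component (sentiment, EBI, dose, or a defined
    outcome label) are dropped with a logged reason.  Returns rows, labels
    aligned with the rows, and the drop log.
    """
    rows: list[FeatureRow] = []
    kept_labels: list[bool] = []
    log_rows: list[dict[str, str]] = []
    for pid in sorted(labels):
        reasons = []
        if labels[pid] is None:
            reasons.append("undefined outcome label")
        if pid not in sentiments:
            reasons.append("no session sentiment")
        if pid not in ebi_summaries:
            reasons.append("no EBI summary")
        if pid not in doses:
            reasons.append("no dose record")
        if reasons:
            log_rows.append({"participant_id": pid, "reason": "; ".join(reasons)})
            continue
        s = sentiments[pid]
        rows.append(
            FeatureRow(
                participant_id=pid,
                therapist_arousal=s.therapist_arousal,
                therapist_valence=s.therapist_valence,
                participant_arousal=s.participant_arousal,
                participant_valence=s.participant_valence,
                ebi_summary=ebi_summaries[pid],
                dose_mg=doses[pid],
            )
        )
        kept_labels.append(bool(labels[pid]))
    log = pd.DataFrame(log_rows, columns=["participant_id", "reason"])
    return rows, kept_labels, log


def features_frame(rows: Sequence[FeatureRow], labels: Sequence[bool]) -> pd.DataFrame:
    """Feature table with one row per participant plus the outcome label."""
    records = []
    for row, y in zip(rows, labels):
        rec = {"participant_id": row.participant_id}
        rec.update(zip(FEATURE_COLUMNS, feature_vector(row)))
        rec["dose_mg"] = row.dose_mg
        rec["label"] = int(y)
        records.append(rec)
    return pd.DataFrame(records)
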