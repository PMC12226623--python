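"""Emotional Breakthrough Inventory (EBI) scoring.

The EBI is an eight-item self-report questionnaire indexing emotional
release/catharsis during a psychedelic experience; items are visual-analog
values on a 0–100 scale by default.  The conventional summary is the simple
mean of the eight items; this module also provides the PCA-weighted summary
— a weighted average whose weights are proportional to the first
principal-component loadings of the cohort item matrix — which is the
summary the responder models use.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

N_ITEMS = 8
ITEM_COLUMNS = tuple(f"ebi_{i}" for i in range(1, N_ITEMS + 1))


class EBIError(ValueError):
    pass


@dataclass(frozen=True)
class EBIResponse:
    participant_id: str
    items: tuple[float, ...]
    scale_min: float = 0.0
    scale_max: float = 100.0

    def __post_init__(self) -> None:
        if len(self.items) != N_ITEMS:
            raise EBIError(
                f"{self.participant_id}: expected {N_ITEMS} items, "
                f"got {len(self.items)}"
            )
        for i, v in enumerate(self.items, start=1):
            if not np.isfinite(v):
                raise EBIError(f"{self.participant_id}: item {i} missing")
            if not (self.scale_min <= v <= self.scale_max):
                raise EBIError(
                    f"{self.participant_id}: item {i} value {v} outside "
                    f"[{self.scale_min}, {self.scale_max}]"
                )


@dataclass(frozen=True)
class EBIWeights:
    """First-PC loadings rescaled to sum to one, plus the fit context."""

    weights: tuple[float, ...]
    explained_variance_fraction: float
    standardize: bool
    item_means: tuple[float, ...]
    item_sds: tuple[float, ...]
    scale_min: float = 0.0
    scale_max: float = 100.0

    def __post_init__(self) -> None:
        if len(self.weights) != N_ITEMS:
            raise EBIError("expected 8 weights")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise EBIError("weights must sum to 1")


def ebi_simple_mean(response: EBIResponse) -> float:
    """Conventional EBI summary: arithmetic mean of the eight items."""
    return float(np.mean(response.items))


def fit_ebi_pca(
    responses: Sequence[EBIResponse], standardize: bool = True
) -> EBIWeights:
    """First-principal-component weights from a cohort of EBI responses.

    The item matrix is centred (and z-scored when ``standardize``); the
    first right singular vector gives the loadings, sign-fixed so the
    weighted score correlates positively with the simple mean (loadings
    flipped when their sum is negative), then rescaled to sum to one.
    """
    if len(responses) <= N_ITEMS:
        raise EBIError(
            f"need more responses ({len(responses)}) than items ({N_ITEMS}) "
            "to fit PCA weights"
        )
    x = np.array([r.items for r in responses], dtype=float)
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=1)
    if standardize:
        zero_var = np.where(sds == 0)[0]
        if zero_var.size:
            raise EBIError(
                f"item {zero_var[0] + 1} has zero variance; cannot standardize"
            )
        xc = (x - means) / sds
    else:
        xc = x - means
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    loadings = vt[0]
    if loadings.sum() < 0:
        loadings = -loadings
    total = loadings.sum()
    if total <= 0:
        raise EBIError("first-component loadings sum to zero; cannot normalize")
    var = s**2
    return EBIWeights(
        weights=tuple(float(w) for w in loadings / total),
        explained_variance_fraction=float(var[0] / var.sum()),
        standardize=standardize,
        item_means=tuple(float(m) for m in means),
        item_sds=tuple(float(sd) for sd in sds),
        scale_min=responses[0].scale_min,
        scale_max=responses[0].scale_max,
    )


def ebi_pca_summary(response: EBIResponse, weights: EBIWeights) -> float:
    """PCA-weighted average of the items: Σ wᵢ·itemᵢ.

    Because the weights sum to one, the summary stays on the item scale and
    is directly comparable with :func:`ebi_simple_mean`; standardization
    only changes how the loadings were estimated (correlation- vs
    covariance-matrix PCA), not the weighting formula.
    """
    if (response.scale_min, response.scale_max) != (weights.scale_min, weights.scale_max):
        raise EBIError(
            f"response scale [{response.scale_min}, {response.scale_max}] does "
            f"not match the scale the weights were fit on "
            f"[{weights.scale_min}, {weights.scale_max}]"
        )
    return float(np.dot(weights.weights, response.items))


def read_ebi_csv(path: str | Path) -> list[EBIResponse]:
    """Read responses from CSV with columns participant_id, ebi_1..ebi_8."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing = [c for c in ("participant_id", *ITEM_COLUMNS) if c not in df.columns]
    if missing:
        raise EBIError(f"{path}: missing columns {missing}")
    return [
        EBIResponse(row["participant_id"], tuple(float(row[c]) for c in ITEM_COLUMNS))
        for _, row in df.iterrows()
    ]


def write_ebi_csv(responses: Iterable[EBIResponse], path: str | Path) -> None:
    rows = [
        {"participant_id": r.participant_id, **dict(zip(ITEM_COLUMNS, r.items))}
        for r in responses
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6g")


def save_weights(weights: EBIWeights, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "weights": list(weights.weights),
                "explained_variance_fraction": weights.explained_variance_fraction,
                "standardize": weights.standardize,
                "item_means": list(weights.item_means),
                "item_sds": list(weights.item_sds),
                "scale_min": weights.scale_min,
                "scale_max": weights.scale_max,
            },
            indent=1,
        ),
        encoding="utf-8",
    )


def load_weights(path: str | Path) -> EBIWeights:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    return EBIWeights(
        weights=tuple(doc["weights"]),
        explained_variance_fraction=doc["explained_variance_fraction"],
        standardize=doc["standardize"],
        item_means=tuple(doc["item_means"]),
        item_sds=tuple(doc["item_sds"]),
        scale_min=doc.get("scale_min", 0.0),
        scale_max=doc.get("scale_max", 100.0),
    )
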