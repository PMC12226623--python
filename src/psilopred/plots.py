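"""Report figures: ROC curves, class-probability KDEs, predictor scatters."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def roc_plot(results: Mapping[str, dict], path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 5))
    for name in ("Week 3", "Sustained"):
        if name not in results:
            continue
        cv = results[name]["cv"]
        ax.plot(cv.roc_fpr, cv.roc_tpr, label=f"{name} (AUC={cv.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def kde_plot(results: Mapping[str, dict], path: str | Path) -> None:
    names = [n for n in ("Week 3", "Sustained") if n in results]
    fig, axes = plt.subplots(len(names), 1, figsize=(6, 3 * len(names)), squeeze=False)
    for ax, name in zip(axes[:, 0], names):
        d = results[name]["density"]
        ax.plot(d.grid, d.density_non_responder, label="non-responder")
        ax.plot(d.grid, d.density_responder, label="responder")
        ax.set_title(name)
        ax.set_xlabel("Predicted responder probability")
        ax.set_ylabel("Density")
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def scatter_grid(
    frame: pd.DataFrame, week3_change: Sequence[float], path: str | Path
) -> None:
    predictors = [
        ("therapist_arousal", "Therapist arousal"),
        ("therapist_valence", "Therapist valence"),
        ("participant_arousal", "Participant arousal"),
        ("participant_valence", "Participant valence"),
        ("ebi_summary", "EBI summary"),
        ("dose_mg", "Dose (mg)"),
    ]
    y = np.asarray(week3_change, dtype=float)
    fig, axes = plt.subplots(2, 3, figsize=(11, 7))
    for ax, (col, label) in zip(axes.ravel(), predictors):
        x = frame[col].to_numpy(dtype=float)
        ax.scatter(x, y, s=12, alpha=0.7)
        if np.std(x) > 0:
            slope, intercept = np.polyfit(x, y, 1)
            xs = np.linspace(x.min(), x.max(), 10)
            ax.plot(xs, slope * xs + intercept, "r-", lw=1)
        ax.set_xlabel(label)
        ax.set_ylabel("MADRS change (wk 3)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
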