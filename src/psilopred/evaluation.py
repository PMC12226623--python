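"""Cross-validated evaluation of the responder models.

Leave-one-out cross-validation (LOOCV) refits the model n times, each time
predicting the held-out participant — including refitting the EBI PCA
weights inside every training fold so no cohort-level information leaks
into the held-out prediction.  Out-of-fold probabilities are summarized by
a confusion matrix at a probability threshold (default 0.5), the usual
accuracy / Matthews correlation / F1 metrics, the ROC curve with trapezoid
AUC, and a percentile-bootstrap 95% confidence interval for the AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from .ebi import EBIResponse, ebi_pca_summary, fit_ebi_pca
from .features import FEATURE_COLUMNS
from .model import fit_logistic, predict_proba


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionMatrix:
    tn: int
    fp: int
    fn: int
    tp: int

    def __post_init__(self) -> None:
        if min(self.tn, self.fp, self.fn, self.tp) < 0:
            raise EvaluationError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tn + self.fp + self.fn + self.tp


@dataclass
class CVResult:
    """Pooled out-of-fold LOOCV predictions and derived metrics."""

    participant_ids: list[str]
    probabilities: np.ndarray
    labels: np.ndarray
    doses: np.ndarray
    threshold: float
    confusion: ConfusionMatrix
    accuracy: float
    mcc: float
    f1: float
    auc: float
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    auc_ci: Optional[tuple[float, float]] = None
    failed_folds: list[str] = field(default_factory=list)


def confusion_at_threshold(
    probabilities: Sequence[float],
    labels: Sequence[bool] | Sequence[int],
    threshold: float = 0.5,
) -> ConfusionMatrix:
    """Tally predictions, calling positive iff probability ≥ threshold."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if np.any((p < 0) | (p > 1)):
        raise EvaluationError("probabilities must lie in [0, 1]")
    pred = p >= threshold
    return ConfusionMatrix(
        tn=int(np.sum(~pred & (y == 0))),
        fp=int(np.sum(pred & (y == 0))),
        fn=int(np.sum(~pred & (y == 1))),
        tp=int(np.sum(pred & (y == 1))),
    )


def metrics(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """(accuracy, MCC, F1) from a confusion matrix.

    MCC is defined as 0 when any marginal factor of its denominator is 0;
    F1 is 0 when there are no predicted or actual positives.
    """
    if cm.n == 0:
        raise EvaluationError("empty confusion matrix")
    tn, fp, fn, tp = (float(v) for v in (cm.tn, cm.fp, cm.fn, cm.tp))
    accuracy = (tp + tn) / cm.n
    f1_denom = 2 * tp + fp + fn
    f1 = 2 * tp / f1_denom if f1_denom > 0 else 0.0
    factors = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(factors) if factors > 0 else 0.0
    return float(accuracy), float(mcc), float(f1)


def roc_auc(
    probabilities: Sequence[float], labels: Sequence[bool] | Sequence[int]
) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC points by sweeping all distinct thresholds, AUC by trapezoid.

    Tied scores step the curve diagonally, so the AUC equals the
    tie-corrected pairwise concordance probability.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise EvaluationError("both classes required for ROC")
    fpr, tpr, _ = roc_curve(y, p, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def _auc_rank(p: np.ndarray, y: np.ndarray) -> float:
    """Tie-corrected AUC via the rank-sum (Mann–Whitney) identity."""
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    ranks = stats.rankdata(p)
    return (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def bootstrap_auc_ci(
    probabilities: Sequence[float],
    labels: Sequence[bool] | Sequence[int],
    reps: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the AUC of (probability, label) pairs.

    Participant-level resampling with replacement; resamples lacking one of
    the classes are redrawn.  Deterministic given ``seed``.
    """
    if reps < 1:
        raise EvaluationError("reps must be >= 1")
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise EvaluationError("both classes required")
    n = len(p)
    rng = np.random.default_rng(seed)
    aucs = np.empty(reps)
    done = 0
    while done < reps:
        idx = rng.integers(0, n, size=(reps - done, n))
        ys = y[idx]
        ok = (ys.sum(axis=1) > 0) & (ys.sum(axis=1) < n)
        for row in np.nonzero(ok)[0]:
            aucs[done] = _auc_rank(p[idx[row]], ys[row])
            done += 1
    lower, upper = np.quantile(aucs, (alpha / 2, 1 - alpha / 2))
    return float(lower), float(upper)


def loocv_probabilities(
    features: pd.DataFrame,
    labels: Sequence[bool] | Sequence[int],
    ebi_items: Optional[pd.DataFrame] = None,
    regularization: Optional[float] = None,
    ebi_standardize: bool = True,
    min_rows: int = 20,
) -> tuple[np.ndarray, list[str]]:
    """Out-of-fold predicted probability for every participant.

    ``features`` holds the non-EBI predictors (sentiment columns plus
    ``dose_10``/``dose_25``).  When ``ebi_items`` (participant-aligned
    ``ebi_1..ebi_8`` matrix) is given, the PCA weights for the EBI summary
    are refit on each training fold and applied to the held-out participant
    — the summary is never computed with knowledge of the held-out row.
    Folds whose training labels collapse to a single class are recorded as
    failed and get probability NaN.
    """
    y = np.asarray(labels, dtype=int)
    n = len(features)
    if n < min_rows:
        raise EvaluationError(f"need at least {min_rows} rows for LOOCV, got {n}")
    if len(y) != n:
        raise EvaluationError("features and labels length mismatch")

    items = None if ebi_items is None else ebi_items.to_numpy(dtype=float)
    if items is None:
        # pre-computed ebi_summary column used as-is (no per-fold refit)
        cols = [c for c in FEATURE_COLUMNS if c in features.columns]
        n_before_ebi = len(cols)
    else:
        cols = [
            c
            for c in FEATURE_COLUMNS
            if c != "ebi_summary" and c in features.columns
        ]
        # fold EBI summary is inserted after the sentiment block
        n_before_ebi = sum(not c.startswith("dose_") for c in cols)
    x_base = features[cols].to_numpy(dtype=float)
    ids = (
        features["participant_id"].astype(str).tolist()
        if "participant_id" in features.columns
        else [str(i) for i in range(n)]
    )

    oof = np.full(n, np.nan)
    failed: list[str] = []
    for i in range(n):
        train = np.arange(n) != i
        y_train = y[train]
        if len(np.unique(y_train)) < 2:
            failed.append(ids[i])
            continue
        x_train = x_base[train]
        x_test = x_base[i : i + 1]
        if items is not None:
            fold_responses = [
                EBIResponse(str(j), tuple(items[j]))
                for j in np.nonzero(train)[0]
            ]
            w = fit_ebi_pca(fold_responses, standardize=ebi_standardize)
            summary_train = np.array(
                [ebi_pca_summary(r, w) for r in fold_responses]
            )
            summary_test = ebi_pca_summary(
                EBIResponse(str(i), tuple(items[i])), w
            )
            x_train = np.column_stack(
                [x_train[:, :n_before_ebi], summary_train, x_train[:, n_before_ebi:]]
            )
            x_test = np.column_stack(
                [x_test[:, :n_before_ebi], [summary_test], x_test[:, n_before_ebi:]]
            )
        fit = fit_logistic(
            x_train,
            y_train,
            regularization=regularization,
            min_rows=min(min_rows, len(y_train)),
        )
        oof[i] = predict_proba(fit, x_test)[0]
    return oof, failed


def evaluate_cv(
    features: pd.DataFrame,
    labels: Sequence[bool] | Sequence[int],
    ebi_items: Optional[pd.DataFrame] = None,
    threshold: float = 0.5,
    bootstrap_reps: int = 2000,
    seed: int = 0,
    regularization: Optional[float] = None,
) -> CVResult:
    """Run LOOCV and derive all pooled metrics."""
    oof, failed = loocv_probabilities(
        features, labels, ebi_items=ebi_items, regularization=regularization
    )
    y = np.asarray(labels, dtype=int)
    ok = ~np.isnan(oof)
    p_ok, y_ok = oof[ok], y[ok]
    cm = confusion_at_threshold(p_ok, y_ok, threshold)
    accuracy, mcc, f1 = metrics(cm)
    fpr, tpr, auc = roc_auc(p_ok, y_ok)
    ci = bootstrap_auc_ci(p_ok, y_ok, reps=bootstrap_reps, seed=seed)
    ids = (
        features["participant_id"].astype(str).tolist()
        if "participant_id" in features.columns
        else [str(i) for i in range(len(y))]
    )
    doses = (
        features["dose_mg"].to_numpy()
        if "dose_mg" in features.columns
        else np.full(len(y), -1)
    )
    return CVResult(
        participant_ids=ids,
        probabilities=oof,
        labels=y,
        doses=doses,
        threshold=threshold,
        confusion=cm,
        accuracy=accuracy,
        mcc=mcc,
        f1=f1,
        auc=auc,
        roc_fpr=fpr,
        roc_tpr=tpr,
        auc_ci=ci,
        failed_folds=failed,
    )


def per_group_results(cv: CVResult, model_name: str = "model") -> pd.DataFrame:
    """Metrics per dose arm plus the pooled ALL row (Group column).

    Per-dose rows subset the pooled out-of-fold probabilities; groups whose
    labels collapse to one class keep the threshold metrics but omit AUC.
    """
    rows = []
    ok = ~np.isnan(cv.probabilities)
    groups: list[tuple[str, np.ndarray]] = [("ALL", ok)]
    for dose in sorted(set(cv.doses[ok])):
        groups.append((f"{dose} mg", ok & (cv.doses == dose)))
    for name, mask in groups:
        p, y = cv.probabilities[mask], cv.labels[mask]
        cm = confusion_at_threshold(p, y, cv.threshold)
        accuracy, mcc, f1 = metrics(cm)
        if len(np.unique(y)) == 2:
            auc = roc_auc(p, y)[2]
        else:
            auc = np.nan
        rows.append(
            {
                "Model": model_name,
                "Group": name,
                "Accuracy": accuracy,
                "MCC": mcc,
                "f1": f1,
                "AUC": auc,
                "TN": cm.tn,
                "FP": cm.fp,
                "FN": cm.fn,
                "TP": cm.tp,
                "N": cm.n,
            }
        )
    return pd.DataFrame(rows)


def univariate_correlations(
    features: pd.DataFrame,
    madrs_week3_change: Sequence[float],
    dose_coding: str = "mg",
) -> pd.DataFrame:
    """Pearson r (and two-sided p) of each predictor vs week-3 MADRS change.

    The treatment arm enters as a scalar: numeric mg by default, or ordinal
    0/1/2 with ``dose_coding='ordinal'``.
    """
    y = np.asarray(madrs_week3_change, dtype=float)
    if len(y) < 3:
        raise EvaluationError("need at least 3 observations")
    cols = {
        "therapist_arousal": features["therapist_arousal"],
        "therapist_valence": features["therapist_valence"],
        "participant_arousal": features["participant_arousal"],
        "participant_valence": features["participant_valence"],
        "ebi_summary": features["ebi_summary"],
    }
    dose = features["dose_mg"].to_numpy(dtype=float)
    if dose_coding == "ordinal":
        dose = np.searchsorted(np.array([1.0, 10.0, 25.0]), dose).astype(float)
    cols["dose"] = pd.Series(dose)
    rows = []
    for name, series in cols.items():
        x = np.asarray(series, dtype=float)
        if np.std(x) == 0:
            raise EvaluationError(f"zero-variance column {name!r}")
        r, p = stats.pearsonr(x, y)
        rows.append({"feature": name, "r": float(r), "p": float(p), "n": len(y)})
    return pd.DataFrame(rows)
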