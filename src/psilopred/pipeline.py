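"""End-to-end pipeline: transcripts → sentiment → features → models → report.

``run_pipeline`` reads transcripts (JSON dialect), EBI CSV and MADRS CSV
from configured paths and writes, under the output directory:

* ``model_fits.csv`` — per-model fit diagnostics (pseudo-R², LR chi-square,
  df, p, N),
* ``cv_metrics.csv`` — per-model, per-dose-group cross-validated metrics
  (accuracy, MCC, f1, AUC, confusion counts),
* ``auc_ci.csv`` — AUC with bootstrap 95% CI per model,
* ``cv_probabilities.csv`` and ``roc_points.csv``,
* ``univariate_correlations.csv`` — Pearson r of each predictor vs the
  week-3 MADRS change,
* plots (ROC curves, class-probability KDEs, scatter grid), and
* ``provenance.json`` — config hash, seeds and package versions.

Every numeric output is reproducible from config + seed alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ebi import ITEM_COLUMNS, ebi_pca_summary, fit_ebi_pca, read_ebi_csv
from .evaluation import CVResult, evaluate_cv, per_group_results, univariate_correlations
from .features import assemble_features, features_frame
from .model import class_probability_density, fit_logistic, predict_proba
from .outcomes import (
    apply_exclusions,
    madrs_change,
    read_madrs_csv,
    responder_week3,
    sustained_responder,
)
from .sentiment import (
    InvalidSessionError,
    LexiconBackend,
    NLIZeroShotBackend,
    score_transcript,
    session_sentiment,
)
from .transcripts import read_transcript, segment_utterances

log = logging.getLogger("psilopred")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    transcripts_dir: str = "data/transcripts"
    ebi_csv: str = "data/ebi.csv"
    madrs_csv: str = "data/madrs.csv"
    output_dir: str = "results/pipeline"
    backend: str = "lexicon"  # or "nli"
    min_tokens: int = 1
    min_utterances: int = 5
    threshold: float = 0.5
    bootstrap_reps: int = 2000
    bootstrap_seed: int = 0
    normal_range_max: int = 6
    ebi_standardize: bool = True
    regularization: Optional[float] = None
    make_plots: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        doc.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**doc)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _make_backend(config: PipelineConfig):
    if config.backend == "lexicon":
        return LexiconBackend()
    if config.backend == "nli":
        return NLIZeroShotBackend()
    raise PipelineError("config", f"unknown backend {config.backend!r}")


def score_sessions(config: PipelineConfig) -> pd.DataFrame:
    """Score every transcript; returns per-utterance scores (long table)."""
    backend = _make_backend(config)
    tdir = Path(config.transcripts_dir)
    paths = sorted(tdir.glob("*.json"))
    if not paths:
        raise PipelineError("sentiment", f"no transcripts in {tdir}")
    rows = []
    for path in paths:
        transcript = segment_utterances(
            read_transcript(path, "json"), min_tokens=config.min_tokens
        )
        for utt, score in score_transcript(transcript, backend=backend):
            rows.append(
                {
                    "session_id": transcript.session_id,
                    "participant_id": transcript.participant_id,
                    "utterance_index": utt.utterance_index,
                    "role": utt.speaker_role,
                    "valence": score.valence,
                    "arousal": score.arousal,
                }
            )
    return pd.DataFrame(rows)


def _session_sentiments(utt_scores: pd.DataFrame, config: PipelineConfig):
    from .sentiment import SentimentScore
    from .transcripts import Utterance

    sentiments = {}
    skipped = []
    for pid, group in utt_scores.groupby("participant_id"):
        scored = [
            (
                Utterance(row.role, "", 0, int(row.utterance_index)),
                SentimentScore(row.valence, row.arousal, int(row.utterance_index)),
            )
            for row in group.itertuples()
        ]
        try:
            sentiments[str(pid)] = session_sentiment(
                scored, min_utterances=config.min_utterances
            )
        except InvalidSessionError as exc:
            skipped.append({"participant_id": str(pid), "reason": str(exc)})
            log.warning("session %s skipped: %s", pid, exc)
    return sentiments, pd.DataFrame(skipped, columns=["participant_id", "reason"])


def run_pipeline(config: PipelineConfig) -> dict[str, object]:
    """Execute all stages and write the report bundle; returns key results."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- outcomes & exclusions ------------------------------------------
    try:
        cohort = read_madrs_csv(config.madrs_csv)
    except Exception as exc:
        raise PipelineError("outcomes", str(exc)) from exc
    week3_cohort, excl3 = apply_exclusions(
        cohort, normal_range_max=config.normal_range_max, sustained=False
    )
    sustained_cohort, excl_sust = apply_exclusions(
        week3_cohort, normal_range_max=config.normal_range_max, sustained=True
    )
    excl3.to_csv(outdir / "exclusions_week3.csv", index=False)
    excl_sust.to_csv(outdir / "exclusions_sustained.csv", index=False)

    # --- sentiment -------------------------------------------------------
    utt_scores = score_sessions(config)
    utt_scores.to_csv(outdir / "utterance_scores.csv", index=False, float_format="%.6f")
    sentiments, skipped = _session_sentiments(utt_scores, config)
    skipped.to_csv(outdir / "invalid_sessions.csv", index=False)

    # --- EBI -------------------------------------------------------------
    try:
        ebi_responses = read_ebi_csv(config.ebi_csv)
    except Exception as exc:
        raise PipelineError("ebi", str(exc)) from exc
    ebi_by_pid = {r.participant_id: r for r in ebi_responses}

    results: dict[str, object] = {}
    fit_rows, metric_frames, ci_rows, prob_frames, roc_frames = [], [], [], [], []

    for model_name, model_cohort, label_fn in (
        ("Week 3", week3_cohort, responder_week3),
        ("Sustained", sustained_cohort, sustained_responder),
    ):
        labels = {s.participant_id: label_fn(s) for s in model_cohort}
        doses = {
            s.participant_id: s.dose_mg
            for s in model_cohort
            if s.dose_mg is not None
        }
        # full-cohort PCA weights for the all-data fit & univariate panel
        cohort_ebi = [
            ebi_by_pid[pid] for pid in labels if pid in ebi_by_pid
        ]
        if len(cohort_ebi) <= 8:
            raise PipelineError("ebi", f"{model_name}: too few EBI responses")
        weights = fit_ebi_pca(cohort_ebi, standardize=config.ebi_standardize)
        summaries = {
            r.participant_id: ebi_pca_summary(r, weights) for r in cohort_ebi
        }

        rows, y, drop_log = assemble_features(sentiments, summaries, doses, labels)
        drop_log.to_csv(
            outdir / f"dropped_{model_name.lower().replace(' ', '')}.csv", index=False
        )
        if len(rows) < 20:
            raise PipelineError(
                "features", f"{model_name}: only {len(rows)} complete rows"
            )
        frame = features_frame(rows, y)

        # all-data fit (adequacy check, Table-1 shape)
        try:
            fit = fit_logistic(rows, y, regularization=config.regularization)
        except Exception as exc:
            raise PipelineError("fit", f"{model_name}: {exc}") from exc
        fit.to_json(outdir / f"fit_{model_name.lower().replace(' ', '')}.json")
        fit_rows.append(
            {
                "Model": model_name,
                "Pseudo R-squared": fit.pseudo_r2,
                "Chi-square": fit.lr_chi2,
                "p-value": fit.p_value,
                "df": fit.df,
                "N": fit.n,
            }
        )

        # class-probability densities from the all-data fit
        in_sample = predict_proba(fit, rows)
        density = class_probability_density(in_sample, y)

        # LOOCV with per-fold EBI PCA refit
        ebi_items = pd.DataFrame(
            [ebi_by_pid[r.participant_id].items for r in rows],
            columns=list(ITEM_COLUMNS),
        )
        try:
            cv: CVResult = evaluate_cv(
                frame,
                y,
                ebi_items=ebi_items,
                threshold=config.threshold,
                bootstrap_reps=config.bootstrap_reps,
                seed=config.bootstrap_seed,
                regularization=config.regularization,
            )
        except Exception as exc:
            raise PipelineError("crossval", f"{model_name}: {exc}") from exc

        metric_frames.append(per_group_results(cv, model_name))
        ci_rows.append(
            {
                "Model": model_name,
                "AUC": cv.auc,
                "Lower": cv.auc_ci[0],
                "Upper": cv.auc_ci[1],
            }
        )
        prob_frames.append(
            pd.DataFrame(
                {
                    "model": model_name,
                    "participant_id": cv.participant_ids,
                    "label": cv.labels,
                    "dose_mg": cv.doses,
                    "oof_probability": cv.probabilities,
                }
            )
        )
        roc_frames.append(
            pd.DataFrame(
                {"model": model_name, "fpr": cv.roc_fpr, "tpr": cv.roc_tpr}
            )
        )
        results[model_name] = {
            "fit": fit,
            "cv": cv,
            "density": density,
            "frame": frame,
        }

        if model_name == "Week 3":
            changes = [
                madrs_change(next(s for s in model_cohort if s.participant_id == r.participant_id), 3)
                for r in rows
            ]
            corr = univariate_correlations(frame, changes)
            corr.to_csv(
                outdir / "univariate_correlations.csv", index=False, float_format="%.6f"
            )
            results["univariate"] = corr
            results["week3_changes"] = changes

    pd.DataFrame(fit_rows).to_csv(
        outdir / "model_fits.csv", index=False, float_format="%.6f"
    )
    metrics_table = pd.concat(metric_frames, ignore_index=True)
    metrics_table.to_csv(outdir / "cv_metrics.csv", index=False, float_format="%.6f")
    pd.DataFrame(ci_rows).to_csv(
        outdir / "auc_ci.csv", index=False, float_format="%.6f"
    )
    pd.concat(prob_frames, ignore_index=True).to_csv(
        outdir / "cv_probabilities.csv", index=False, float_format="%.6f"
    )
    pd.concat(roc_frames, ignore_index=True).to_csv(
        outdir / "roc_points.csv", index=False, float_format="%.6f"
    )

    if config.make_plots:
        from . import plots

        plots.roc_plot(results, outdir / "roc.png")
        plots.kde_plot(results, outdir / "class_probability_kde.png")
        if "univariate" in results:
            plots.scatter_grid(
                results["Week 3"]["frame"],  # type: ignore[index]
                results["week3_changes"],  # type: ignore[arg-type]
                outdir / "univariate_scatter.png",
            )

    provenance = {
        "package_version": __version__,
        "config": asdict(config),
        "config_hash": self_hash(config),
        "seeds": {"bootstrap": config.bootstrap_seed},
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (outdir / "provenance.json").write_text(
        json.dumps(provenance, indent=1), encoding="utf-8"
    )
    results["metrics_table"] = metrics_table
    return results


def self_hash(config: PipelineConfig) -> str:
    return config.config_hash()
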