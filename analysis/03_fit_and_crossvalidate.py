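#!/usr/bin/env python
"""Fit the responder models and evaluate them by leave-one-out CV.

Runs the full pipeline: exclusion filters on the MADRS series, session
sentiment means, per-cohort EBI PCA weights, the six-predictor logistic
fits (week-3 and sustained responders), LOOCV with per-fold EBI weight
refits, confusion-matrix metrics per dose group, ROC/AUC with bootstrap
95% CIs, and the univariate predictor correlations. Writes the report
bundle (tables, plots, provenance).

Usage: python analysis/03_fit_and_crossvalidate.py [--cohort results/cohort]
"""

import argparse
from pathlib import Path

from psilopred.pipeline import PipelineConfig, run_pipeline


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results/report"))
    ap.add_argument("--bootstrap-reps", type=int, default=2000)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    config = PipelineConfig(
        transcripts_dir=str(args.cohort / "transcripts"),
        ebi_csv=str(args.cohort / "ebi.csv"),
        madrs_csv=str(args.cohort / "madrs.csv"),
        output_dir=str(args.out),
        bootstrap_reps=args.bootstrap_reps,
        bootstrap_seed=args.seed,
    )
    results = run_pipeline(config)

    print("cross-validated metrics:")
    print(
        results["metrics_table"].to_string(
            index=False, float_format=lambda v: f"{v:.3f}"
        )
    )
    for name in ("Week 3", "Sustained"):
        fit = results[name]["fit"]
        print(
            f"{name}: pseudo-R2={fit.pseudo_r2:.3f} "
            f"chi2={fit.lr_chi2:.2f} (df={fit.df}, p={fit.p_value:.2e}, n={fit.n})"
        )
    print(f"report written to {args.out}")


if __name__ == "__main__":
    main()
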