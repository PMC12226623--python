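#!/usr/bin/env python
"""Score transcript utterances with the 2-D circumplex sentiment model.

Segments every session transcript into utterances, scores each with the
deterministic lexicon zero-shot backend (valence and arousal from the
probability-weighted centroid of the eight circumplex anchors), and writes
the long utterance-level table.

Usage: python analysis/02_score_sentiment.py [--cohort results/cohort]
"""

import argparse
from pathlib import Path

from psilopred.pipeline import PipelineConfig, score_sessions


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results/sentiment"))
    args = ap.parse_args()

    config = PipelineConfig(
        transcripts_dir=str(args.cohort / "transcripts"),
        output_dir=str(args.out),
    )
    scores = score_sessions(config)
    args.out.mkdir(parents=True, exist_ok=True)
    path = args.out / "utterance_scores.csv"
    scores.to_csv(path, index=False, float_format="%.6f")

    by_role = scores.groupby("role")[["valence", "arousal"]].mean()
    print(f"scored {len(scores)} utterances from {scores.session_id.nunique()} sessions")
    print("mean scores by role:")
    print(by_role.round(3).to_string())
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
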