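# psilopred

Predicting clinical response to psilocybin therapy for treatment-resistant
depression from the language of the first post-dosing *integration session*.

After a psilocybin dosing session, participant and therapist meet to talk
through the experience. This package implements a pipeline that turns the
transcript of that dialog — together with the participant's Emotional
Breakthrough Inventory (EBI) and treatment dose — into a prediction of
whether the participant will be a MADRS *responder* (≥50% reduction from
baseline at week 3) or a *sustained responder* (≥50% reduction at weeks 3,
6, 9 and 12):

1. **Transcripts** — speaker-labelled dialog (TSV or JSON) is segmented
   into sentence-level utterances.
2. **2-D sentiment** — each utterance gets a valence/arousal score in
   [−1, 1]²: a pluggable zero-shot classifier assigns probabilities `pᵢ` to
   eight emotion labels placed on Russell's circumplex, and the score is
   the probability-weighted centroid of the label anchors
   `(v, a) = Σᵢ pᵢ·(vᵢ, aᵢ)`. The reference backend is a BART-MNLI style
   NLI zero-shot classifier (optional); a deterministic lexicon backend
   (matched-term counts with Laplace smoothing) ships for testing and
   simulation.
3. **Session sentiment** — unweighted per-speaker means, giving four
   numbers per session: participant/therapist × valence/arousal.
4. **EBI summary** — a weighted average of the eight EBI items with
   weights proportional to the first principal-component loadings of the
   cohort item matrix (sign-fixed, rescaled to sum to 1).
5. **Responder models** — binary logistic regression on the four sentiment
   means, the EBI summary and two dose indicators (reference 1 mg; df = 7),
   with McFadden pseudo-R² / likelihood-ratio diagnostics.
6. **Evaluation** — leave-one-out cross-validation (EBI PCA weights refit
   inside every training fold), confusion-matrix metrics (accuracy, MCC,
   F1), ROC/AUC with percentile-bootstrap 95% CIs, per-dose breakdowns,
   and univariate Pearson correlations of each predictor against the
   week-3 MADRS change.

No clinical data ship with the package. A synthetic-cohort generator
(`psilopred.simulate`) produces transcripts, EBI and MADRS files with the
dependence structure the analysis assumes — a single latent "emotional
breakthrough" variable drives session sentiment, EBI items and MADRS
reduction, plus a dose effect and missing visits — so the entire pipeline
is testable end to end.

## Worked example

```bash
python analysis/01_simulate_cohort.py --seed 1      # cohort -> results/cohort/
python analysis/02_score_sentiment.py               # utterance scores
python analysis/03_fit_and_crossvalidate.py         # models + report
python analysis/04_calibration_checks.py            # null/strong/planted checks
```

The third step prints (seed 1):

```
    Model Group  Accuracy   MCC    f1   AUC  TN  FP  FN  TP  N
   Week 3   ALL     0.785 0.537 0.706 0.886  49   9  11  24 93
   ...
Sustained   ALL     0.814 0.569 0.704 0.878  51   7   9  19 86
Week 3: pseudo-R2=0.535 chi2=65.90 (df=7, p=9.91e-12, n=93)
Sustained: pseudo-R2=0.512 chi2=55.54 (df=7, p=1.17e-09, n=86)
```

Reading: of the 101 simulated participants, 93 survive the exclusion
filters for the week-3 analysis; out-of-fold predictions classify 78.5% of
them correctly and rank responders above non-responders with probability
0.886 (AUC). The confusion counts (TN/FP/FN/TP) are at the 0.5 probability
threshold. The calibration step confirms the machinery: LOOCV AUC ≈ 0.5 on
a cohort with no feature–outcome link, high AUC on a low-noise cohort, and
planted logistic coefficients recovered within a few percent at n = 2000.

The same pipeline runs from the command line (`psilopred simulate`,
`psilopred report --transcripts ... --ebi ... --madrs ...`) or from a YAML
config; every output directory contains a `provenance.json` with the
config hash and seeds, and reruns are byte-identical.

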