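# Methods

This note documents the models and procedures implemented in `psilopred`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical decisions that matter.

## Utterance segmentation

A session transcript is an ordered list of speaker turns (participant or
therapist). Each turn is split into sentence-level utterances at terminal
punctuation (`.`, `!`, `?`, `…`) with a guard list for common
abbreviations (Dr., e.g., …). Bracketed non-verbal annotations
(`[laughs]`) are stripped and whitespace runs collapsed before
tokenization; casing is preserved because NLI backends are case-aware.
Utterances shorter than `min_tokens` whitespace tokens are dropped
(default 1, i.e. keep everything). Sentence-within-turn is the chosen
granularity: it gives the classifier short, coherent units; the
`min_tokens` knob and the fact that a turn with no terminator is one
utterance cover coarser readings.

## Two-dimensional sentiment

Sentiment is modelled on Russell's valence/arousal circumplex. A *label
set* is a list of emotion words, each anchored at a point on or inside
the unit circle; the default is eight words at 45° spacing (happy at
(1, 0), excited, tense, distressed, sad, bored, calm, content). A
zero-shot classification backend maps an utterance to non-negative
weights over the labels; after normalization to a probability vector
`p`, the utterance score is the centroid `Σᵢ pᵢ·anchorᵢ`. Scores
therefore always lie in the convex hull of the anchors, and permuting
the label order changes nothing.

Backends are pluggable behind a one-method protocol:

* **NLI backend** (reference): entailment probabilities from a
  BART-MNLI-style zero-shot pipeline with hypothesis template
  `"This statement expresses {label}."`. Optional dependency; never used
  by tests.
* **Lexicon backend** (deterministic): per-label weight = number of
  matched lexicon terms (case-insensitive, word boundaries, occurrences
  counted) + 1 (Laplace). Used by the test suite and the transcript
  generator. With symmetric anchors the smoothing mass cancels, so an
  utterance with per-label term counts `m` scores
  `Σ m·anchor / (K + Σm)` for `K = 8` labels — the attainable region is
  the hull shrunk by `M/(M+K)` at `M` matched terms.

Session sentiment is the unweighted mean of utterance valence and arousal
per speaker role (the aggregation the "average sentiment" framing
implies; no length weighting). Sessions where either role has fewer than
`min_utterances` scored utterances (default 5) are rejected as unstable
for modelling; both the statistic (mean vs median) and the threshold are
configurable.

## EBI scoring

The Emotional Breakthrough Inventory has eight items on a 0–100
visual-analog scale. Besides the conventional simple mean, the analysis
summary is a weighted average whose weights are proportional to the
first principal-component loadings of the cohort item matrix. Defaults
and conventions:

* PCA on standardized items (correlation matrix) by default — scale-free
  and conventional; covariance-matrix PCA is a flag.
* Sign fix: loadings are negated if their sum is negative, so the
  summary correlates positively with the simple mean ("higher = more
  breakthrough").
* Loadings are rescaled to sum to one, keeping the summary on the item
  scale and directly comparable with the simple mean (with equal
  loadings the two coincide exactly).
* Fitting requires more respondents than items; a zero-variance item is
  an error under standardization (named in the message).

## Outcomes and exclusions

MADRS totals (0–60) are collected at baseline, the day after dosing and
weeks 1, 3, 6, 9, 12. Week-3 *responder*: week-3 score ≤ ½·baseline
(boundary inclusive, computed in integer arithmetic as
`2·score ≤ baseline`); *sustained responder*: the criterion holds at
weeks 3, 6, 9 and 12, undefined if any of the four is missing (and a
sustained responder is by construction a week-3 responder). Cohort
filters drop participants missing week 3 and participants whose baseline
is already in the normal range (default cutoff ≤ 6, the conventional
MADRS normal band; configurable since the exact cutoff used for such
exclusions is rarely stated). The sustained analysis additionally
requires weeks 6/9/12. Day-after and week-1 scores are stored but unused
by the models.

## Responder models

One row per retained participant: therapist arousal, therapist valence,
participant arousal, participant valence (each in [−1, 1]), the EBI PCA
summary (item scale), and treatment arm as two indicators with 1 mg as
reference — 7 slope parameters, matching a two-class ("multinomial")
logistic regression fit as ordinary binary logistic regression.

The fit is Newton–Raphson (equivalently IRLS) to gradient max-norm
< 1e-8, with step halving only when the penalized log-likelihood
worsens beyond float tolerance (1e-9 relative — near the optimum the
surface is flat to machine precision and strict monotone damping stalls
the final step). Features enter on their natural scales (no
standardization by default). Quasi-separation — expected in
leave-one-out refits of small cohorts with strong predictors — is
detected two ways: a slope walking past a threshold (default 30) while
the likelihood still climbs, or a converged fit in which every
observation is predicted with near-certainty in its own class
(max |y − μ| < 1e-4). Either triggers a ridge refit (λ = 1e-4, intercept
unpenalized) with a warning. Diagnostics: McFadden pseudo-R²
(1 − LL/LL₀; the variant standard logistic summaries print), LR
chi-square 2(LL − LL₀) with df = number of slopes, and its χ² p-value.
The fit is cross-checked against an independent maximum-likelihood
implementation in the test suite.

Class-probability densities (the separability picture) use a Gaussian
KDE per outcome class on a 256-point grid over [0, 1], Scott's-rule
bandwidth with a 0.01 floor (degenerate inputs stay well-defined), and
reflection at 0 and 1 so each density integrates to 1 on the unit
interval despite probability mass piling up near the boundaries.

## Evaluation

* **LOOCV**: n refits, each predicting the held participant. The EBI PCA
  weights (and any standardization statistics) are refit inside every
  training fold — the held-out participant never influences their own
  summary. Folds whose training labels collapse to one class are
  recorded as failed and excluded from pooled metrics.
* **Threshold metrics**: positive iff out-of-fold probability ≥ 0.5
  (neutral default; configurable). Accuracy, F1, and MCC with the
  zero-denominator convention MCC = 0.
* **ROC/AUC**: all distinct thresholds, trapezoid rule; tied scores step
  diagonally, making the AUC equal the tie-corrected pairwise
  concordance probability (asserted against a brute-force oracle in the
  tests). Pooled out-of-fold probabilities give one curve per model;
  per-dose rows subset the same pooled probabilities rather than
  refitting per arm (their confusion counts then sum to the pooled
  row's). A one-class subgroup keeps threshold metrics but omits AUC.
* **Bootstrap AUC CI**: percentile 2.5/97.5 over participant-level
  resamples with replacement (the "simple bootstrap"); resamples missing
  a class are redrawn; bit-reproducible given the seed. Resampling the
  (probability, label) pairs — not re-running LOOCV per resample — is
  the deliberate default.
* **Univariate panel**: Pearson r of each predictor against the week-3
  MADRS change, p from the exact t transform with n−2 df; dose enters as
  numeric mg (ordinal 0/1/2 coding available).

## Synthetic cohorts

The generator's latent mode encodes the working interpretation that the
predictors and the outcome are expressions of one underlying process: a
latent breakthrough variable `B ~ N(dose_shift, 1)` drives

* EBI items: `clip(45 + 18·B + N(0, 20), 0, 100)` per item;
* session-sentiment targets: `clip(offset + 0.15·B + N(0, 0.09), ±0.55)`
  (therapist loadings attenuated ×0.6);
* fractional MADRS reduction per week:
  `ramp_w·(0.32 + 0.18·B + persistent) + weekly`, with a persistent
  participant-level deviation (sd 0.10) plus week-to-week jitter
  (sd 0.05) — most noise must persist across visits or sustained
  response becomes vanishingly rare; scores are integer-rounded and
  clipped to [0, 60], baselines uniform on 20–40, visits dropped
  completely at random (≈2–5% per week).

With dose shifts (0, 0.1, 0.95) for (1, 10, 25) mg these defaults put
the cohort in the intended operating regime: ~20/25/50% week-3
responders by arm, ~15–40% sustained, LOOCV AUC ≈ 0.85–0.92 and
pseudo-R² ≈ 0.45–0.6 at n = 101. `null_config()` (no latent or dose
effect, base reduction at the 50% boundary) yields label noise — LOOCV
AUC ≈ 0.5; `strong_signal_config()` tightens every noise term so the
latent driver separates the classes by roughly three standard
deviations — LOOCV AUC ≥ 0.93 in practice.

Synthetic transcripts are built from the same lexicon the deterministic
backend matches. For a target (v, a) the generator solves for per-label
term counts whose smoothed lexicon score equals the target — the target
is expressed over the two anchors adjacent in angle, any remainder
spread uniformly (contributing zero by symmetry) — then samples each
utterance's counts from a multinomial around that mixture and renders
them as templated dialog turns. At the default 80 terms per utterance
the attainable region is the hull scaled by 80/88 ≈ 0.91; targets whose
best attainable score deviates more than 0.12 componentwise raise an
error, and planted targets round-trip through
segment → classify → average to within ±0.03 in practice (tolerance
±0.1).

The **planted-coefficient mode** exists for estimator checks rather than
realism: features are drawn independently on a small grid of replicated
patterns (two-point sentiments ±0.9, two-point EBI level 5/95, three
arms) and labels follow the planted logistic model with *balanced
randomization* — each identical-feature group receives the
largest-remainder-rounded share of its expected responders, assigned at
random within the group. The marginal law `E[y|x] = σ(β'x)` is
unchanged, but the binomial noise in the sufficient statistics is
suppressed, so coefficient-recovery checks measure the fitter, not label
luck: with the default planted coefficients (chosen to equalize
per-coefficient Fisher information), full-data fits at n = 2000 recover
every sign and land within ~7% of every magnitude across seeds. Under
fully independent labels the same check has an irreducible ~15–20%
failure rate at this n — the max over eight ~2σ quantities — which is a
property of the noise, not the estimator.

What the generator does **not** emulate: real clinical language (the
transcripts are lexicon salads around templated openers), rater
behaviour and blinding, informative missingness, item-level EBI
structure beyond one factor, therapist effects, or site effects.
Passing tests therefore demonstrate that the pipeline's statistics
behave correctly under the assumed dependence structure — not that the
sentiment model extracts signal from real dialog.

## Problem sizes and determinism

Tests and the acceptance script use cohorts of 100–200 participants for
cross-validation checks, n = 2000 for coefficient recovery, 1000–2000
bootstrap replicates, and 200 replicates for CI coverage — sizes at
which each check runs in seconds while leaving its statistical margin
intact. Every stochastic component takes an explicit seed
(`numpy.random.default_rng`); pipeline outputs embed config hash and
seeds, and identical configs reproduce identical files byte for byte.

## Known limitations

* The exact label phrases, hypothesis template and any post-scaling of
  the original zero-shot sentiment model are not public; the circumplex
  centroid construction here is a faithful, configurable realization,
  not a numeric replica — label sets and templates are config.
* The lexicon backend is intentionally crude (term counting); it exists
  to make the pipeline deterministic and testable, not to rival the NLI
  backend.
* Percentile bootstrap CIs are first-order; no DeLong or BCa variants.
* LOOCV only; no k-fold or stratified variants.
* The normal-range baseline cutoff and the classification threshold are
  conventions exposed as configuration, and results at small n are
  sensitive to them.
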