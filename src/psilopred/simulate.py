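"""Synthetic cohorts with the dependence structure the analysis assumes.

A single latent "emotional breakthrough" variable ``B`` (standard normal,
shifted upward by dose) jointly drives three observables per participant:

* the session-sentiment targets realized as a synthetic dialog transcript,
* the eight EBI item values, and
* the fractional MADRS reduction at each follow-up week (hence the
  responder labels), with independent noise on every measure.

This mirrors the working interpretation that sentiment, emotional
breakthrough and clinical response are expressions of one underlying
process, and gives every pipeline stage a testable ground truth without
any clinical data.  An alternative *planted-coefficient* mode draws
independent features and Bernoulli labels from a known logistic model, for
coefficient-recovery and calibration checks.

Synthetic transcripts are built from the lexicon that the deterministic
scoring backend matches, so planted sentiment targets survive the full
segment→classify→average round trip (to within the granularity of the
Laplace-smoothed label distribution).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .ebi import EBIResponse, write_ebi_csv
from .lexicon import DEFAULT_LABELS, LEXICON
from .outcomes import MADRSSeries, write_madrs_csv
from .transcripts import (
    PARTICIPANT,
    THERAPIST,
    SessionTranscript,
    Turn,
    write_transcript,
)


class SimulationError(ValueError):
    pass


class UnreachableTargetError(SimulationError):
    """Sentiment target not attainable with the template bank and lexicon."""


@dataclass(frozen=True)
class CohortConfig:
    """Generating parameters of a synthetic cohort.

    Defaults emulate the trial regime the pipeline targets: ~100
    participants split 1:1:1 across 25/10/1 mg arms, baseline MADRS 20–40,
    roughly half the 25 mg arm and a fifth of the low-dose arms responding
    at week 3, and ~5% missing visits.
    """

    n_participants: int = 101
    dose_proportions: Mapping[int, float] = field(
        default_factory=lambda: {1: 1 / 3, 10: 1 / 3, 25: 1 / 3}
    )
    #: additive shift of the latent breakthrough B per arm
    dose_effect: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.0, 10: 0.1, 25: 0.95}
    )
    #: fractional MADRS reduction per unit of B
    latent_effect: float = 0.18
    #: mean fractional MADRS reduction at B = 0
    base_reduction: float = 0.32
    #: multiplier on the reduction at early assessments
    week_ramp: Mapping[int, float] = field(
        default_factory=lambda: {0: 0.8, 1: 0.9, 3: 1.0, 6: 1.0, 9: 1.0, 12: 1.0}
    )
    #: reduction-fraction noise: a persistent participant-level deviation
    #: plus independent week-to-week jitter (sustained response requires the
    #: criterion to hold at four visits, so most noise must persist)
    noise_sd: float = 0.05
    persistent_noise_sd: float = 0.10
    baseline_madrs_range: tuple[int, int] = (20, 40)
    missing_week_rates: Mapping[int, float] = field(
        default_factory=lambda: {0: 0.02, 1: 0.02, 3: 0.05, 6: 0.04, 9: 0.04, 12: 0.04}
    )
    # EBI: item = clip(base + scale·loading·B + noise, 0, 100)
    ebi_loading: float = 1.0
    ebi_base: float = 45.0
    ebi_scale: float = 18.0
    ebi_noise_sd: float = 20.0
    # sentiment targets: clip(offset + loading·B + noise, ±clip)
    sentiment_loading: float = 0.15
    sentiment_offsets: Mapping[str, float] = field(
        default_factory=lambda: {
            "participant_valence": 0.05,
            "participant_arousal": 0.00,
            "therapist_valence": 0.10,
            "therapist_arousal": 0.02,
        }
    )
    therapist_attenuation: float = 0.6
    sentiment_noise_sd: float = 0.09
    sentiment_clip: float = 0.55
    # transcript realization
    with_transcripts: bool = True
    n_utterances_per_role: int = 40
    terms_per_utterance: int = 80
    #: None → latent-variable labels; mapping feature→coefficient (keys:
    #: intercept, therapist_arousal, therapist_valence, participant_arousal,
    #: participant_valence, ebi_summary, dose_10, dose_25) → logistic labels
    planted_coefficients: Optional[Mapping[str, float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise SimulationError("n_participants must be >= 1")
        if abs(sum(self.dose_proportions.values()) - 1.0) > 1e-9:
            raise SimulationError("dose proportions must sum to 1")
        for w, r in self.missing_week_rates.items():
            if not (0.0 <= r <= 1.0):
                raise SimulationError(f"missing rate for week {w} outside [0, 1]")
        lo, hi = self.baseline_madrs_range
        if not (0 <= lo <= hi <= 60):
            raise SimulationError("baseline range must lie within [0, 60]")


@dataclass
class SyntheticParticipant:
    participant_id: str
    dose_mg: int
    latent_b: float
    sentiment_targets: dict[str, float]
    transcript: Optional[SessionTranscript]
    ebi: EBIResponse
    madrs: MADRSSeries
    true_probability: Optional[float] = None  # planted-coefficient mode only


# ---------------------------------------------------------------------------
# transcript generation


_ANCHORS = np.array(
    [(l.valence_anchor, l.arousal_anchor) for l in DEFAULT_LABELS]
)
_LABEL_NAMES = [l.label_text for l in DEFAULT_LABELS]

_OPENERS = {
    PARTICIPANT: ("I feel", "Today I am", "Right now I feel", "It left me"),
    THERAPIST: ("It sounds like you feel", "I hear that you are",
                "You seem", "That sounds"),
}


def _mixture_for_target(
    valence: float, arousal: float, n_terms: int, tol: float
) -> np.ndarray:
    """Per-label expected term counts whose lexicon score hits the target.

    With Laplace-1 smoothing over K labels the score of an utterance with
    per-label term counts ``m`` is ``Σ m·anchor / (K + Σm)`` (the uniform
    smoothing mass cancels because the anchors sum to zero).  We therefore
    need mixture weights ``q`` over anchors with ``Σ q·anchor = u`` where
    ``u = target·(K + M)/M``; ``u`` is expressed with the two anchors
    adjacent in angle.  Targets whose best achievable score deviates more
    than ``tol`` componentwise are rejected.
    """
    k = len(_ANCHORS)
    m_total = float(n_terms)
    target = np.array([valence, arousal])
    u = target * (k + m_total) / m_total
    radius = float(np.hypot(*u))
    if radius < 1e-12:
        return np.full(k, m_total / k)
    angle = math.atan2(u[1], u[0])
    # anchors are at 45° spacing starting from 0 (happy); find bracketing pair
    step = math.pi / 4
    j = int(math.floor(angle / step)) % k
    order = [0, 1, 2, 3, 4, 5, 6, 7]  # DEFAULT_LABELS is already angle-ordered
    a1 = _ANCHORS[order[j]]
    a2 = _ANCHORS[order[(j + 1) % k]]
    # solve u = w1·a1 + w2·a2 (2×2 system); scale back if outside the hull
    mat = np.column_stack([a1, a2])
    w = np.linalg.solve(mat, u)
    w = np.clip(w, 0.0, None)
    scale = w.sum()
    if scale > 1.0:
        w = w / scale  # radial projection onto the chord (hull boundary)
    counts = np.zeros(k)
    counts[order[j]] = w[0] * m_total
    counts[order[(j + 1) % k]] = w[1] * m_total
    # uniform remainder contributes zero to the score
    counts += (m_total - counts.sum()) / k
    achieved = counts @ _ANCHORS / (k + m_total)
    if np.max(np.abs(achieved - target)) > tol:
        raise UnreachableTargetError(
            f"target ({valence:+.3f}, {arousal:+.3f}) unreachable: best "
            f"achievable ({achieved[0]:+.3f}, {achieved[1]:+.3f})"
        )
    return counts


def generate_transcript(
    target_valence: float,
    target_arousal: float,
    n_utterances_per_role: int = 40,
    seed: int | np.random.Generator = 0,
    therapist_targets: Optional[tuple[float, float]] = None,
    terms_per_utterance: int = 80,
    session_id: str = "synthetic",
    participant_id: str = "synthetic",
    reach_tol: float = 0.12,
) -> SessionTranscript:
    """Synthetic dialog whose lexicon-scored session means hit the targets.

    Each utterance samples its per-label term counts from a multinomial
    around the target mixture, so utterance scores scatter around the
    target and their mean converges to it.  Raises
    :class:`UnreachableTargetError` when a target lies too far outside
    what the smoothed lexicon score can express.
    """
    for t in (target_valence, target_arousal):
        if not (-1.0 <= t <= 1.0):
            raise SimulationError(f"target {t} outside [-1, 1]")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if therapist_targets is None:
        therapist_targets = (target_valence, target_arousal)
    mixtures = {
        PARTICIPANT: _mixture_for_target(
            target_valence, target_arousal, terms_per_utterance, reach_tol
        ),
        THERAPIST: _mixture_for_target(
            therapist_targets[0], therapist_targets[1], terms_per_utterance, reach_tol
        ),
    }

    def make_utterance(role: str) -> str:
        q = mixtures[role] / mixtures[role].sum()
        counts = rng.multinomial(terms_per_utterance, q)
        words: list[str] = []
        for label, count in zip(_LABEL_NAMES, counts):
            terms = LEXICON[label]
            words.extend(terms[i] for i in rng.integers(0, len(terms), count))
        perm = rng.permutation(len(words))
        opener = _OPENERS[role][rng.integers(0, len(_OPENERS[role]))]
        return f"{opener} " + " ".join(words[i] for i in perm) + "."

    turns: list[Turn] = []
    remaining = {PARTICIPANT: n_utterances_per_role, THERAPIST: n_utterances_per_role}
    role = THERAPIST
    while remaining[PARTICIPANT] > 0 or remaining[THERAPIST] > 0:
        if remaining[role] == 0:
            role = PARTICIPANT if role == THERAPIST else THERAPIST
        per_turn = int(min(remaining[role], 1 + rng.integers(0, 3)))
        text = " ".join(make_utterance(role) for _ in range(per_turn))
        turns.append(Turn(role, text, index=len(turns)))
        remaining[role] -= per_turn
        role = PARTICIPANT if role == THERAPIST else THERAPIST
    return SessionTranscript(session_id, participant_id, turns)


# ---------------------------------------------------------------------------
# cohort generation


def _draw_doses(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    doses = sorted(config.dose_proportions)
    props = np.array([config.dose_proportions[d] for d in doses])
    # deterministic 1:1:1-style allocation: largest-remainder, then shuffle
    counts = np.floor(props * config.n_participants).astype(int)
    remainder = config.n_participants - counts.sum()
    frac = props * config.n_participants - counts
    for i in np.argsort(-frac)[:remainder]:
        counts[i] += 1
    assigned = np.repeat(doses, counts)
    rng.shuffle(assigned)
    return assigned


def _madrs_from_reduction(
    baseline: int,
    b: float,
    dose: int,
    config: CohortConfig,
    rng: np.random.Generator,
) -> dict[int, int]:
    scores = {}
    person_shift = rng.normal(0.0, config.persistent_noise_sd)
    for week, ramp in config.week_ramp.items():
        frac = ramp * (config.base_reduction + config.latent_effect * b + person_shift)
        frac = frac + rng.normal(0.0, config.noise_sd)
        frac = min(max(frac, 0.0), 0.98)
        score = int(round(baseline * (1.0 - frac)))
        scores[week] = min(max(score, 0), 60)
    return scores


def _apply_missingness(
    scores: dict[int, int], config: CohortConfig, rng: np.random.Generator
) -> dict[int, int]:
    out = {}
    for week, score in scores.items():
        if rng.random() >= config.missing_week_rates.get(week, 0.0):
            out[week] = score
    return out


#: Planted logistic model for coefficient-recovery checks.  Effect sizes
#: equalize per-coefficient Fisher information given the planted feature
#: spreads, which maximizes identifiability at moderate cohort sizes.
PLANTED_DEFAULT: Mapping[str, float] = {
    "intercept": -3.8,
    "therapist_arousal": 1.5,
    "therapist_valence": 1.5,
    "participant_arousal": 1.5,
    "participant_valence": 1.5,
    "ebi_summary": 1.5 / 45.0,
    "dose_10": 3.2,
    "dose_25": 3.2,
}

_SENT_KEYS = (
    "therapist_arousal",
    "therapist_valence",
    "participant_arousal",
    "participant_valence",
)


def _madrs_for_label(
    baseline: int,
    responder: bool,
    config: CohortConfig,
    rng: np.random.Generator,
) -> dict[int, int]:
    """MADRS trajectory consistent with a planted responder label."""
    frac3 = rng.uniform(0.55, 0.85) if responder else rng.uniform(0.10, 0.40)
    scores = {}
    for week in config.week_ramp:
        f = frac3 + rng.normal(0.0, 0.03)
        score = int(round(baseline * (1.0 - f)))
        if responder:
            score = min(score, baseline // 2)
        else:
            score = max(score, baseline // 2 + 1)
        scores[week] = min(max(score, 0), 60)
    return scores


def _generate_planted(config: CohortConfig, rng: np.random.Generator):
    """Planted-coefficient cohort with balanced label randomization.

    Features live on a small grid of replicated patterns (two-point
    sentiments ±0.9, two-point EBI level 5/95, three dose arms) and each
    pattern group receives its expected number of responders (largest-
    remainder rounding of n·p, randomized within the group).  This removes
    the binomial noise a fully independent label draw would add, so
    coefficient-recovery checks probe the estimator rather than label luck.
    """
    planted = dict(config.planted_coefficients)  # type: ignore[arg-type]
    n = config.n_participants
    doses = _draw_doses(config, rng)
    sent = rng.choice([-0.9, 0.9], size=(n, len(_SENT_KEYS)))
    ebi_level = rng.choice([5.0, 95.0], size=n)
    eta = np.full(n, planted.get("intercept", 0.0))
    for j, key in enumerate(_SENT_KEYS):
        eta += planted.get(key, 0.0) * sent[:, j]
    eta += planted.get("ebi_summary", 0.0) * ebi_level
    eta += planted.get("dose_10", 0.0) * (doses == 10)
    eta += planted.get("dose_25", 0.0) * (doses == 25)
    prob = 1.0 / (1.0 + np.exp(-eta))

    # balanced allocation of responders within identical-pattern groups
    pattern = np.column_stack([sent, ebi_level, doses])
    _, inverse = np.unique(pattern, axis=0, return_inverse=True)
    y = np.zeros(n, dtype=bool)
    for g in np.unique(inverse):
        idx = np.nonzero(inverse == g)[0]
        expected = len(idx) * prob[idx[0]]
        k = int(np.floor(expected))
        if rng.random() < expected - k:
            k += 1
        y[rng.choice(idx, size=min(k, len(idx)), replace=False)] = True

    lo, hi = config.baseline_madrs_range
    participants = []
    for i in range(n):
        pid = f"S{i + 1:04d}"
        targets = {key: float(sent[i, j]) for j, key in enumerate(_SENT_KEYS)}
        ebi = EBIResponse(pid, tuple([float(ebi_level[i])] * 8))
        baseline = int(rng.integers(lo, hi + 1))
        scores = _apply_missingness(
            _madrs_for_label(baseline, bool(y[i]), config, rng), config, rng
        )
        participants.append(
            SyntheticParticipant(
                participant_id=pid,
                dose_mg=int(doses[i]),
                latent_b=float("nan"),
                sentiment_targets=targets,
                transcript=None,
                ebi=ebi,
                madrs=MADRSSeries(pid, baseline, scores, dose_mg=int(doses[i])),
                true_probability=float(prob[i]),
            )
        )
    return participants


def generate_cohort(config: CohortConfig) -> list[SyntheticParticipant]:
    """Draw a full synthetic cohort; deterministic given ``config.seed``.

    Latent mode (default) ties sentiment, EBI and outcome together through
    the breakthrough variable ``B``; planted mode (``planted_coefficients``
    set) draws independent features and labels from the given logistic
    model and never realizes transcripts.
    """
    rng = np.random.default_rng(config.seed)
    if config.planted_coefficients is not None:
        return _generate_planted(config, rng)

    doses = _draw_doses(config, rng)
    lo, hi = config.baseline_madrs_range
    participants: list[SyntheticParticipant] = []

    for i in range(config.n_participants):
        pid = f"S{i + 1:04d}"
        dose = int(doses[i])
        b = rng.normal(config.dose_effect.get(dose, 0.0), 1.0)

        targets: dict[str, float] = {}
        for key, offset in config.sentiment_offsets.items():
            loading = config.sentiment_loading
            if key.startswith("therapist"):
                loading *= config.therapist_attenuation
            value = offset + loading * b + rng.normal(0.0, config.sentiment_noise_sd)
            targets[key] = float(
                np.clip(value, -config.sentiment_clip, config.sentiment_clip)
            )

        level = config.ebi_base + config.ebi_scale * config.ebi_loading * b
        items = np.clip(level + rng.normal(0.0, config.ebi_noise_sd, 8), 0.0, 100.0)
        ebi = EBIResponse(pid, tuple(float(v) for v in items))

        baseline = int(rng.integers(lo, hi + 1))
        scores = _apply_missingness(
            _madrs_from_reduction(baseline, b, dose, config, rng), config, rng
        )
        madrs = MADRSSeries(pid, baseline, scores, dose_mg=dose)

        transcript = None
        if config.with_transcripts:
            transcript = generate_transcript(
                targets["participant_valence"],
                targets["participant_arousal"],
                n_utterances_per_role=config.n_utterances_per_role,
                seed=rng,
                therapist_targets=(
                    targets["therapist_valence"],
                    targets["therapist_arousal"],
                ),
                terms_per_utterance=config.terms_per_utterance,
                session_id=f"{pid}-integration1",
                participant_id=pid,
            )

        participants.append(
            SyntheticParticipant(
                participant_id=pid,
                dose_mg=dose,
                latent_b=float(b),
                sentiment_targets=targets,
                transcript=transcript,
                ebi=ebi,
                madrs=madrs,
                true_probability=None,
            )
        )
    return participants


def null_config(n_participants: int = 200, seed: int = 0, **overrides) -> CohortConfig:
    """Cohort with no feature–outcome link: labels are pure noise.

    ``base_reduction`` is raised to 0.5 so the coin lands near the 50%
    responder boundary and both classes stay populated.
    """
    kwargs = dict(
        n_participants=n_participants,
        latent_effect=0.0,
        dose_effect={1: 0.0, 10: 0.0, 25: 0.0},
        base_reduction=0.5,
        seed=seed,
    )
    kwargs.update(overrides)
    return CohortConfig(**kwargs)


def strong_signal_config(
    n_participants: int = 100, seed: int = 0, **overrides
) -> CohortConfig:
    """High signal-to-noise regime: the latent driver dominates all noise.

    Tightened noise terms put roughly three latent standard deviations
    between the feature means of the two outcome classes, the regime in
    which the pipeline should discriminate almost perfectly.
    """
    kwargs = dict(
        n_participants=n_participants,
        latent_effect=0.22,
        base_reduction=0.36,
        noise_sd=0.03,
        persistent_noise_sd=0.04,
        ebi_noise_sd=8.0,
        sentiment_noise_sd=0.03,
        sentiment_loading=0.24,
        missing_week_rates={0: 0.0, 1: 0.0, 3: 0.0, 6: 0.0, 9: 0.0, 12: 0.0},
        seed=seed,
    )
    kwargs.update(overrides)
    return CohortConfig(**kwargs)


def cohort_features(
    participants: Sequence[SyntheticParticipant],
    outcome: str = "week3",
):
    """Model inputs straight from a cohort's planted sentiment targets.

    Bypasses transcript realization/scoring (the targets stand in for the
    session means), which is what coefficient-recovery and LOOCV
    calibration checks need.  Returns ``(features_frame, labels,
    ebi_items)`` with participants lacking a defined label dropped.
    """
    import pandas as pd

    from .ebi import ITEM_COLUMNS
    from .features import encode_dose
    from .outcomes import responder_week3, sustained_responder

    label_fn = responder_week3 if outcome == "week3" else sustained_responder
    rows, labels, items = [], [], []
    for p in participants:
        label = label_fn(p.madrs)
        if label is None:
            continue
        d10, d25 = encode_dose(p.dose_mg)
        rows.append(
            {
                "participant_id": p.participant_id,
                "therapist_arousal": p.sentiment_targets["therapist_arousal"],
                "therapist_valence": p.sentiment_targets["therapist_valence"],
                "participant_arousal": p.sentiment_targets["participant_arousal"],
                "participant_valence": p.sentiment_targets["participant_valence"],
                "dose_10": float(d10),
                "dose_25": float(d25),
                "dose_mg": p.dose_mg,
            }
        )
        labels.append(bool(label))
        items.append(dict(zip(ITEM_COLUMNS, p.ebi.items)))
    return pd.DataFrame(rows), labels, pd.DataFrame(items)


# ---------------------------------------------------------------------------
# on-disk emission (same formats the real pipeline reads)


def write_cohort(
    participants: Sequence[SyntheticParticipant],
    outdir: str | Path,
    config: Optional[CohortConfig] = None,
) -> dict[str, Path]:
    """Emit transcripts JSON, EBI CSV, MADRS CSV and a ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tdir = outdir / "transcripts"
    tdir.mkdir(exist_ok=True)
    for p in participants:
        if p.transcript is not None:
            write_transcript(p.transcript, tdir / f"{p.participant_id}.json")
    ebi_path = outdir / "ebi.csv"
    write_ebi_csv([p.ebi for p in participants], ebi_path)
    madrs_path = outdir / "madrs.csv"
    write_madrs_csv([p.madrs for p in participants], madrs_path)
    truth = {
        p.participant_id: {
            "dose_mg": p.dose_mg,
            "latent_b": p.latent_b,
            "sentiment_targets": p.sentiment_targets,
            "true_probability": p.true_probability,
        }
        for p in participants
    }
    truth_path = outdir / "ground_truth.json"
    payload: dict = {"participants": truth}
    if config is not None:
        cfg = asdict(config)
        cfg["dose_proportions"] = {str(k): v for k, v in cfg["dose_proportions"].items()}
        cfg["dose_effect"] = {str(k): v for k, v in cfg["dose_effect"].items()}
        cfg["week_ramp"] = {str(k): v for k, v in cfg["week_ramp"].items()}
        cfg["missing_week_rates"] = {
            str(k): v for k, v in cfg["missing_week_rates"].items()
        }
        payload["config"] = cfg
    truth_path.write_text(json.dumps(payload, indent=1), encoding="utf-8")
    return {
        "transcripts": tdir,
        "ebi": ebi_path,
        "madrs": madrs_path,
        "ground_truth": truth_path,
    }
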