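"""Synthetic cohort generator: determinism, planted structure, round trips."""

import numpy as np
import pytest

from psilopred.outcomes import responder_week3
from psilopred.sentiment import LexiconBackend, score_transcript, session_sentiment
from psilopred.simulate import (
    PLANTED_DEFAULT,
    CohortConfig,
    SimulationError,
    UnreachableTargetError,
    cohort_features,
    generate_cohort,
    generate_transcript,
    write_cohort,
)
from psilopred.transcripts import read_transcript, segment_utterances


def roundtrip_means(transcript):
    seg = segment_utterances(transcript, min_tokens=1)
    return session_sentiment(score_transcript(seg, backend=LexiconBackend()))


class TestGenerateTranscript:
    def test_deterministic_given_seed(self):
        t1 = generate_transcript(0.2, -0.1, n_utterances_per_role=10, seed=4)
        t2 = generate_transcript(0.2, -0.1, n_utterances_per_role=10, seed=4)
        assert [(a.speaker_role, a.text) for a in t1.turns] == [
            (a.speaker_role, a.text) for a in t2.turns
        ]

    @pytest.mark.parametrize("target", [(0.0, 0.0), (0.4, -0.3), (0.8, 0.5)])
    def test_targets_recovered_by_lexicon_scoring(self, target):
        t = generate_transcript(*target, n_utterances_per_role=50, seed=9)
        s = roundtrip_means(t)
        assert s.participant_valence == pytest.approx(target[0], abs=0.1)
        assert s.participant_arousal == pytest.approx(target[1], abs=0.1)
        assert s.therapist_valence == pytest.approx(target[0], abs=0.1)

    def test_both_roles_populated(self):
        t = generate_transcript(0.1, 0.1, n_utterances_per_role=8, seed=0)
        roles = {turn.speaker_role for turn in t.turns}
        assert roles == {"participant", "therapist"}

    def test_unreachable_target_rejected(self):
        with pytest.raises(UnreachableTargetError):
            generate_transcript(0.99, 0.99, n_utterances_per_role=10, seed=0)

    def test_out_of_range_target_rejected(self):
        with pytest.raises(SimulationError):
            generate_transcript(1.5, 0.0, seed=0)


class TestGenerateCohort:
    def test_deterministic(self):
        cfg = CohortConfig(n_participants=50, seed=7)
        c1, c2 = generate_cohort(cfg), generate_cohort(cfg)
        for a, b in zip(c1, c2):
            assert a.madrs == b.madrs
            assert a.ebi == b.ebi
            assert a.sentiment_targets == b.sentiment_targets
            assert [t.text for t in a.transcript.turns] == [t.text for t in b.transcript.turns]

    def test_dose_allocation_near_proportions(self):
        cohort = generate_cohort(CohortConfig(n_participants=99, with_transcripts=False))
        counts = {d: sum(p.dose_mg == d for p in cohort) for d in (1, 10, 25)}
        assert counts == {1: 33, 10: 33, 25: 33}

    def test_higher_dose_higher_responder_rate(self):
        cohort = generate_cohort(
            CohortConfig(n_participants=500, with_transcripts=False, seed=21)
        )
        rates = {}
        for d in (1, 25):
            labels = [
                responder_week3(p.madrs)
                for p in cohort
                if p.dose_mg == d and p.madrs.has_week(3)
            ]
            rates[d] = np.mean(labels)
        assert rates[25] > rates[1] + 0.15

    def test_latent_variable_links_features_and_outcome(self):
        cohort = generate_cohort(
            CohortConfig(n_participants=300, with_transcripts=False, seed=2)
        )
        b = np.array([p.latent_b for p in cohort])
        ebi_means = np.array([np.mean(p.ebi.items) for p in cohort])
        valence = np.array([p.sentiment_targets["participant_valence"] for p in cohort])
        assert np.corrcoef(b, ebi_means)[0, 1] > 0.5
        assert np.corrcoef(b, valence)[0, 1] > 0.5

    def test_missingness_rates_respected(self):
        cfg = CohortConfig(
            n_participants=800,
            with_transcripts=False,
            missing_week_rates={0: 0, 1: 0, 3: 0.2, 6: 0, 9: 0, 12: 0},
            seed=3,
        )
        cohort = generate_cohort(cfg)
        missing = np.mean([not p.madrs.has_week(3) for p in cohort])
        assert missing == pytest.approx(0.2, abs=0.04)

    def test_invalid_config_rejected(self):
        with pytest.raises(SimulationError):
            CohortConfig(n_participants=0)
        with pytest.raises(SimulationError):
            CohortConfig(dose_proportions={1: 0.5, 10: 0.2, 25: 0.2})

    def test_planted_mode_probabilities_match_features(self):
        cfg = CohortConfig(
            n_participants=200, planted_coefficients=PLANTED_DEFAULT, seed=5
        )
        cohort = generate_cohort(cfg)
        p = cohort[0]
        assert p.transcript is None
        eta = PLANTED_DEFAULT["intercept"]
        eta += sum(
            PLANTED_DEFAULT[k] * p.sentiment_targets[k]
            for k in (
                "therapist_arousal",
                "therapist_valence",
                "participant_arousal",
                "participant_valence",
            )
        )
        eta += PLANTED_DEFAULT["ebi_summary"] * np.mean(p.ebi.items)
        eta += PLANTED_DEFAULT["dose_10"] * (p.dose_mg == 10)
        eta += PLANTED_DEFAULT["dose_25"] * (p.dose_mg == 25)
        assert p.true_probability == pytest.approx(1 / (1 + np.exp(-eta)))

    def test_planted_labels_consistent_with_madrs(self):
        cfg = CohortConfig(
            n_participants=100,
            planted_coefficients=PLANTED_DEFAULT,
            seed=6,
            missing_week_rates={0: 0, 1: 0, 3: 0, 6: 0, 9: 0, 12: 0},
        )
        cohort = generate_cohort(cfg)
        # labels should track the planted probabilities on average
        probs = np.array([p.true_probability for p in cohort])
        labels = np.array([responder_week3(p.madrs) for p in cohort], dtype=float)
        assert labels.mean() == pytest.approx(probs.mean(), abs=0.1)


class TestWriteCohort:
    def test_emitted_files_readable_by_pipeline_readers(self, tmp_path):
        from psilopred.ebi import read_ebi_csv
        from psilopred.outcomes import read_madrs_csv

        cfg = CohortConfig(n_participants=12, seed=1, n_utterances_per_role=6)
        cohort = generate_cohort(cfg)
        paths = write_cohort(cohort, tmp_path / "cohort", cfg)
        transcripts = sorted(paths["transcripts"].glob("*.json"))
        assert len(transcripts) == 12
        t = read_transcript(transcripts[0], "json")
        assert t.participant_id == "S0001"
        assert len(read_ebi_csv(paths["ebi"])) == 12
        madrs = read_madrs_csv(paths["madrs"])
        assert [m.participant_id for m in madrs] == [p.participant_id for p in cohort]
        assert paths["ground_truth"].exists()

    def test_cohort_features_alignment(self):
        cohort = generate_cohort(
            CohortConfig(n_participants=40, with_transcripts=False, seed=8)
        )
        frame, labels, items = cohort_features(cohort)
        assert len(frame) == len(labels) == len(items)
        defined = [p for p in cohort if p.madrs.has_week(3)]
        assert len(frame) == len(defined)
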