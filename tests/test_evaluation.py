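"""Confusion metrics, ROC/AUC, bootstrap CIs, LOOCV, correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from psilopred.evaluation import (
    ConfusionMatrix,
    EvaluationError,
    bootstrap_auc_ci,
    confusion_at_threshold,
    loocv_probabilities,
    metrics,
    per_group_results,
    roc_auc,
    univariate_correlations,
)


def brute_force_metrics(tn, fp, fn, tp):
    n = tn + fp + fn + tp
    acc = (tp + tn) / n
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    return acc, mcc, f1


def concordance_auc(p, y):
    """Oracle: pairwise concordance probability with half credit for ties."""
    p, y = np.asarray(p, float), np.asarray(y, int)
    pos, neg = p[y == 1], p[y == 0]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return wins / (len(pos) * len(neg))


class TestConfusion:
    def test_basic_tally(self):
        cm = confusion_at_threshold([0.9, 0.1], [1, 0], 0.5)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (1, 1, 0, 0)

    def test_threshold_inclusive(self):
        cm = confusion_at_threshold([0.5, 0.5], [1, 0], 0.5)
        assert (cm.tp, cm.fp) == (1, 1)

    def test_matches_brute_force_tally(self, rng):
        p = rng.random(20)
        y = rng.integers(0, 2, 20)
        cm = confusion_at_threshold(p, y, 0.4)
        pred = p >= 0.4
        assert cm.tp == int(np.sum(pred & (y == 1)))
        assert cm.tn == int(np.sum(~pred & (y == 0)))
        assert cm.n == 20


class TestMetrics:
    def test_perfect_classifier(self):
        assert metrics(ConfusionMatrix(tn=10, fp=0, fn=0, tp=5)) == (1.0, 1.0, 1.0)

    def test_zero_denominator_mcc_convention(self):
        acc, mcc, f1 = metrics(ConfusionMatrix(tn=0, fp=0, fn=3, tp=7))
        assert mcc == 0.0

    def test_against_brute_force_many_matrices(self, rng):
        for _ in range(1000):
            tn, fp, fn, tp = rng.integers(0, 30, 4)
            if tn + fp + fn + tp == 0:
                continue
            got = metrics(ConfusionMatrix(int(tn), int(fp), int(fn), int(tp)))
            assert got == pytest.approx(brute_force_metrics(tn, fp, fn, tp), abs=1e-12)

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import accuracy_score, f1_score, matthews_corrcoef

        y = rng.integers(0, 2, 50)
        pred = rng.integers(0, 2, 50)
        cm = ConfusionMatrix(
            tn=int(np.sum((pred == 0) & (y == 0))),
            fp=int(np.sum((pred == 1) & (y == 0))),
            fn=int(np.sum((pred == 0) & (y == 1))),
            tp=int(np.sum((pred == 1) & (y == 1))),
        )
        acc, mcc, f1 = metrics(cm)
        assert acc == pytest.approx(accuracy_score(y, pred))
        assert mcc == pytest.approx(matthews_corrcoef(y, pred), abs=1e-12)
        assert f1 == pytest.approx(f1_score(y, pred), abs=1e-12)


class TestRocAuc:
    def test_perfect_ranking(self):
        _, _, auc = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == 1.0

    def test_all_tied_gives_half(self):
        fpr, tpr, auc = roc_auc([0.5] * 10, [0, 1] * 5)
        assert auc == pytest.approx(0.5)

    def test_curve_endpoints_and_monotonicity(self, rng):
        p = rng.random(50)
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        fpr, tpr, _ = roc_auc(p, y)
        assert fpr[0] == tpr[0] == 0.0
        assert fpr[-1] == tpr[-1] == 1.0
        assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)

    def test_equals_concordance_oracle_with_ties(self, rng):
        p = rng.integers(0, 5, 40) / 4  # heavy ties
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        _, _, auc = roc_auc(p, y)
        assert auc == pytest.approx(concordance_auc(p, y), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            roc_auc([0.1, 0.9], [1, 1])


class TestBootstrapCI:
    def test_deterministic_given_seed(self, rng):
        p = rng.random(60)
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        ci1 = bootstrap_auc_ci(p, y, reps=500, seed=7)
        ci2 = bootstrap_auc_ci(p, y, reps=500, seed=7)
        assert ci1 == ci2
        assert ci1 != bootstrap_auc_ci(p, y, reps=500, seed=8)

    def test_degenerate_perfect_separation(self):
        p = [0.1] * 10 + [0.9] * 10
        y = [0] * 10 + [1] * 10
        assert bootstrap_auc_ci(p, y, reps=200, seed=1) == (1.0, 1.0)

    def test_interval_brackets_point_auc(self, rng):
        p = rng.random(80)
        y = (rng.random(80) < 0.4).astype(int)
        y[:2] = [0, 1]
        lo, hi = bootstrap_auc_ci(p, y, reps=1000, seed=3)
        _, _, auc = roc_auc(p, y)
        assert lo <= auc <= hi

    def test_planted_signal_interval_narrow(self, rng):
        y = (rng.random(100) < 0.4).astype(int)
        p = np.clip(0.3 + 0.4 * y + rng.normal(0, 0.15, 100), 0, 1)
        lo, hi = bootstrap_auc_ci(p, y, reps=2000, seed=1)
        assert 0 < hi - lo < 0.3


class TestLoocv:
    @staticmethod
    def planted_frame(rng, n=60, signal=2.5):
        y = (rng.random(n) < 0.4).astype(int)
        x = rng.normal(0, 0.2, (n, 4)) + 0.15 * signal * y[:, None]
        frame = pd.DataFrame(
            np.clip(x, -1, 1),
            columns=[
                "therapist_arousal",
                "therapist_valence",
                "participant_arousal",
                "participant_valence",
            ],
        )
        frame["participant_id"] = [f"p{i}" for i in range(n)]
        return frame, y

    def test_one_probability_per_participant(self, rng):
        frame, y = self.planted_frame(rng, n=25)
        oof, failed = loocv_probabilities(frame, y)
        assert len(oof) == 25
        assert not failed
        assert np.all((oof >= 0) & (oof <= 1))

    def test_strong_signal_discriminates(self, rng):
        frame, y = self.planted_frame(rng, n=100, signal=3.0)
        oof, _ = loocv_probabilities(frame, y)
        _, _, auc = roc_auc(oof, y)
        assert auc >= 0.95

    def test_constant_model_accuracy_is_majority_fraction(self, rng):
        # intercept-only folds predict the training prevalence (<0.5), so
        # every prediction is 'non-responder' at threshold 0.5
        n = 40
        y = (np.arange(n) < 12).astype(int)  # 30% positive
        frame = pd.DataFrame(
            {
                "therapist_arousal": np.zeros(n),
                "therapist_valence": np.zeros(n),
                "participant_arousal": np.zeros(n),
                "participant_valence": np.zeros(n),
            }
        )
        oof, _ = loocv_probabilities(frame, y, regularization=1e-4)
        cm = confusion_at_threshold(oof, y, 0.5)
        acc, _, _ = metrics(cm)
        assert acc == pytest.approx(1 - y.mean(), abs=1e-12)

    def test_ebi_weights_refit_per_fold(self, rng):
        # an extreme held-out EBI row must not influence its own summary weights
        frame, y = self.planted_frame(rng, n=30)
        items = pd.DataFrame(
            rng.uniform(40, 60, (30, 8)), columns=[f"ebi_{i}" for i in range(1, 9)]
        )
        items.iloc[0] = [0, 100, 0, 100, 0, 100, 0, 100]
        oof, failed = loocv_probabilities(frame, y, ebi_items=items)
        assert not failed
        assert np.all(np.isfinite(oof))


class TestPerGroup:
    def make_cv(self, rng, n=60):
        from psilopred.evaluation import CVResult

        p = rng.random(n)
        y = rng.integers(0, 2, n)
        y[:2] = [0, 1]
        doses = np.repeat([1, 10, 25], n // 3)
        cm = confusion_at_threshold(p, y, 0.5)
        acc, mcc, f1 = metrics(cm)
        fpr, tpr, auc = roc_auc(p, y)
        return CVResult(
            participant_ids=[str(i) for i in range(n)],
            probabilities=p,
            labels=np.asarray(y),
            doses=doses,
            threshold=0.5,
            confusion=cm,
            accuracy=acc,
            mcc=mcc,
            f1=f1,
            auc=auc,
            roc_fpr=fpr,
            roc_tpr=tpr,
        )

    def test_four_rows_and_conservation(self, rng):
        cv = self.make_cv(rng)
        table = per_group_results(cv, "Week 3")
        assert list(table.Group) == ["ALL", "1 mg", "10 mg", "25 mg"]
        assert table[table.Group != "ALL"].N.sum() == table[table.Group == "ALL"].N.iloc[0]

    def test_subset_metrics_match_brute_force(self, rng):
        cv = self.make_cv(rng)
        table = per_group_results(cv, "m")
        sub = cv.doses == 10
        cm = confusion_at_threshold(cv.probabilities[sub], cv.labels[sub], 0.5)
        acc, mcc, f1 = metrics(cm)
        row = table[table.Group == "10 mg"].iloc[0]
        assert row.Accuracy == pytest.approx(acc)
        assert row.MCC == pytest.approx(mcc)
        assert row.f1 == pytest.approx(f1)

    def test_single_class_group_omits_auc(self, rng):
        cv = self.make_cv(rng)
        cv.labels[cv.doses == 1] = 0
        cm = confusion_at_threshold(cv.probabilities, cv.labels, 0.5)
        table = per_group_results(cv, "m")
        row = table[table.Group == "1 mg"].iloc[0]
        assert np.isnan(row.AUC)
        assert np.isfinite(row.Accuracy)


class TestUnivariateCorrelations:
    def frame(self, rng, n=10):
        f = pd.DataFrame(
            rng.uniform(-1, 1, (n, 4)),
            columns=[
                "therapist_arousal",
                "therapist_valence",
                "participant_arousal",
                "participant_valence",
            ],
        )
        f["ebi_summary"] = rng.uniform(0, 100, n)
        f["dose_mg"] = rng.choice([1, 10, 25], n)
        return f

    def test_self_correlation(self, rng):
        f = self.frame(rng)
        out = univariate_correlations(f, f["ebi_summary"])
        assert out[out.feature == "ebi_summary"].r.iloc[0] == pytest.approx(1.0)

    def test_anti_correlation(self, rng):
        f = self.frame(rng)
        out = univariate_correlations(f, -f["participant_valence"])
        assert out[out.feature == "participant_valence"].r.iloc[0] == pytest.approx(-1.0)

    def test_matches_covariance_formula(self, rng):
        f = self.frame(rng)
        y = rng.normal(size=10)
        out = univariate_correlations(f, y)
        x = f["therapist_arousal"].to_numpy()
        r_manual = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert out[out.feature == "therapist_arousal"].r.iloc[0] == pytest.approx(
            r_manual, abs=1e-12
        )

    def test_p_value_from_t_distribution(self, rng):
        f = self.frame(rng, n=20)
        y = rng.normal(size=20)
        out = univariate_correlations(f, y)
        row = out[out.feature == "participant_arousal"].iloc[0]
        t = row.r * np.sqrt(18 / (1 - row.r**2))
        assert row.p == pytest.approx(2 * stats.t.sf(abs(t), 18), rel=1e-9)

    def test_zero_variance_rejected(self, rng):
        f = self.frame(rng)
        f["ebi_summary"] = 50.0
        with pytest.raises(EvaluationError, match="zero-variance"):
            univariate_correlations(f, rng.normal(size=10))
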