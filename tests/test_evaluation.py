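"""Cross-validation schemes, confusion metrics, ROC/AUC and the DeLong test."""

import numpy as np
import pytest
from scipy import stats

import helpers
from vbmsvm import (
    auc_mann_whitney,
    confusion_metrics,
    delong_compare,
    loo_cv,
    roc_curve,
    split_half_validation,
)


def _clusters(rng, n=10, p=5, gap=6.0):
    y = np.r_[np.ones(n), -np.ones(n)]
    X = rng.normal(size=(2 * n, p))
    X[:, 0] += y * gap
    return X, y


class TestLOO:
    def test_separated_clusters_perfect(self, rng):
        X, y = _clusters(rng)
        cv = loo_cv(X, y)
        assert cv.accuracy == 1.0
        assert len(cv.scores) == len(y)
        assert np.array_equal(np.unique(cv.fold_id), np.arange(len(y)))

    def test_shortcut_equals_naive(self, rng):
        X, y = helpers.random_separable_problem(rng, n=24, p=50, margin=0.8)
        fast = loo_cv(X, y, shortcut=True)
        naive = loo_cv(X, y, shortcut=False)
        np.testing.assert_array_equal(fast.y_pred, naive.y_pred)
        np.testing.assert_allclose(fast.scores, naive.scores, atol=1e-6)

    def test_null_accuracy_near_half(self):
        accs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(40, 100))
            y = np.r_[np.ones(20), -np.ones(20)]
            accs.append(loo_cv(X, y).accuracy)
        assert abs(np.mean(accs) - 0.5) < 0.07

    def test_accuracy_is_mean_correctness(self, rng):
        X, y = helpers.random_separable_problem(rng, n=16, p=30, margin=0.3)
        cv = loo_cv(X, y)
        assert cv.accuracy == pytest.approx(np.mean(cv.y_pred == cv.y_true))

    def test_too_small_rejected(self, rng):
        with pytest.raises(ValueError):
            loo_cv(rng.normal(size=(3, 2)), [1, -1, 1])

    def test_foldwise_covariates_leakage_modes(self, rng):
        X, y = _clusters(rng, n=8, gap=8.0)
        cov = rng.normal(size=(16, 2))
        for leakage in ("foldwise", "pooled"):
            cv = loo_cv(X, y, covariates=cov, leakage=leakage)
            assert cv.details["leakage"] == leakage
            assert len(cv.scores) == 16
        with pytest.raises(ValueError, match="leakage"):
            loo_cv(X, y, covariates=cov, leakage="nope")

    def test_removing_group_confound_reduces_accuracy(self, rng):
        """When the only group signal is a covariate-driven global offset,
        fold-wise residualisation on that covariate removes it."""
        n = 12
        y = np.r_[np.ones(n), -np.ones(n)]
        conf = y * 2.0 + rng.normal(scale=0.5, size=2 * n)
        X = rng.normal(size=(2 * n, 40)) + conf[:, None]
        plain = loo_cv(X, y)
        adjusted = loo_cv(X, y, covariates=conf, leakage="foldwise")
        assert plain.accuracy > 0.9
        assert adjusted.accuracy < plain.accuracy


class TestSplitHalf:
    def test_counts_and_determinism(self, rng):
        X, y = _clusters(rng, n=20)
        a = split_half_validation(X, y, n_train_case=10, n_train_control=9, seed=5)
        assert len(a.scores) == 40 - 19
        b = split_half_validation(X, y, n_train_case=10, n_train_control=9, seed=5)
        np.testing.assert_array_equal(a.scores, b.scores)
        assert a.subject_ids == b.subject_ids
        c = split_half_validation(X, y, n_train_case=10, n_train_control=9, seed=6)
        assert not np.array_equal(np.sort(a.subject_ids), np.sort(c.subject_ids)) or (
            not np.allclose(a.scores, c.scores)
        )

    def test_counts_exceeding_group_rejected(self, rng):
        X, y = _clusters(rng, n=5)
        with pytest.raises(ValueError, match="exceed"):
            split_half_validation(X, y, n_train_case=6, n_train_control=3)

    def test_full_groups_give_empty_test_set(self, rng):
        X, y = _clusters(rng, n=5)
        with pytest.raises(ValueError, match="empty test set"):
            split_half_validation(X, y, n_train_case=5, n_train_control=5)


class TestConfusionMetrics:
    def test_reference_study_counts(self):
        """67 true positives / 7 false negatives / 65 true negatives /
        4 false positives give the printed sensitivity, specificity and
        132/143 accuracy."""
        y_true = np.r_[np.ones(74), -np.ones(69)]
        y_pred = np.r_[np.ones(67), -np.ones(7), -np.ones(65), np.ones(4)]
        m = confusion_metrics(y_true, y_pred)
        assert (m.tp, m.fn, m.tn, m.fp) == (67, 7, 65, 4)
        assert m.sensitivity == pytest.approx(0.9054, abs=5e-5)
        assert m.specificity == pytest.approx(0.9420, abs=5e-5)
        assert m.accuracy == pytest.approx(132 / 143)

    def test_all_correct(self):
        m = confusion_metrics([1, -1], [1, -1])
        assert (m.accuracy, m.sensitivity, m.specificity) == (1.0, 1.0, 1.0)

    def test_all_predicted_control(self):
        m = confusion_metrics([1, 1, -1], [-1, -1, -1])
        assert m.sensitivity == 0.0 and m.specificity == 1.0

    def test_empty_class_flagged(self):
        m = confusion_metrics([1, 1], [1, -1])
        assert "specificity" in m.undefined and np.isnan(m.specificity)


class TestAUC:
    def test_perfect_and_quarter(self):
        assert auc_mann_whitney([1, 2, 3, 4], [-1, -1, 1, 1]) == 1.0
        assert auc_mann_whitney([1, 2, 3, 4], [1, -1, 1, -1]) == 0.25

    def test_all_tied_is_half(self):
        assert auc_mann_whitney([2, 2, 2, 2], [1, -1, 1, -1]) == 0.5

    def test_matches_pairwise_oracle(self, rng):
        for _ in range(30):
            n = rng.integers(4, 30)
            scores = rng.integers(0, 10, size=n).astype(float)  # many ties
            labels = np.where(rng.uniform(size=n) < 0.5, 1, -1)
            labels[:2] = [1, -1]
            assert auc_mann_whitney(scores, labels) == pytest.approx(
                helpers.auc_pairwise(scores, labels), abs=1e-10
            )

    def test_invariant_to_monotone_transform(self, rng):
        scores = rng.normal(size=30)
        labels = np.where(rng.uniform(size=30) < 0.5, 1, -1)
        labels[:2] = [1, -1]
        a = auc_mann_whitney(scores, labels)
        b = auc_mann_whitney(np.exp(3 * scores) + 7, labels)
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_mann_whitney([1.0, 2.0], [1, 1])


class TestROC:
    def test_perfect_curve_through_corner(self):
        roc = roc_curve([3.0, 2.0, 1.0, 0.0], [1, 1, -1, -1])
        assert roc.auc == 1.0
        assert any((f == 0.0 and t == 1.0) for f, t in zip(roc.fpr, roc.tpr))

    def test_anti_separating(self):
        roc = roc_curve([0.0, 1.0, 2.0, 3.0], [1, 1, -1, -1])
        assert roc.auc == 0.0
        assert any((f == 1.0 and t == 0.0) for f, t in zip(roc.fpr, roc.tpr))

    def test_endpoints_and_monotonicity(self, rng):
        scores = rng.normal(size=40)
        labels = np.where(rng.uniform(size=40) < 0.4, 1, -1)
        labels[:2] = [1, -1]
        roc = roc_curve(scores, labels)
        assert (roc.fpr[0], roc.tpr[0]) == (0.0, 0.0)
        assert (roc.fpr[-1], roc.tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(roc.fpr) >= 0) and np.all(np.diff(roc.tpr) >= 0)

    def test_trapezoid_equals_mann_whitney(self, rng):
        for _ in range(50):
            n = rng.integers(6, 40)
            scores = np.round(rng.normal(size=n), 1)  # ties likely
            labels = np.where(rng.uniform(size=n) < 0.5, 1, -1)
            labels[:2] = [1, -1]
            assert roc_curve(scores, labels).auc == pytest.approx(
                auc_mann_whitney(scores, labels), abs=1e-10
            )


class TestDeLong:
    def test_identical_scores_degenerate(self):
        r = delong_compare([3, 2, 1, 0], [3, 2, 1, 0], [1, 1, -1, -1])
        assert r.degenerate and r.p == 1.0 and r.auc_a == r.auc_b

    def test_four_subject_hand_computation(self):
        """labels [+,+,-,-]; a separates perfectly (AUC 1), b gets one case
        below both controls (pairwise count 2/4 = 0.5).  Structural
        components by hand: V10_a=[1,1], V01_a=[1,1] (all variance 0);
        V10_b=[1,0], V01_b=[0.5,0.5], so var(AUC_b)=0.5/2=0.25, covariance
        0, z = 0.5/0.5 = 1."""
        labels = [1, 1, -1, -1]
        a = [0.9, 0.8, 0.2, 0.1]
        b = [0.9, 0.1, 0.8, 0.2]
        r = delong_compare(a, b, labels)
        assert r.auc_a == pytest.approx(1.0)
        assert r.auc_b == pytest.approx(helpers.auc_pairwise(b, labels))  # 0.5
        assert r.auc_b == pytest.approx(0.5)
        assert r.var_diff == pytest.approx(0.25, abs=1e-12)
        assert r.z == pytest.approx(1.0, abs=1e-12)
        assert r.p == pytest.approx(2 * stats.norm.sf(1.0), abs=1e-12)

    def test_swap_negates_z_keeps_p(self, rng):
        labels = np.where(rng.uniform(size=40) < 0.5, 1, -1)
        labels[:2] = [1, -1]
        a = rng.normal(size=40) + (labels == 1) * 0.8
        b = rng.normal(size=40) + (labels == 1) * 0.3
        r1 = delong_compare(a, b, labels)
        r2 = delong_compare(b, a, labels)
        assert r1.z == pytest.approx(-r2.z, abs=1e-12)
        assert r1.p == pytest.approx(r2.p, abs=1e-12)
        assert r1.auc_a == r2.auc_b

    def test_ci_truncated_and_ordered(self, rng):
        labels = np.r_[np.ones(25), -np.ones(25)]
        a = rng.normal(size=50) + (labels == 1) * 3.0
        b = rng.normal(size=50)
        r = delong_compare(a, b, labels, ci_level=0.95)
        lo, hi = r.ci_a
        assert 0.0 <= lo <= r.auc_a <= hi <= 1.0
        rl = delong_compare(a, b, labels, ci_level=0.95, ci_method="logit")
        lo_l, hi_l = rl.ci_b
        assert 0.0 < lo_l < rl.auc_b < hi_l < 1.0
        with pytest.raises(ValueError, match="ci_method"):
            delong_compare(a, b, labels, ci_method="exact")

    def test_type_one_error_calibrated_small(self, rng):
        """Reduced-size check of DeLong's null calibration with correlated
        scores (shared latent + independent noise)."""
        rej = 0
        n_rep = 400
        for _ in range(n_rep):
            labels = np.r_[np.ones(40), -np.ones(40)]
            latent = rng.normal(size=80) + (labels == 1) * 0.7
            a = latent + rng.normal(scale=0.8, size=80)
            b = latent + rng.normal(scale=0.8, size=80)
            if delong_compare(a, b, labels).p <= 0.05:
                rej += 1
        assert 0.015 <= rej / n_rep <= 0.10
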