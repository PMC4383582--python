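"""Model validation: leave-one-out and split-half cross-validation,
confusion-matrix metrics, ROC/AUC, and the DeLong test for correlated
ROC curves.

The positive class is +1 (preterm) throughout; sensitivity is the true
positive rate over true cases and specificity the true negative rate over
true controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import _smo
from .svm import HardMarginLinearSVC
from .volumes import FeatureMatrix

__all__ = [
    "CVResult",
    "ROCCurve",
    "DeLongResult",
    "ConfusionMetrics",
    "loo_cv",
    "split_half_validation",
    "confusion_metrics",
    "auc_mann_whitney",
    "roc_curve",
    "delong_compare",
]


def _as_xy(features, labels):
    if isinstance(features, FeatureMatrix):
        X = features.X
        ids = list(features.subject_ids)
    else:
        X = np.asarray(features, dtype=np.float64)
        ids = list(range(X.shape[0]))
    y = np.asarray(labels, dtype=np.float64)
    if y.shape != (X.shape[0],):
        raise ValueError("labels must have one entry per subject")
    if not np.all(np.isin(y, (-1.0, 1.0))):
        raise ValueError("labels must be -1 or +1")
    return X, y, ids


@dataclass
class CVResult:
    """Out-of-fold predictions: one score and label per held-out subject."""

    subject_ids: list
    y_true: np.ndarray
    y_pred: np.ndarray
    scores: np.ndarray
    fold_id: np.ndarray
    scheme: str
    details: dict = field(default_factory=dict)

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.y_pred == self.y_true))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.subject_ids,
                "fold": self.fold_id,
                "y_true": self.y_true.astype(int),
                "y_pred": self.y_pred.astype(int),
                "score": self.scores,
            }
        )


@dataclass
class ConfusionMetrics:
    tp: int
    fn: int
    tn: int
    fp: int
    accuracy: float
    sensitivity: float
    specificity: float
    undefined: list = field(default_factory=list)


@dataclass
class ROCCurve:
    """Threshold-sweep ROC: (FPR, TPR) from (0,0) to (1,1), tied scores
    collapsed onto a single threshold; ``auc`` is the trapezoidal area."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


@dataclass
class DeLongResult:
    auc_a: float
    auc_b: float
    var_a: float
    var_b: float
    var_diff: float
    z: float
    p: float
    ci_a: tuple
    ci_b: tuple
    ci_level: float
    degenerate: bool = False


# ---------------------------------------------------------------------------
# cross-validation

def _fold_residual_operator(C_design, train_rows, n):
    """n x n operator A with (A X) = features residualised on the covariate
    design fitted to ``train_rows`` only, applied to all rows."""
    D = np.column_stack([np.ones(n), C_design])
    S = D[train_rows]
    A = np.eye(n) - D @ np.linalg.pinv(S) @ np.eye(n)[train_rows]
    return A


def _prep_covariates(X, covariates, leakage):
    """Returns (K, fold_operator) where fold_operator(train_rows) -> Gram
    matrix to use for that fold (None when no per-fold work is needed)."""
    K = X @ X.T
    if covariates is None:
        return K, None
    C = np.asarray(covariates, dtype=np.float64)
    if C.ndim == 1:
        C = C[:, None]
    if leakage == "pooled":
        # single projection fitted on all subjects, as in an analysis that
        # residualises once before cross-validation
        n = X.shape[0]
        A = _fold_residual_operator(C, np.arange(n), n)
        Kr = A @ K @ A.T
        return Kr, None
    if leakage != "foldwise":
        raise ValueError("leakage must be 'foldwise' or 'pooled'")

    def fold_gram(train_rows):
        A = _fold_residual_operator(C, train_rows, X.shape[0])
        return A @ K @ A.T

    return K, fold_gram


def loo_cv(
    features,
    labels,
    trainer: HardMarginLinearSVC | None = None,
    covariates=None,
    leakage: str = "foldwise",
    shortcut: bool = True,
) -> CVResult:
    """Leave-one-out cross-validation of the hard-margin SVM.

    Each subject is scored by a model trained on all others.  With
    ``shortcut`` (default), folds whose left-out subject is a strict
    non-support vector of the full model reuse the full model — the
    maximum-margin solution is unchanged by removing such a point; the
    shortcut is score-identical to the naive loop within solver tolerance.

    ``covariates`` (optional, one row per subject, intercept added) are
    removed by a residual-forming projection fitted per training fold
    (``leakage='foldwise'``, leakage-safe) or once on all subjects
    (``leakage='pooled'``).
    """
    X, y, ids = _as_xy(features, labels)
    n = len(y)
    if n < 4 or (y == 1).sum() < 2 or (y == -1).sum() < 2:
        raise ValueError("LOO requires n >= 4 with at least 2 per class")
    tr = trainer if trainer is not None else HardMarginLinearSVC()
    K, fold_gram = _prep_covariates(X, covariates, leakage)

    if fold_gram is None:
        scores, status = _smo.loo_scores(
            K, y, float(tr.C), float(tr.eps), int(tr.max_iter),
            float(tr.kkt_tol), bool(shortcut),
        )
        if status != _smo.OK:
            raise RuntimeError("SMO iteration cap hit during LOO")
    else:
        scores = np.empty(n)
        for i in range(n):
            rows = np.delete(np.arange(n), i)
            if len(np.unique(y[rows])) < 2:
                raise ValueError(f"class absent in training fold {i}")
            Ki = fold_gram(rows)
            alpha, b, gap, it, status = _smo.dual_solve(
                Ki[np.ix_(rows, rows)], y[rows], float(tr.C), float(tr.eps),
                int(tr.max_iter),
            )
            if status != _smo.OK:
                raise RuntimeError(f"SMO iteration cap hit in fold {i}")
            scores[i] = float(alpha * y[rows] @ Ki[rows, i] + b)

    y_pred = np.where(scores > 0, 1.0, -1.0)
    return CVResult(
        subject_ids=ids,
        y_true=y,
        y_pred=y_pred,
        scores=scores,
        fold_id=np.arange(n),
        scheme="loo",
        details={
            "covariates": covariates is not None,
            "leakage": leakage if covariates is not None else None,
            "shortcut": shortcut,
            "C": tr.C,
        },
    )


def split_half_validation(
    features,
    labels,
    n_train_case: int = 37,
    n_train_control: int = 35,
    seed: int = 0,
    trainer: HardMarginLinearSVC | None = None,
) -> CVResult:
    """Train on a per-group random subsample, classify all held-out subjects.

    The default counts (37 cases / 35 controls in training) follow the
    reference design of a 74/69 cohort.
    """
    X, y, ids = _as_xy(features, labels)
    cases = np.flatnonzero(y == 1)
    controls = np.flatnonzero(y == -1)
    if n_train_case > len(cases) or n_train_control > len(controls):
        raise ValueError("requested training counts exceed group sizes")
    rng = np.random.default_rng(seed)
    tr_idx = np.concatenate(
        [
            rng.choice(cases, size=n_train_case, replace=False),
            rng.choice(controls, size=n_train_control, replace=False),
        ]
    )
    te_idx = np.setdiff1d(np.arange(len(y)), tr_idx)
    if te_idx.size == 0:
        raise ValueError("empty test set: training counts equal the group sizes")
    est = (trainer.clone() if trainer is not None else HardMarginLinearSVC())
    est.fit(X[tr_idx], y[tr_idx])
    scores = est.decision_function(X[te_idx])
    return CVResult(
        subject_ids=[ids[i] for i in te_idx],
        y_true=y[te_idx],
        y_pred=np.where(scores > 0, 1.0, -1.0),
        scores=scores,
        fold_id=np.zeros(te_idx.size, dtype=int),
        scheme=f"split_half(train={n_train_case}+{n_train_control}, seed={seed})",
        details={"train_idx": tr_idx, "seed": seed},
    )


# ---------------------------------------------------------------------------
# metrics

def confusion_metrics(y_true, y_pred) -> ConfusionMetrics:
    """Accuracy, sensitivity (over true +1) and specificity (over true -1).

    An empty class leaves the corresponding rate NaN and flags it in
    ``undefined`` rather than silently reporting 0.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must align")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == -1)))
    tn = int(np.sum((y_true == -1) & (y_pred == -1)))
    fp = int(np.sum((y_true == -1) & (y_pred == 1)))
    n = tp + fn + tn + fp
    undefined = []
    if tp + fn > 0:
        sens = tp / (tp + fn)
    else:
        sens = np.nan
        undefined.append("sensitivity")
    if tn + fp > 0:
        spec = tn / (tn + fp)
    else:
        spec = np.nan
        undefined.append("specificity")
    acc = (tp + tn) / n if n else np.nan
    return ConfusionMetrics(tp, fn, tn, fp, acc, sens, spec, undefined)


def _check_two_classes(labels):
    labels = np.asarray(labels)
    pos = labels == 1
    neg = labels == -1
    if not pos.any() or not neg.any():
        raise ValueError("both classes must be present")
    return pos, neg


def auc_mann_whitney(scores, labels) -> float:
    """AUC as the Mann-Whitney statistic with midrank tie handling:
    [#(case score > control score) + 0.5 #ties] / (n_case * n_control)."""
    scores = np.asarray(scores, dtype=np.float64)
    pos, neg = _check_two_classes(labels)
    ranks = stats.rankdata(scores)
    n1, n0 = int(pos.sum()), int(neg.sum())
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def roc_curve(scores, labels) -> ROCCurve:
    """ROC from a descending sweep over unique score thresholds, including
    the (0,0) and (1,1) endpoints; its trapezoidal area equals the
    Mann-Whitney AUC."""
    scores = np.asarray(scores, dtype=np.float64)
    pos, neg = _check_two_classes(labels)
    n1, n0 = int(pos.sum()), int(neg.sum())
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    is_pos = pos[order]
    # cumulative counts at each unique threshold (ties collapsed)
    last = np.r_[np.flatnonzero(np.diff(s)), len(s) - 1]
    tp = np.cumsum(is_pos)[last]
    fp = np.cumsum(~is_pos)[last]
    tpr = np.r_[0.0, tp / n1]
    fpr = np.r_[0.0, fp / n0]
    thresholds = np.r_[np.inf, s[last]]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc)


# ---------------------------------------------------------------------------
# DeLong test for two correlated AUCs

def _structural_components(scores, pos, neg):
    """DeLong structural components via midranks.

    V10 (one per case) and V01 (one per control); their means equal the AUC.
    """
    s = np.asarray(scores, dtype=np.float64)
    n1, n0 = int(pos.sum()), int(neg.sum())
    rz = stats.rankdata(s)
    r1 = stats.rankdata(s[pos])
    r0 = stats.rankdata(s[neg])
    v10 = (rz[pos] - r1) / n0
    v01 = 1.0 - (rz[neg] - r0) / n1
    auc = float(v10.mean())
    return auc, v10, v01


def delong_compare(
    scores_a, scores_b, labels, ci_level: float = 0.95, ci_method: str = "wald"
) -> DeLongResult:
    """DeLong test comparing two correlated AUCs over the same subjects.

    The covariance of (AUC_a, AUC_b) is S10/n1 + S01/n0 with S10, S01 the
    sample covariances of the per-case and per-control structural
    components; z = dAUC / sqrt(var(diff)) with a two-sided normal p.
    Per-AUC confidence intervals are Wald on the AUC scale truncated to
    [0, 1] (default) or computed on the logit scale
    (``ci_method='logit'``), which respects the bounds by construction.
    Identical score vectors give a degenerate (zero-variance) difference,
    flagged and reported as p = 1.
    """
    if ci_method not in ("wald", "logit"):
        raise ValueError("ci_method must be 'wald' or 'logit'")
    scores_a = np.asarray(scores_a, dtype=np.float64)
    scores_b = np.asarray(scores_b, dtype=np.float64)
    if scores_a.shape != scores_b.shape:
        raise ValueError("score vectors must cover the same subjects")
    pos, neg = _check_two_classes(labels)
    n1, n0 = int(pos.sum()), int(neg.sum())
    auc_a, v10a, v01a = _structural_components(scores_a, pos, neg)
    auc_b, v10b, v01b = _structural_components(scores_b, pos, neg)
    V10 = np.vstack([v10a, v10b])
    V01 = np.vstack([v01a, v01b])
    if n1 > 1:
        S10 = np.cov(V10)
    else:  # pragma: no cover - degenerate single-case design
        S10 = np.zeros((2, 2))
    if n0 > 1:
        S01 = np.cov(V01)
    else:  # pragma: no cover
        S01 = np.zeros((2, 2))
    S = S10 / n1 + S01 / n0
    var_a, var_b = float(S[0, 0]), float(S[1, 1])
    var_diff = float(S[0, 0] + S[1, 1] - 2 * S[0, 1])
    d = auc_a - auc_b
    degenerate = var_diff <= 1e-16
    if degenerate:
        z, p = 0.0, 1.0
    else:
        z = d / np.sqrt(var_diff)
        p = float(2.0 * stats.norm.sf(abs(z)))
    zc = stats.norm.ppf(1.0 - (1.0 - ci_level) / 2.0)

    def ci(auc, var):
        se = np.sqrt(max(var, 0.0))
        if ci_method == "logit" and 0.0 < auc < 1.0 and se > 0.0:
            # delta method on logit(AUC): se_logit = se / (auc (1 - auc))
            logit = np.log(auc / (1.0 - auc))
            h = zc * se / (auc * (1.0 - auc))
            lo, hi = logit - h, logit + h
            return (1.0 / (1.0 + np.exp(-lo)), 1.0 / (1.0 + np.exp(-hi)))
        h = zc * se
        return (max(0.0, auc - h), min(1.0, auc + h))

    return DeLongResult(
        auc_a=auc_a,
        auc_b=auc_b,
        var_a=var_a,
        var_b=var_b,
        var_diff=var_diff,
        z=float(z),
        p=float(p),
        ci_a=ci(auc_a, var_a),
        ci_b=ci(auc_b, var_b),
        ci_level=ci_level,
        degenerate=degenerate,
    )
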