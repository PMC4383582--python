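"""Linear hard-margin SVM trained in the dual (Gram-matrix) form.

Voxel-based-morphometry classification problems have far more voxels than
subjects (p >> n), so the model is fitted on the n x n Gram matrix and the
voxel weight map is recovered afterwards as w = X' (alpha * y).  The "hard"
margin is realised as a soft margin with a very large finite box constraint
``C`` plus an explicit post-fit separability check: smoothed gray-matter
features with p >> n are linearly separable, and any subject whose dual
coefficient saturates the box while violating the margin triggers a
:class:`NotSeparableError` rather than a silent soft-margin fit.

The estimator follows the scikit-learn API (``fit`` / ``decision_function``
/ ``predict``, ``get_params`` / ``set_params``, fitted attributes with a
trailing underscore) so it composes with sklearn pipelines and model
selection, without depending on scikit-learn itself.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from . import _smo

__all__ = [
    "HardMarginLinearSVC",
    "NotSeparableError",
    "decision_scores",
    "train_linear_svm",
    "weight_map",
]


class NotSeparableError(RuntimeError):
    """Raised when the training data admit no separating hyperplane at the
    requested margin tolerance."""

    def __init__(self, message: str, subjects: Sequence = ()):
        super().__init__(message)
        self.subjects = list(subjects)


class HardMarginLinearSVC:
    """Maximum-margin linear classifier for separable two-class data.

    Parameters
    ----------
    C : float
        Box constraint used to realise the hard margin; effectively
        infinite at the default 1e8.  A finite moderate value turns the
        estimator into an ordinary soft-margin SVM (used, flagged, for the
        single-feature total-intracranial-volume classifier where the groups
        overlap).
    kkt_tol : float
        Margin tolerance for the Karush-Kuhn-Tucker checks: training
        margins must satisfy y_i f(x_i) >= 1 - kkt_tol and support vectors
        lie at |y_i f(x_i) - 1| <= kkt_tol.
    eps : float
        Dual-gap stopping tolerance of the SMO solver.
    sv_tol_factor : float
        A training point counts as a support vector when
        alpha_i > sv_tol_factor * max(alpha).
    check_separable : bool
        If True (default), raise :class:`NotSeparableError` when any dual
        coefficient saturates C while its margin is violated.
    max_iter : int
        Iteration cap for the solver.

    Attributes
    ----------
    coef_ : ndarray of shape (1, n_features)
        Voxel weight vector w.
    intercept_ : ndarray of shape (1,)
        Bias b.  Decision scores are f(x) = w . x + b.
    alpha_ : ndarray of shape (n_samples,)
        Dual coefficients (nonnegative).
    support_ : ndarray of int
        Indices of the support vectors (alpha above tolerance).
    classes_ : ndarray
        Always ``[-1, 1]``; +1 is the case (preterm) side.
    """

    def __init__(
        self,
        C: float = 1e8,
        kkt_tol: float = 1e-4,
        eps: float = 1e-6,
        sv_tol_factor: float = 1e-6,
        check_separable: bool = True,
        max_iter: int = 2_000_000,
    ):
        self.C = C
        self.kkt_tol = kkt_tol
        self.eps = eps
        self.sv_tol_factor = sv_tol_factor
        self.check_separable = check_separable
        self.max_iter = max_iter

    # -- scikit-learn plumbing -------------------------------------------
    _param_names = ("C", "kkt_tol", "eps", "sv_tol_factor", "check_separable", "max_iter")

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params) -> "HardMarginLinearSVC":
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"unknown parameter {k!r} for HardMarginLinearSVC")
            setattr(self, k, v)
        return self

    def clone(self) -> "HardMarginLinearSVC":
        return HardMarginLinearSVC(**self.get_params())

    def __repr__(self) -> str:  # sklearn-style
        args = ", ".join(f"{k}={getattr(self, k)!r}" for k in self._param_names)
        return f"HardMarginLinearSVC({args})"

    # -- fitting ----------------------------------------------------------
    @staticmethod
    def _validate(X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D (subjects x features) array")
        if y.shape != (X.shape[0],):
            raise ValueError("y must have one label per row of X")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        yi = y.astype(np.float64)
        if not np.all(np.isin(yi, (-1.0, 1.0))):
            raise ValueError("labels must be -1 (control) or +1 (case)")
        if np.unique(yi).size < 2:
            raise ValueError("both classes must be present in the training data")
        return X, yi

    def fit(self, X, y, subject_ids: Sequence | None = None) -> "HardMarginLinearSVC":
        X, yf = self._validate(X, y)
        K = X @ X.T
        alpha, b, gap, n_iter, status = _smo.dual_solve(
            K, yf, float(self.C), float(self.eps), int(self.max_iter)
        )
        if status != _smo.OK:
            raise RuntimeError(
                f"SMO did not converge within max_iter={self.max_iter} "
                f"(residual KKT gap {gap:.3g}); the data may not be separable "
                f"at C={self.C:g}"
            )
        w = X.T @ (alpha * yf)
        margins = yf * (X @ w + b)
        self._check_hard_margin(alpha, margins, subject_ids)

        a_max = float(alpha.max())
        sv_tol = self.sv_tol_factor * a_max if a_max > 0 else 0.0
        self.coef_ = w[np.newaxis, :]
        self.intercept_ = np.array([b])
        self.alpha_ = alpha
        self.support_ = np.flatnonzero(alpha > sv_tol)
        self.sv_tol_ = sv_tol
        self.n_iter_ = n_iter
        self.dual_gap_ = gap
        self.classes_ = np.array([-1, 1])
        self.n_features_in_ = X.shape[1]
        self.y_ = yf
        self.subject_ids_ = list(subject_ids) if subject_ids is not None else None
        return self

    def _check_hard_margin(self, alpha, margins, subject_ids):
        if not self.check_separable:
            return
        at_bound = alpha >= self.C * (1.0 - 1e-6)
        violated = margins < 1.0 - self.kkt_tol
        bad = np.flatnonzero(at_bound & violated)
        if bad.size == 0 and np.any(violated):
            # margins can only be violated with alpha at the bound once the
            # solver has converged; treat residual violations the same way
            bad = np.flatnonzero(violated)
        if bad.size:
            ids = (
                [subject_ids[i] for i in bad]
                if subject_ids is not None
                else bad.tolist()
            )
            raise NotSeparableError(
                "training data are not separable under a hard margin; "
                f"margin violated for subjects {ids}",
                subjects=ids,
            )

    # -- inference --------------------------------------------------------
    def _check_fitted(self):
        if not hasattr(self, "coef_"):
            raise RuntimeError("this HardMarginLinearSVC instance is not fitted yet")

    def decision_function(self, X) -> np.ndarray:
        """Signed distance-to-boundary scores f(x) = w . x + b."""
        self._check_fitted()
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X must have {self.n_features_in_} feature columns in the "
                "model's column order"
            )
        return X @ self.coef_[0] + self.intercept_[0]

    def predict(self, X) -> np.ndarray:
        """Predicted labels; an exact tie f(x) = 0 goes to -1 (control)."""
        f = self.decision_function(X)
        return np.where(f > 0, 1, -1)

    def score(self, X, y) -> float:
        y = np.asarray(y)
        return float(np.mean(self.predict(X) == y))


# ---------------------------------------------------------------------------
# thin functional wrappers

def train_linear_svm(
    features,
    labels,
    C_effective: float = 1e8,
    tol: float = 1e-4,
    subject_ids=None,
    **kwargs,
) -> HardMarginLinearSVC:
    """Train a hard-margin linear SVM; see :class:`HardMarginLinearSVC`."""
    est = HardMarginLinearSVC(C=C_effective, kkt_tol=tol, **kwargs)
    return est.fit(features, labels, subject_ids=subject_ids)


def decision_scores(model: HardMarginLinearSVC, features) -> np.ndarray:
    """Per-subject prediction scores f(x) = w . x + b."""
    return model.decision_function(features)


def weight_map(model: HardMarginLinearSVC, mask) -> np.ndarray:
    """Unvectorise the fitted weight vector onto the mask's 3-D grid.

    Voxels outside the mask are zero; ``vectorize(weight_map(m), mask)``
    returns ``m.coef_[0]`` exactly.
    """
    model._check_fitted()
    from .volumes import unvectorize  # local import to avoid a cycle

    return unvectorize(model.coef_[0], mask)
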