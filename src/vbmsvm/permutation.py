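"""Label-permutation significance testing.

Group labels are permuted uniformly at random while images and covariates
travel with their subjects, answering "is the group assignment informative
given the images".  p-values use the add-one convention
p = (1 + #{null >= observed}) / (1 + n_perm), which is valid (never zero)
and matches bound-style reporting: when no null draw reaches the observed
statistic, the minimal reportable p with N permutations is 1/(N+1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _smo
from .evaluation import _as_xy, _prep_covariates, auc_mann_whitney
from .svm import HardMarginLinearSVC
from .volumes import BrainMask, unvectorize

__all__ = [
    "PermutationNull",
    "PValueMap",
    "permute_global",
    "weight_pvalue_map",
    "min_reportable_p",
]


def min_reportable_p(n_perm: int) -> float:
    """Smallest p reportable with ``n_perm`` permutations: 1 / (n_perm + 1)."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    return 1.0 / (n_perm + 1)


@dataclass
class PermutationNull:
    statistic: str
    observed: float
    null: np.ndarray
    n_perm: int
    seed: int
    p_value: float
    p_bound_form: str


@dataclass
class PValueMap:
    """Per-masked-voxel uncorrected p-values for the SVM weight map."""

    p: np.ndarray
    n_perm: int
    seed: int
    sidedness: str = "two-sided on |w|"
    mask: BrainMask | None = None

    def as_volume(self) -> np.ndarray:
        if self.mask is None:
            raise ValueError("no mask attached to this p-value map")
        out = unvectorize(self.p, self.mask)
        out[~self.mask.mask] = 1.0
        return out


def _statistic_value(scores, y, statistic):
    if statistic == "accuracy":
        return float(np.mean(np.where(scores > 0, 1.0, -1.0) == y))
    if statistic == "auc":
        return auc_mann_whitney(scores, y)
    raise ValueError(f"unknown statistic {statistic!r}; use 'accuracy' or 'auc'")


def permute_global(
    features,
    labels,
    statistic: str = "accuracy",
    n_perm: int = 999,
    seed: int = 0,
    trainer: HardMarginLinearSVC | None = None,
    covariates=None,
    leakage: str = "pooled",
    shortcut: bool = True,
) -> PermutationNull:
    """Permutation null for the leave-one-out classification statistic.

    For each of ``n_perm`` uniformly random label permutations the full LOO
    pipeline is recomputed and the chosen statistic (accuracy or AUC of the
    out-of-fold scores) recorded.  The Gram matrix is label-free and thus
    computed once.  With covariates, ``leakage='pooled'`` residualises once
    up front (fast path); ``'foldwise'`` refits the projection per fold and
    per permutation.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X, y, _ = _as_xy(features, labels)
    n = len(y)
    tr = trainer if trainer is not None else HardMarginLinearSVC()
    _statistic_value(np.zeros(n), y, statistic)  # validate statistic name early

    K, fold_gram = _prep_covariates(X, covariates, leakage)
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(n) for _ in range(n_perm)])

    def loo_for(yp):
        if fold_gram is None:
            s, status = _smo.loo_scores(
                K, yp, float(tr.C), float(tr.eps), int(tr.max_iter),
                float(tr.kkt_tol), bool(shortcut),
            )
            if status != _smo.OK:
                raise RuntimeError("SMO iteration cap hit during permutation LOO")
            return s
        from .evaluation import loo_cv

        return loo_cv(X, yp, trainer=tr, covariates=covariates,
                      leakage=leakage, shortcut=shortcut).scores

    observed = _statistic_value(loo_for(y), y, statistic)
    if fold_gram is None:
        perm_labels = y[perms]
        score_mat = _smo.permutation_loo_scores(
            K, perm_labels, float(tr.C), float(tr.eps), int(tr.max_iter),
            float(tr.kkt_tol), bool(shortcut),
        )
        null = np.array(
            [_statistic_value(score_mat[r], perm_labels[r], statistic)
             for r in range(n_perm)]
        )
    else:
        null = np.empty(n_perm)
        for r in range(n_perm):
            yp = y[perms[r]]
            null[r] = _statistic_value(loo_for(yp), yp, statistic)

    k = int(np.sum(null >= observed))
    p = (1 + k) / (1 + n_perm)
    bound = (
        f"p < 1/{n_perm} (no null draw reached the observed value)"
        if k == 0
        else f"p = (1+{k})/(1+{n_perm})"
    )
    return PermutationNull(
        statistic=statistic,
        observed=observed,
        null=null,
        n_perm=n_perm,
        seed=seed,
        p_value=p,
        p_bound_form=bound,
    )


def weight_pvalue_map(
    features,
    labels,
    n_perm: int = 199,
    seed: int = 0,
    trainer: HardMarginLinearSVC | None = None,
    permutations: np.ndarray | None = None,
) -> PValueMap:
    """Voxelwise permutation p-values for the full-data SVM weight map.

    The observed map w* is fitted on the true labels; each permutation
    refits on permuted labels and the two-sided per-voxel p-value is
    (1 + #{|w_perm| >= |w*|}) / (1 + n_perm), uncorrected.  ``permutations``
    (n_perm x n index rows) overrides the random draws, e.g. to audit the
    identity permutation.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X, y, _ = _as_xy(features, labels)
    mask = features.mask if hasattr(features, "mask") else None
    tr = trainer if trainer is not None else HardMarginLinearSVC()
    K = X @ X.T
    alpha, b, gap, it, status = _smo.dual_solve(
        K, y, float(tr.C), float(tr.eps), int(tr.max_iter)
    )
    if status != _smo.OK:
        raise RuntimeError("SMO iteration cap hit on the observed fit")
    w_obs = X.T @ (alpha * y)
    if permutations is None:
        rng = np.random.default_rng(seed)
        permutations = np.stack([rng.permutation(len(y)) for _ in range(n_perm)])
    else:
        permutations = np.asarray(permutations)
        if permutations.shape != (n_perm, len(y)):
            raise ValueError("permutations must be (n_perm, n) index rows")
    perm_labels = y[permutations]
    counts = _smo.permutation_weight_counts(
        K, X, perm_labels, np.abs(w_obs), float(tr.C), float(tr.eps),
        int(tr.max_iter),
    )
    p = (1.0 + counts) / (1.0 + n_perm)
    return PValueMap(p=p, n_perm=n_perm, seed=seed, mask=mask)
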