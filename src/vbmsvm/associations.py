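"""Clinical associations of the SVM decision score: Pearson correlations
with gestational age, birth weight and IQ; partial correlations after
covariate removal; WHO gestational-age stratification; subgroup, SGA-excluded
and TIV-only analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .evaluation import CVResult, loo_cv, roc_curve
from .svm import HardMarginLinearSVC, NotSeparableError
from .volumes import Residualizer

__all__ = [
    "UndefinedCorrelationError",
    "pearson_corr",
    "correlate_scores",
    "partial_correlation_after_residualization",
    "who_stratify",
    "WHO_CATEGORIES",
    "subgroup_mean_scores",
    "pairwise_subgroup_classification",
    "sga_excluded_analysis",
    "tiv_only_classification",
]

# WHO gestational-age bands for cases (weeks, half-open intervals) and the
# numeric codes used for them; term controls are -1.
WHO_CATEGORIES = {
    1: "moderately_preterm",   # 32 <= GA < 37
    2: "very_preterm",         # 28 <= GA < 32
    3: "extremely_preterm",    # GA < 28
    -1: "term",
}


class UndefinedCorrelationError(ValueError):
    """A correlation is undefined (zero variance or too few pairs)."""


def _finite_pairs(x, y):
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def pearson_corr(x, y):
    """Pearson r with a two-sided p from the t transform (n - 2 df).

    Non-finite pairs are removed pairwise; fewer than 3 remaining pairs or
    zero variance in either vector raises :class:`UndefinedCorrelationError`.
    Returns ``(r, p, n)``.
    """
    x, y = _finite_pairs(x, y)
    n = len(x)
    if n < 3:
        raise UndefinedCorrelationError(f"need >= 3 finite pairs, have {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in one of the vectors")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), n


@dataclass
class CorrelationRow:
    variable: str
    subset: str
    n: int
    r: float
    p: float
    error: str | None = None


def correlate_scores(table: pd.DataFrame, scores, variables, subset: str = "all") -> pd.DataFrame:
    """Correlate decision scores with clinical variables over a subject subset.

    ``subset`` is 'all', 'cases' (+1) or 'controls' (-1); missing values are
    removed pairwise per variable and each row reports its own n.  Undefined
    correlations are surfaced per variable in the ``error`` column.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if len(scores) != len(table):
        raise ValueError("scores must align with the participant table")
    if subset == "all":
        keep = np.ones(len(table), dtype=bool)
    elif subset == "cases":
        keep = table["group"].to_numpy() == 1
    elif subset == "controls":
        keep = table["group"].to_numpy() == -1
    else:
        raise ValueError("subset must be 'all', 'cases' or 'controls'")
    if not keep.any():
        raise ValueError(f"subset {subset!r} selects no subjects")
    rows = []
    for var in variables:
        if var not in table.columns:
            raise KeyError(f"unknown variable {var!r}")
        try:
            r, p, n = pearson_corr(scores[keep], table.loc[keep, var].to_numpy())
            rows.append(CorrelationRow(var, subset, n, r, p))
        except UndefinedCorrelationError as exc:
            rows.append(CorrelationRow(var, subset, 0, np.nan, np.nan, str(exc)))
    return pd.DataFrame([row.__dict__ for row in rows])


def partial_correlation_after_residualization(table, scores, variable, covariates):
    """Pearson correlation of score and variable after removing covariates.

    Both vectors are residualised on the covariate design (intercept
    included) with the residual-forming projection, then correlated; the
    t-test uses n - 2 - k degrees of freedom for k non-intercept covariate
    columns.  Returns ``(r, p, n)``.
    """
    scores = np.asarray(scores, dtype=np.float64)
    v = table[variable].to_numpy(dtype=np.float64) if isinstance(variable, str) else np.asarray(variable, dtype=np.float64)
    C = np.asarray(covariates, dtype=np.float64)
    if C.ndim == 1:
        C = C[:, None]
    if C.size and C.shape[0] != len(scores):
        raise ValueError("covariates must have one row per subject")
    keep = np.isfinite(scores) & np.isfinite(v)
    if C.size:
        keep &= np.all(np.isfinite(C), axis=1)
    s, v = scores[keep], v[keep]
    n = len(s)
    if n < 4:
        raise UndefinedCorrelationError(f"need >= 4 finite rows, have {n}")
    if C.size == 0 or C.shape[1] == 0:
        return pearson_corr(s, v)
    res = Residualizer().fit(C[keep], np.column_stack([s, v]))
    R = res.transform(C[keep], np.column_stack([s, v]))
    rs, rv = R[:, 0], R[:, 1]
    if np.allclose(rs, 0, atol=1e-12) or np.allclose(rv, 0, atol=1e-12):
        raise UndefinedCorrelationError(
            "residual variance is zero (a covariate duplicates a variable?)"
        )
    r = float(np.corrcoef(rs, rv)[0, 1])
    k = res.n_covariate_columns
    df = n - 2 - k
    if df < 1:
        raise UndefinedCorrelationError("not enough residual degrees of freedom")
    t = r * np.sqrt(df / max(1e-300, 1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return r, p, n


def who_stratify(ga_weeks, group):
    """WHO gestational-age category codes: term -1; moderately (+1) for
    32 <= GA < 37, very (+2) for 28 <= GA < 32, extremely (+3) for GA < 28.

    A case with GA >= 37 weeks is a consistency error.
    """
    ga = np.atleast_1d(np.asarray(ga_weeks, dtype=np.float64))
    grp = np.atleast_1d(np.asarray(group))
    if ga.shape != grp.shape:
        raise ValueError("ga_weeks and group must align")
    if not np.all(np.isfinite(ga)):
        raise ValueError("ga_weeks must be finite")
    out = np.empty(ga.shape, dtype=int)
    is_case = grp == 1
    bad = is_case & (ga >= 37.0)
    if bad.any():
        raise ValueError(
            f"case subjects with GA >= 37 weeks at rows {np.flatnonzero(bad).tolist()}"
        )
    out[~is_case] = -1
    out[is_case & (ga < 28.0)] = 3
    out[is_case & (ga >= 28.0) & (ga < 32.0)] = 2
    out[is_case & (ga >= 32.0)] = 1
    return out if np.ndim(ga_weeks) else int(out[0])


def subgroup_mean_scores(scores, categories) -> pd.DataFrame:
    """Mean decision score and count per WHO category; empty categories are
    absent from the output rather than reported as zero."""
    scores = np.asarray(scores, dtype=np.float64)
    categories = np.asarray(categories)
    rows = []
    for code in (-1, 1, 2, 3):
        sel = categories == code
        if sel.any():
            rows.append(
                {
                    "category": WHO_CATEGORIES[code],
                    "code": code,
                    "n": int(sel.sum()),
                    "mean_score": float(scores[sel].mean()),
                }
            )
    return pd.DataFrame(rows)


def _select_category(table, cat):
    codes = who_stratify(table["ga_weeks"].to_numpy(), table["group"].to_numpy())
    if cat == "controls":
        return codes == -1
    if cat in (1, 2, 3):
        return codes == cat
    raise ValueError("category must be 'controls' or a WHO code 1, 2 or 3")


def pairwise_subgroup_classification(
    features, table: pd.DataFrame, cat_a, cat_b, trainer=None, **loo_kwargs
) -> CVResult:
    """Leave-one-out classification restricted to two subject sets.

    Each set is 'controls' or a WHO case category code (1, 2 or 3); the
    first set is labelled -1 and the second +1 for the restricted run.
    """
    if cat_a == cat_b:
        raise ValueError("the two categories must differ")
    sel_a = _select_category(table, cat_a)
    sel_b = _select_category(table, cat_b)
    if not sel_a.any() or not sel_b.any():
        raise ValueError("both selected sets must be non-empty")
    if np.any(sel_a & sel_b):
        raise ValueError("selected sets overlap")
    X = features.X if hasattr(features, "X") else np.asarray(features, dtype=np.float64)
    rows = np.flatnonzero(sel_a | sel_b)
    y = np.where(sel_b[rows], 1.0, -1.0)
    cv = loo_cv(X[rows], y, trainer=trainer, **loo_kwargs)
    cv.scheme = f"loo[{cat_a} vs {cat_b}]"
    cv.subject_ids = table["id"].to_numpy()[rows].tolist()
    return cv


def sga_excluded_analysis(features, table: pd.DataFrame, trainer=None, **loo_kwargs) -> CVResult:
    """LOO classification with SGA cases excluded (controls all retained),
    for comparison against the full-cohort analysis."""
    grp = table["group"].to_numpy()
    sga = table["sga"].to_numpy().astype(bool)
    keep = (grp == -1) | ((grp == 1) & ~sga)
    if not np.any((grp == 1) & ~sga):
        raise ValueError("no non-SGA cases to analyse")
    X = features.X if hasattr(features, "X") else np.asarray(features, dtype=np.float64)
    rows = np.flatnonzero(keep)
    cv = loo_cv(X[rows], grp[rows].astype(float), trainer=trainer, **loo_kwargs)
    cv.scheme = "loo[SGA excluded]"
    cv.subject_ids = table["id"].to_numpy()[rows].tolist()
    cv.details["n_cases_included"] = int(np.sum(grp[rows] == 1))
    return cv


def tiv_only_classification(
    tiv_ml_values, labels, trainer=None, soft_C: float = 1.0, **loo_kwargs
):
    """LOO classification from the single TIV feature, with its ROC curve.

    A hard margin usually fails on one overlapping feature; in that case
    the run falls back to a margin-violation-tolerant soft-margin fit at
    ``soft_C`` and flags it (``details['tolerant_fit']``).  Returns
    ``(CVResult, ROCCurve)``.
    """
    tiv = np.asarray(tiv_ml_values, dtype=np.float64)
    if tiv.ndim != 1:
        raise ValueError("tiv_ml_values must be a vector")
    if np.ptp(tiv) == 0:
        raise NotSeparableError("TIV is constant across subjects; not separable")
    X = tiv[:, None]
    tr = trainer if trainer is not None else HardMarginLinearSVC()
    tolerant = False
    try:
        # probe separability on the full data first (cheap, raises early);
        # with one feature, any subset of separable data stays separable
        probe = tr.clone().set_params(max_iter=min(tr.max_iter, 200_000))
        probe.fit(X, labels)
        cv = loo_cv(X, labels, trainer=tr, **loo_kwargs)
    except (NotSeparableError, RuntimeError):
        # standardising the single feature puts the soft margin's C on a
        # scale-free footing; decision scores are affine in TIV either way
        Xz = (X - tiv.mean()) / tiv.std()
        soft = tr.clone().set_params(C=soft_C, check_separable=False)
        cv = loo_cv(Xz, labels, trainer=soft, **loo_kwargs)
        tolerant = True
    cv.scheme = "loo[TIV only]"
    cv.details["tolerant_fit"] = tolerant
    if tolerant:
        cv.details["soft_C"] = soft_C
    return cv, roc_curve(cv.scores, labels)
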