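"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the hard-margin dual is
solved by a generic constrained QP (scipy SLSQP), AUC by brute-force pair
counting, residuals by per-column least squares, smoothing by explicit
kernel convolution.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize


def random_separable_problem(rng, n=20, p=10, margin=1.0):
    """Random linearly separable two-class data with a guaranteed margin
    buffer along a random direction."""
    y = np.where(rng.uniform(size=n) < 0.5, 1.0, -1.0)
    # ensure both classes
    y[0], y[1] = 1.0, -1.0
    X = rng.normal(size=(n, p))
    u = rng.normal(size=p)
    u /= np.linalg.norm(u)
    X = X - np.outer(X @ u, u)  # remove the separating direction
    offset = rng.normal()
    X += np.outer(y * margin + offset, u)
    return X, y


def qp_hard_margin(X, y, tol=1e-14):
    """Generic QP solve of the hard-margin dual:
    min 1/2 a'Qa - e'a  s.t.  y'a = 0, a >= 0, with Q = (yy') * (XX').

    Returns (w, b, alpha)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    Q = np.outer(y, y) * (X @ X.T)

    def f(a):
        return 0.5 * a @ Q @ a - a.sum()

    def jac(a):
        return Q @ a - 1.0

    cons = [{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}]
    res = optimize.minimize(
        f,
        x0=np.full(n, 1.0 / n),
        jac=jac,
        bounds=[(0.0, None)] * n,
        constraints=cons,
        method="SLSQP",
        options={"maxiter": 1000, "ftol": tol},
    )
    if not res.success:  # pragma: no cover - oracle must converge
        raise RuntimeError(f"QP oracle failed: {res.message}")
    alpha = res.x
    w = X.T @ (alpha * y)
    sv = alpha > 1e-6 * alpha.max()
    b = float(np.mean(y[sv] - X[sv] @ w))
    return w, b, alpha


def auc_pairwise(scores, labels):
    """Brute-force Mann-Whitney AUC over all (case, control) pairs with
    half credit for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == -1]
    total = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(pos) * len(neg))


def residualize_columnwise(X, C, add_intercept=True):
    """Per-column least-squares fit and subtract."""
    C = np.asarray(C, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if add_intercept:
        C = np.column_stack([np.ones(C.shape[0]), C])
    out = np.empty_like(np.asarray(X, dtype=float))
    for j in range(out.shape[1]):
        beta, *_ = np.linalg.lstsq(C, X[:, j], rcond=None)
        out[:, j] = X[:, j] - C @ beta
    return out


def gaussian_kernel_1d(sigma, radius):
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def smooth_by_convolution(vol, sigma_vox):
    """Direct separable convolution with zero padding (truncate 4 sigma,
    matching scipy's default)."""
    out = np.asarray(vol, dtype=float).copy()
    for ax, s in enumerate(np.broadcast_to(sigma_vox, (3,))):
        radius = int(4.0 * s + 0.5)
        k = gaussian_kernel_1d(s, radius)
        padded = np.zeros(
            tuple(
                d + (2 * radius if a == ax else 0) for a, d in enumerate(out.shape)
            )
        )
        sl = tuple(
            slice(radius, radius + out.shape[a]) if a == ax else slice(None)
            for a in range(3)
        )
        padded[sl] = out
        res = np.zeros_like(out)
        for off in range(2 * radius + 1):
            shifted = tuple(
                slice(off, off + out.shape[a]) if a == ax else slice(None)
                for a in range(3)
            )
            res += k[off] * padded[shifted]
        out = res
    return out


def null_cohort_config(seed, n_case=20, n_control=20, grid=(10, 10, 10)):
    from vbmsvm import CohortConfig

    return CohortConfig(
        n_case=n_case,
        n_control=n_control,
        grid_shape=grid,
        effect_scale=0.0,
        tiv_group_gap=0.0,
        seed=seed,
    )


def cohort_features(config):
    """Generate and preprocess a cohort; returns (features, labels, table,
    volumes, truth)."""
    from vbmsvm import build_mask, generate_cohort, smooth_volumes, vectorize

    volset, table, truth = generate_cohort(config)
    y = table["group"].to_numpy(dtype=float)
    smoothed = smooth_volumes(volset, 6.0)
    mask = build_mask(smoothed, 0.1)
    feats = vectorize(smoothed, mask)
    return feats, y, table, volset, truth
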