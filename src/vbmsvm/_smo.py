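"""Dual SMO solver for the (hard-margin) linear SVM, on a precomputed Gram matrix.

The dual problem, in the standard form

    min_a  1/2 a' Q a - e' a    s.t.  y' a = 0,  0 <= a_i <= C,

with Q_ij = y_i y_j K_ij, is solved by sequential minimal optimisation with
maximal-violating-pair working-set selection.  Everything here is
numba-compiled: the leave-one-out and permutation loops call these kernels
thousands of times per analysis, and each fit touches only the n x n Gram
matrix (n = subjects), never the voxel dimension.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# status codes returned by the kernels
OK = 0
MAX_ITER = 1

# box constraints at or above this are treated as a hard margin, solved by
# the direct active-set path rather than SMO
HARD_C = 1e6


@njit(cache=True)
def smo_solve(K, y, C, eps, max_iter):
    """Solve the dual on Gram matrix ``K`` with labels ``y`` in {-1,+1}.

    Returns ``(alpha, b, gap, n_iter, status)``.  ``gap`` is the final
    maximal KKT violation (stopping criterion value); ``b`` is estimated
    from free support vectors, falling back to the violating-pair midpoint.
    """
    n = K.shape[0]
    alpha = np.zeros(n)
    # gradient of the dual objective: G = Q a - e
    G = -np.ones(n)
    it = 0
    gap = 0.0
    while it < max_iter:
        # maximal violating pair: i maximises -y G over I_up,
        # j minimises -y G over I_low
        gmax = -1e300
        gmin = 1e300
        i = -1
        j = -1
        for t in range(n):
            v = -y[t] * G[t]
            if (y[t] > 0 and alpha[t] < C) or (y[t] < 0 and alpha[t] > 0):
                if v > gmax:
                    gmax = v
                    i = t
            if (y[t] > 0 and alpha[t] > 0) or (y[t] < 0 and alpha[t] < C):
                if v < gmin:
                    gmin = v
                    j = t
        gap = gmax - gmin
        if i == -1 or j == -1 or gap < eps:
            break
        # two-variable subproblem along u_i = y_i, u_j = -y_j, which keeps
        # y'a constant.  Curvature a = K_ii + K_jj - 2 K_ij >= 0.
        quad = K[i, i] + K[j, j] - 2.0 * K[i, j]
        if quad < 1e-300:
            quad = 1e-300
        d = gap / quad
        # box constraints on the step
        if y[i] > 0:
            if d > C - alpha[i]:
                d = C - alpha[i]
        else:
            if d > alpha[i]:
                d = alpha[i]
        if y[j] > 0:
            if d > alpha[j]:
                d = alpha[j]
        else:
            if d > C - alpha[j]:
                d = C - alpha[j]
        alpha[i] += y[i] * d
        alpha[j] -= y[j] * d
        for t in range(n):
            G[t] += d * y[t] * (K[t, i] - K[t, j])
        it += 1

    status = OK if it < max_iter else MAX_ITER

    # bias from free support vectors: for 0 < a_i < C, b = -y_i G_i
    b_sum = 0.0
    n_free = 0
    lo = C * 1e-12
    hi = C * (1.0 - 1e-9)
    for t in range(n):
        if lo < alpha[t] < hi and alpha[t] > 0.0:
            b_sum += -y[t] * G[t]
            n_free += 1
    if n_free > 0:
        b = b_sum / n_free
    else:
        b = 0.5 * (gmax + gmin) if (i != -1 and j != -1) else 0.0
    return alpha, b, gap, it, status


@njit(cache=True)
def _solve_active(K, y, active):
    """Solve the equality-constrained KKT system on the active set:
    margins exactly 1 for active points, sum(alpha * y) = 0.

    Returns (alpha_full, b); inactive alphas are 0.  A tiny ridge keeps the
    system nonsingular under duplicated points; it perturbs the solution far
    below the solver tolerances.
    """
    n = K.shape[0]
    idx = np.flatnonzero(active)
    m = idx.size
    M = np.empty((m + 1, m + 1))
    tr = 0.0
    for a in range(m):
        ia = idx[a]
        for b_ in range(m):
            ib = idx[b_]
            M[a, b_] = y[ia] * y[ib] * K[ia, ib]
        tr += K[ia, ia]
        M[a, m] = y[ia]
        M[m, a] = y[ia]
    M[m, m] = 0.0
    ridge = 1e-12 * (tr / m + 1.0)
    for a in range(m):
        M[a, a] += ridge
    rhs = np.ones(m + 1)
    rhs[m] = 0.0
    sol = np.linalg.solve(M, rhs)
    alpha = np.zeros(n)
    for a in range(m):
        alpha[idx[a]] = sol[a]
    return alpha, sol[m]


@njit(cache=True)
def hard_margin_solve(K, y, active, max_cycles=400):
    """Hard-margin dual via an active-set method with KKT certification.

    ``active`` is the starting active set (all-ones for a cold start; a
    previous solution's support set for a warm start) and is modified in
    place.  The loop prunes points whose dual coefficient goes negative and
    re-adds inactive points whose margin falls below 1.  Chunked moves
    converge in a handful of cycles on p >> n data; after 40 cycles the
    moves drop to one element at a time to break potential cycling.  The
    result is only returned with status OK when the full KKT conditions
    hold, so a nonzero status (cycling cap, typically non-separable data)
    lets the caller fall back to the SMO path.

    Returns (alpha, b, status).
    """
    n = K.shape[0]
    alpha = np.zeros(n)
    b = 0.0
    tol_m = 1e-8
    for cycle in range(max_cycles):
        # both classes must stay represented
        npos = 0
        nneg = 0
        for t in range(n):
            if active[t]:
                if y[t] > 0:
                    npos += 1
                else:
                    nneg += 1
        if npos == 0 or nneg == 0:
            return alpha, b, MAX_ITER
        alpha, b = _solve_active(K, y, active)
        amax = 0.0
        for t in range(n):
            if abs(alpha[t]) > amax:
                amax = abs(alpha[t])
        tol_a = 1e-10 * (amax + 1.0)
        single = cycle >= 40
        # prune negative dual coefficients
        worst = 0.0
        worst_i = -1
        n_removed = 0
        for t in range(n):
            if active[t] and alpha[t] < -tol_a:
                if single:
                    if alpha[t] < worst:
                        worst = alpha[t]
                        worst_i = t
                else:
                    active[t] = False
                    n_removed += 1
        if single and worst_i >= 0:
            active[worst_i] = False
            n_removed = 1
        if n_removed > 0:
            continue
        # margins of inactive points
        f = np.empty(n)
        for t in range(n):
            s = b
            for u in range(n):
                if active[u]:
                    s += alpha[u] * y[u] * K[u, t]
            f[t] = s
        worst_m = 1.0
        worst_i = -1
        n_added = 0
        for t in range(n):
            if not active[t] and y[t] * f[t] < 1.0 - tol_m:
                if single:
                    if y[t] * f[t] < worst_m:
                        worst_m = y[t] * f[t]
                        worst_i = t
                else:
                    active[t] = True
                    n_added += 1
        if single and worst_i >= 0:
            active[worst_i] = True
            n_added = 1
        if n_added > 0:
            continue
        # KKT certified: alpha >= 0, all margins >= 1 - tol, actives at 1
        return alpha, b, OK
    return alpha, b, MAX_ITER


@njit(cache=True)
def dual_solve(K, y, C, eps, max_iter):
    """Hard-margin active-set path for C >= HARD_C (SMO fallback if it
    cycles); plain SMO for moderate C."""
    if C >= HARD_C:
        active = np.ones(K.shape[0], np.bool_)
        alpha, b, status = hard_margin_solve(K, y, active)
        if status == OK:
            return alpha, b, 0.0, 0, OK
    return smo_solve(K, y, C, eps, max_iter)


@njit(cache=True)
def train_margins(K, y, alpha, b):
    """Functional margins y_i f(x_i) for the training points."""
    n = K.shape[0]
    m = np.empty(n)
    for t in range(n):
        s = b
        for u in range(n):
            s += alpha[u] * y[u] * K[u, t]
        m[t] = y[t] * s
    return m


@njit(cache=True)
def _fit_scores(K, y, C, eps, max_iter):
    """Fit on the full Gram matrix and return (alpha, b, f) with f the
    decision values on the training points."""
    alpha, b, gap, it, status = dual_solve(K, y, C, eps, max_iter)
    n = K.shape[0]
    f = np.empty(n)
    for t in range(n):
        s = b
        for u in range(n):
            s += alpha[u] * y[u] * K[u, t]
        f[t] = s
    return alpha, b, f, status


@njit(cache=True)
def loo_scores(K, y, C, eps, max_iter, kkt_tol, shortcut):
    """Leave-one-out decision scores on a precomputed Gram matrix.

    With ``shortcut`` enabled, a left-out subject that is strictly outside
    the full-model margin (alpha ~ 0 and y f > 1 + kkt_tol) reuses the
    full-model score: removing a non-support vector leaves the maximum-margin
    solution unchanged.  Otherwise the fold is retrained from scratch.

    Returns ``(scores, status)``; status is nonzero if any fit hit the
    iteration cap.
    """
    n = K.shape[0]
    scores = np.empty(n)
    worst = OK

    alpha_f, b_f, f_full, st = _fit_scores(K, y, C, eps, max_iter)
    if st != OK:
        worst = st
    a_max = alpha_f.max()
    sv_tol = 1e-6 * a_max if a_max > 0 else 0.0

    hard = C >= HARD_C
    idx = np.empty(n - 1, np.int64)
    Ksub = np.empty((n - 1, n - 1))
    ysub = np.empty(n - 1, y.dtype)
    active = np.empty(n - 1, np.bool_)
    for i in range(n):
        if shortcut and alpha_f[i] <= sv_tol and y[i] * f_full[i] > 1.0 + kkt_tol:
            scores[i] = f_full[i]
            continue
        k = 0
        for t in range(n):
            if t != i:
                idx[k] = t
                k += 1
        for a_ in range(n - 1):
            ysub[a_] = y[idx[a_]]
            for b_ in range(n - 1):
                Ksub[a_, b_] = K[idx[a_], idx[b_]]
        if hard:
            # warm start from the full model's support set
            for a_ in range(n - 1):
                active[a_] = alpha_f[idx[a_]] > sv_tol
            alpha, b, st = hard_margin_solve(Ksub, ysub, active)
            if st != OK:  # pragma: no cover - cycling fallback
                alpha, b, gap, it, st = smo_solve(Ksub, ysub, C, eps, max_iter)
        else:
            alpha, b, gap, it, st = smo_solve(Ksub, ysub, C, eps, max_iter)
        if st != OK:
            worst = st
        s = b
        for a_ in range(n - 1):
            s += alpha[a_] * ysub[a_] * K[idx[a_], i]
        scores[i] = s
    return scores, worst


@njit(cache=True)
def permutation_loo_scores(K, perm_labels, C, eps, max_iter, kkt_tol, shortcut):
    """LOO decision scores for each row of permuted labels.

    ``perm_labels`` has shape (n_perm, n); returns an (n_perm, n) score
    matrix.  The Gram matrix never changes under label permutation, so it is
    computed once by the caller.
    """
    n_perm = perm_labels.shape[0]
    n = perm_labels.shape[1]
    out = np.empty((n_perm, n))
    for r in range(n_perm):
        s, _ = loo_scores(K, perm_labels[r], C, eps, max_iter, kkt_tol, shortcut)
        out[r] = s
    return out


@njit(cache=True)
def permutation_weight_counts(K, X, perm_labels, w_obs_abs, C, eps, max_iter):
    """Count, per voxel, permuted full-data weights with |w_perm| >= |w_obs|.

    Each permutation refits on the full Gram matrix and materialises its
    weight vector w = X' (alpha * y) once.
    """
    n_perm = perm_labels.shape[0]
    n, p = X.shape
    counts = np.zeros(p, np.int64)
    for r in range(n_perm):
        y = perm_labels[r]
        alpha, b, gap, it, st = dual_solve(K, y, C, eps, max_iter)
        coef = alpha * y.astype(np.float64)
        w = X.T @ coef
        for v in range(p):
            if abs(w[v]) >= w_obs_abs[v]:
                counts[v] += 1
    return counts
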