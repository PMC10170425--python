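"""Coordinate-descent LASSO path solver on precomputed Gram matrices.

Solves ``min_beta 1/(2n) ||y - X beta||^2 + alpha ||beta||_1`` for a
descending grid of penalties with warm starts, using only the centered
second moments ``G = X'X / n`` and ``c = X'y / n``. Working on the Gram
matrix makes a path fit O(p^2) per sweep independent of n, which is what
lets the bootstrap re-run the full estimation procedure thousands of
times. The kernels are numba-compiled with hand-rolled inner loops (for
p ~ 13 a BLAS dispatch per dot product costs more than the arithmetic);
the gradient vector is maintained incrementally so a sweep only pays for
coordinates that actually move.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False, fastmath=False)
def _cd_grid(G, c, alphas, tol, max_sweeps, beta, q, B):
    """Warm-started cyclic CD along a descending grid, writing rows of B.

    ``beta`` is the running solution and ``q = c - G beta`` the running
    negative gradient of the smooth part; both are updated in place.
    Returns True if every grid point converged within the sweep budget.
    """
    p = G.shape[0]
    na = alphas.shape[0]
    converged = True
    for a in range(na):
        alpha = alphas[a]
        for _sweep in range(max_sweeps):
            delta = 0.0
            for k in range(p):
                gkk = G[k, k]
                if gkk <= 0.0:
                    continue
                r = q[k] + gkk * beta[k]
                if r > alpha:
                    bk = (r - alpha) / gkk
                elif r < -alpha:
                    bk = (r + alpha) / gkk
                else:
                    bk = 0.0
                d = bk - beta[k]
                if d != 0.0:
                    ad = abs(d)
                    if ad > delta:
                        delta = ad
                    beta[k] = bk
                    for l in range(p):
                        q[l] -= G[l, k] * d
            if delta < tol:
                break
        else:
            converged = False
        for k in range(p):
            B[a, k] = beta[k]
    return converged


@njit(cache=False, fastmath=False)
def cd_path(G, c, alphas, tol, max_sweeps):
    """Coefficient path of the penalized regression on Gram moments.

    Parameters
    ----------
    G : (p, p) centered Gram matrix X'X/n
    c : (p,) centered cross-moment X'y/n
    alphas : (na,) strictly descending penalties
    tol : convergence tolerance on the max absolute coefficient update
    max_sweeps : sweep budget per grid point

    Returns
    -------
    B : (na, p) coefficients at each penalty
    converged : True if every grid point converged within the budget
    """
    p = G.shape[0]
    na = alphas.shape[0]
    B = np.zeros((na, p))
    beta = np.zeros(p)
    q = c.copy()
    converged = _cd_grid(G, c, alphas, tol, max_sweeps, beta, q, B)
    return B, converged


@njit(cache=False, fastmath=False)
def cv_fold_mse(
    G_tr, C_tr, xbar_tr, ybar_tr,
    S2_te, S1_te, Sy_te, s1y_te, Syy_te, m_te,
    alphas_all, tol, max_sweeps,
):
    """Cross-validation MSE curves for every (outcome node, fold) pair.

    Fits the full penalty path on each fold's training moments (warm
    starts) and scores held-out prediction MSE from the test fold's raw
    moments, so no per-row work happens inside the CV loop. Shapes:
    training moments ``G_tr (F,p,p)``, ``C_tr (F,N,p)``,
    ``xbar_tr (F,p)``, ``ybar_tr (F,N)``; test-fold raw moments
    ``S2_te (F,p,p)``, ``S1_te (F,p)``, ``Sy_te (F,N,p)``,
    ``s1y_te (F,N)``, ``Syy_te (F,N)``, ``m_te (F,)``; penalty grids
    ``alphas_all (N, na)``.

    Returns ``(fold_mse (N, F, na), converged)``.
    """
    F, N, p = C_tr.shape
    na = alphas_all.shape[1]
    fold_mse = np.empty((N, F, na))
    beta = np.zeros(p)
    q = np.zeros(p)
    converged = True
    for j in range(N):
        for f in range(F):
            G = G_tr[f]
            c = C_tr[f, j]
            for k in range(p):
                beta[k] = 0.0
                q[k] = c[k]
            m = m_te[f]
            for a in range(na):
                alpha = alphas_all[j, a]
                for _sweep in range(max_sweeps):
                    delta = 0.0
                    for k in range(p):
                        gkk = G[k, k]
                        if gkk <= 0.0:
                            continue
                        r = q[k] + gkk * beta[k]
                        if r > alpha:
                            bk = (r - alpha) / gkk
                        elif r < -alpha:
                            bk = (r + alpha) / gkk
                        else:
                            bk = 0.0
                        d = bk - beta[k]
                        if d != 0.0:
                            ad = abs(d)
                            if ad > delta:
                                delta = ad
                            beta[k] = bk
                            for l in range(p):
                                q[l] -= G[l, k] * d
                    if delta < tol:
                        break
                else:
                    converged = False
                # held-out SSE from the test fold's raw moments:
                # yhat = a0 + x . beta with a0 from the training fold
                a0 = ybar_tr[f, j]
                bS1 = 0.0
                bSy = 0.0
                bS2b = 0.0
                for u in range(p):
                    bu = beta[u]
                    if bu != 0.0:
                        a0 -= xbar_tr[f, u] * bu
                        bS1 += S1_te[f, u] * bu
                        bSy += Sy_te[f, j, u] * bu
                        acc = 0.0
                        for v in range(p):
                            if beta[v] != 0.0:
                                acc += S2_te[f, u, v] * beta[v]
                        bS2b += bu * acc
                sse = (
                    Syy_te[f, j]
                    - 2.0 * (a0 * s1y_te[f, j] + bSy)
                    + m * a0 * a0
                    + 2.0 * a0 * bS1
                    + bS2b
                )
                fold_mse[j, f, a] = sse / m
    return fold_mse, converged


def penalized_objective(X: np.ndarray, y: np.ndarray, beta: np.ndarray, alpha: float) -> float:
    """The LASSO objective 1/(2n)||y - X beta||^2 + alpha ||beta||_1."""
    n = len(y)
    resid = y - X @ beta
    return float(resid @ resid / (2.0 * n) + alpha * np.abs(beta).sum())
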