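"""Numba kernels for BIC-based Metropolis graph search with edge priors.

The marginal likelihood of a graph is approximated by exp(-BIC/2) with the
Gaussian log-likelihood of the support-constrained MLE (covariance selection:
Sigma-hat matches S on the diagonal and on supported edges, Theta is zero off
support). The restricted MLE is computed by iterative proportional scaling
(IPS) over edge and vertex cliques with Woodbury covariance updates, warm
started from the current state so that single-edge toggles are cheap.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _chol_logdet(A):
    """Cholesky log-determinant; returns (ok, logdet) without raising."""
    p = A.shape[0]
    Lc = np.zeros((p, p))
    logdet = 0.0
    for i in range(p):
        s = A[i, i]
        for k in range(i):
            s -= Lc[i, k] * Lc[i, k]
        if s <= 1e-12:
            return False, 0.0
        Lc[i, i] = np.sqrt(s)
        logdet += 2.0 * np.log(Lc[i, i])
        for j in range(i + 1, p):
            t = A[j, i]
            for k in range(i):
                t -= Lc[j, k] * Lc[i, k]
            Lc[j, i] = t / Lc[i, i]
    return True, logdet


@njit(cache=True)
def _apply_block(Theta, Sigma, i, j, d00, d01, d11):
    """Theta += U D U' on clique {i, j}; Sigma updated via Woodbury.

    D = [[d00, d01], [d01, d11]] (use i == j with d01 = d11 = 0 for a
    singleton update). Returns False if the implied 2x2 solve is singular.
    """
    p = Theta.shape[0]
    if i == j:
        d = d00
        denom = 1.0 + d * Sigma[i, i]
        if abs(denom) < 1e-300:
            return False
        Theta[i, i] += d
        coef = d / denom
        col = Sigma[:, i].copy()
        for a in range(p):
            va = coef * col[a]
            for b in range(p):
                Sigma[a, b] -= va * col[b]
        return True
    # M = (I + D Saa)^{-1} D  with Saa = Sigma[[i,j]][:, [i,j]]
    s00 = Sigma[i, i]
    s01 = Sigma[i, j]
    s11 = Sigma[j, j]
    a00 = 1.0 + d00 * s00 + d01 * s01
    a01 = d00 * s01 + d01 * s11
    a10 = d01 * s00 + d11 * s01
    a11 = 1.0 + d01 * s01 + d11 * s11
    det = a00 * a11 - a01 * a10
    if abs(det) < 1e-300:
        return False
    # inv(A) @ D
    m00 = (a11 * d00 - a01 * d01) / det
    m01 = (a11 * d01 - a01 * d11) / det
    m10 = (-a10 * d00 + a00 * d01) / det
    m11 = (-a10 * d01 + a00 * d11) / det
    Theta[i, i] += d00
    Theta[i, j] += d01
    Theta[j, i] += d01
    Theta[j, j] += d11
    ci = Sigma[:, i].copy()
    cj = Sigma[:, j].copy()
    for a in range(p):
        ui = ci[a] * m00 + cj[a] * m10
        uj = ci[a] * m01 + cj[a] * m11
        for b in range(p):
            Sigma[a, b] -= ui * ci[b] + uj * cj[b]
    return True


@njit(cache=True)
def _edge_update(Theta, Sigma, S, i, j):
    """IPS clique update forcing Sigma to match S on the {i, j} block."""
    s00 = S[i, i]
    s01 = S[i, j]
    s11 = S[j, j]
    det_s = s00 * s11 - s01 * s01
    if det_s <= 1e-300:
        return False
    t00 = Sigma[i, i]
    t01 = Sigma[i, j]
    t11 = Sigma[j, j]
    det_t = t00 * t11 - t01 * t01
    if det_t <= 1e-300:
        return False
    # inv(S_AA) - inv(Sigma_AA)
    d00 = s11 / det_s - t11 / det_t
    d01 = -s01 / det_s + t01 / det_t
    d11 = s00 / det_s - t00 / det_t
    return _apply_block(Theta, Sigma, i, j, d00, d01, d11)


@njit(cache=True)
def ips_fit(Theta, Sigma, S, A, tol, max_sweeps):
    """Iterative proportional scaling to the support-constrained MLE.

    A is the (symmetric, 0/1) adjacency; Theta/Sigma are warm starts updated
    in place. Returns (converged, residual).
    """
    p = S.shape[0]
    res = 0.0
    for sweep in range(max_sweeps):
        for i in range(p):
            if abs(Sigma[i, i] - S[i, i]) > tol * 0.1:
                d = 1.0 / S[i, i] - 1.0 / Sigma[i, i]
                _apply_block(Theta, Sigma, i, i, d, 0.0, 0.0)
        for i in range(p):
            for j in range(i + 1, p):
                if A[i, j] != 0 and abs(Sigma[i, j] - S[i, j]) > tol * 0.1:
                    _edge_update(Theta, Sigma, S, i, j)
        res = 0.0
        for i in range(p):
            r = abs(Sigma[i, i] - S[i, i])
            if r > res:
                res = r
            for j in range(i + 1, p):
                if A[i, j] != 0:
                    r = abs(Sigma[i, j] - S[i, j])
                    if r > res:
                        res = r
        if res <= tol:
            return True, res
    return False, res


@njit(cache=True)
def _graph_neg2_loglik(Theta, S, n):
    """-2 log-likelihood (up to constants) of the fitted precision."""
    p = S.shape[0]
    ok, logdet = _chol_logdet(Theta)
    if not ok:
        return False, 0.0
    tr = 0.0
    for i in range(p):
        for j in range(p):
            tr += S[i, j] * Theta[j, i]
    return True, -n * (logdet - tr)


@njit(cache=True)
def mcmc_kernel(S, n, prior, n_iter, burnin, seed, tol, max_sweeps, A0):
    """Metropolis single-edge-toggle search over graph structures.

    Acceptance ratio exp(-(BIC_new - BIC_old)/2) times Bernoulli prior odds
    for the toggled edge. Returns (edge_counts, n_kept, n_accept, n_reject_pd,
    A_final) where edge_counts accumulates post-burn-in adjacency states.
    """
    np.random.seed(seed)
    p = S.shape[0]
    A = A0.copy()
    # initial restricted MLE from a diagonal start
    Theta = np.zeros((p, p))
    Sigma = np.zeros((p, p))
    for i in range(p):
        Theta[i, i] = 1.0 / S[i, i]
        Sigma[i, i] = S[i, i]
    ips_fit(Theta, Sigma, S, A, tol, 200)
    ok, neg2ll = _graph_neg2_loglik(Theta, S, n)
    n_edges = 0
    for i in range(p):
        for j in range(i + 1, p):
            if A[i, j] != 0:
                n_edges += 1
    bic = neg2ll + n_edges * np.log(n)

    counts = np.zeros((p, p))
    n_kept = 0
    n_accept = 0
    n_reject_pd = 0
    npairs = p * (p - 1) // 2

    for it in range(n_iter):
        t = np.random.randint(npairs)
        # decode pair index
        i = 0
        acc = p - 1
        while t >= acc:
            t -= acc
            i += 1
            acc = p - 1 - i
        j = i + 1 + t

        adding = A[i, j] == 0
        Ap = A.copy()
        Tp = Theta.copy()
        Sp = Sigma.copy()
        valid = True
        if adding:
            Ap[i, j] = 1
            Ap[j, i] = 1
            valid = _edge_update(Tp, Sp, S, i, j)
        else:
            Ap[i, j] = 0
            Ap[j, i] = 0
            d = -Tp[i, j]
            valid = _apply_block(Tp, Sp, i, j, 0.0, d, 0.0)
        if valid:
            conv, _ = ips_fit(Tp, Sp, S, Ap, tol, max_sweeps)
            valid = conv
        if valid:
            ok2, neg2ll_p = _graph_neg2_loglik(Tp, S, n)
            valid = ok2
        if not valid:
            n_reject_pd += 1
        else:
            ne_p = n_edges + (1 if adding else -1)
            bic_p = neg2ll_p + ne_p * np.log(n)
            pij = prior[i, j]
            log_odds = np.log(pij) - np.log(1.0 - pij)
            if not adding:
                log_odds = -log_odds
            log_alpha = -(bic_p - bic) / 2.0 + log_odds
            if np.log(np.random.random()) < log_alpha:
                A = Ap
                Theta = Tp
                Sigma = Sp
                bic = bic_p
                n_edges = ne_p
                n_accept += 1
        if it >= burnin:
            counts += A
            n_kept += 1
        # periodic refresh against Woodbury drift
        if (it + 1) % 2000 == 0:
            Sigma = np.linalg.inv(Theta)
            ips_fit(Theta, Sigma, S, A, tol, 200)
            okr, neg2ll_r = _graph_neg2_loglik(Theta, S, n)
            if okr:
                bic = neg2ll_r + n_edges * np.log(n)
    return counts, n_kept, n_accept, n_reject_pd, A


def restricted_mle(S: np.ndarray, A: np.ndarray, tol: float = 1e-9,
                   max_sweeps: int = 500) -> tuple[np.ndarray, bool]:
    """Support-constrained Gaussian MLE of the precision matrix (IPS)."""
    p = S.shape[0]
    Theta = np.diag(1.0 / np.diag(S)).copy()
    Sigma = np.diag(np.diag(S)).copy()
    conv, _ = ips_fit(Theta, Sigma, S, A.astype(np.int8), tol, max_sweeps)
    return Theta, bool(conv)


def graph_bic(S: np.ndarray, A: np.ndarray, n: int, tol: float = 1e-9) -> float:
    """BIC of a graph: -2 max-loglik (restricted MLE) + |E| log n."""
    Theta, conv = restricted_mle(S, A, tol=tol)
    ok, neg2ll = _graph_neg2_loglik(Theta, S, float(n))
    if not ok or not conv:
        return np.inf
    n_edges = int(np.triu(A, 1).sum())
    return float(neg2ll + n_edges * np.log(n))
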