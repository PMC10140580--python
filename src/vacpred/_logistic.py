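"""Small logistic-regression engine for likelihood-ratio candidate scoring.

Forward selection scores every unselected candidate at every step, across
cross-validation folds, which means thousands of small maximum-likelihood
logistic fits. All candidate models at one step share the same base design
(intercept + selected columns) and differ by a single column, so the Newton
iterations are batched across candidates with einsum-built Hessians. A tiny
ridge keeps the Hessian invertible; fits that fail to converge (complete
separation) are refit with a stronger penalty and flagged.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

_RIDGE = 1e-8
_SEPARATION_RIDGE = 1e-3
_MAX_ITER = 40
_TOL = 1e-9


def log_likelihood(eta: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Bernoulli log-likelihood given linear predictor(s); sums over axis 0."""
    return np.sum(y[:, None] * eta - np.logaddexp(0.0, eta), axis=0) if eta.ndim == 2 \
        else float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(
    D: np.ndarray, y: np.ndarray, ridge: float = _RIDGE
) -> tuple[np.ndarray, float, bool]:
    """Newton fit of a logistic model (``D`` includes the intercept column).

    Returns (beta, unpenalised log-likelihood, converged).
    """
    n, p = D.shape
    beta = np.zeros(p)
    pbar = min(max(y.mean(), 1e-6), 1 - 1e-6)
    beta[0] = np.log(pbar / (1 - pbar))
    converged = False
    for _ in range(_MAX_ITER):
        eta = D @ beta
        mu = expit(eta)
        w = mu * (1 - mu) + 1e-12
        g = D.T @ (y - mu) - ridge * beta
        H = (D * w[:, None]).T @ D + ridge * np.eye(p)
        delta = np.linalg.solve(H, g)
        beta += delta
        if np.max(np.abs(delta)) < _TOL:
            converged = True
            break
    return beta, float(log_likelihood(D @ beta, y)), converged


def batched_candidate_loglik(
    B: np.ndarray,
    C: np.ndarray,
    y: np.ndarray,
    base_beta: np.ndarray,
    ridge: float = _RIDGE,
) -> tuple[np.ndarray, np.ndarray]:
    """Log-likelihood of ``[B, c_j]`` logistic models for every column of C.

    ``B`` is the shared base design (intercept + selected features);
    ``base_beta`` warm-starts the shared coefficients. Returns the per
    -candidate unpenalised log-likelihoods and a boolean mask of candidates
    that needed the separation fallback penalty.
    """
    n, p = B.shape
    m = C.shape[1]
    beta = np.zeros((m, p + 1))
    beta[:, :p] = base_beta
    active = np.ones(m, dtype=bool)
    eye = np.eye(p + 1)
    for _ in range(_MAX_ITER):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        Ca = C[:, idx]
        ba = beta[idx]
        eta = B @ ba[:, :p].T + Ca * ba[:, p]
        mu = expit(eta)
        w = mu * (1 - mu) + 1e-12
        r = y[:, None] - mu
        gB = B.T @ r - ridge * ba[:, :p].T  # (p, k)
        gc = np.sum(Ca * r, axis=0) - ridge * ba[:, p]
        HBB = np.einsum("np,nm,nq->mpq", B, w, B, optimize=True)
        HBc = np.einsum("np,nm,nm->mp", B, w, Ca, optimize=True)
        Hcc = np.sum(w * Ca * Ca, axis=0)
        H = np.empty((idx.size, p + 1, p + 1))
        H[:, :p, :p] = HBB
        H[:, :p, p] = HBc
        H[:, p, :p] = HBc
        H[:, p, p] = Hcc
        H += ridge * eye
        g = np.concatenate([gB.T, gc[:, None]], axis=1)
        delta = np.linalg.solve(H, g[..., None])[..., 0]
        beta[idx] += delta
        done = np.max(np.abs(delta), axis=1) < _TOL
        active[idx[done]] = False
    # (quasi-)separation: non-convergence or a diverging standardised slope
    suspect = active | (np.abs(beta[:, p]) > 10.0)
    penalized = np.zeros(m, dtype=bool)
    if suspect.any() and ridge < _SEPARATION_RIDGE:
        # fallback: refit the stragglers with a stronger penalty
        llf_fallback, _ = batched_candidate_loglik(
            B, C[:, suspect], y, base_beta, ridge=_SEPARATION_RIDGE
        )
        penalized[suspect] = True
    eta = B @ beta[:, :p].T + C * beta[:, p]
    llf = log_likelihood(eta, y)
    if suspect.any() and ridge < _SEPARATION_RIDGE:
        llf[suspect] = llf_fallback
    return llf, penalized
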