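"""Breslow partial likelihood for the Cox model: log-likelihood, gradient,
Hessian, and a damped Newton–Raphson solver with optional ridge penalty.

Used for unpenalized fits (the λ=0 contract), the pure-ridge arm of the
elastic-net grid (α=0), and cross-validated partial-likelihood deviance.
Tied event times are handled with the Breslow approximation; censored
observations at an event time remain in that time's risk set.
"""

from __future__ import annotations

import dataclasses

import numpy as np


def _risk_index(time: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Ascending sort order and, per sorted row, the first index of its
    tied-time group (the start of that time's risk set)."""
    order = np.argsort(time, kind="stable")
    t_s = time[order]
    first = np.searchsorted(t_s, t_s, side="left")
    return order, first


def breslow_loglik(eta: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Breslow log partial likelihood of a linear predictor."""
    eta = np.asarray(eta, float)
    order, first = _risk_index(np.asarray(time, float))
    eta_s = eta[order] - eta.max()
    e_s = np.asarray(event)[order].astype(bool)
    w = np.exp(eta_s)
    rc = np.cumsum(w[::-1])[::-1]  # rc[i] = sum_{j >= i} w_j
    W = rc[first]
    return float(np.sum(eta_s[e_s] - np.log(W[e_s])))


def loglik_grad_hess(
    beta: np.ndarray,
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    *,
    hess: bool = True,
) -> tuple[float, np.ndarray, np.ndarray | None]:
    """Log partial likelihood with analytic gradient and (optionally) Hessian."""
    X = np.asarray(X, float)
    n, p = X.shape
    order, first = _risk_index(np.asarray(time, float))
    Xs = X[order]
    eta = Xs @ beta
    eta -= eta.max()
    e_s = np.asarray(event)[order].astype(bool)
    w = np.exp(eta)
    wx = w[:, None] * Xs
    rc_w = np.cumsum(w[::-1])[::-1]
    rc_wx = np.cumsum(wx[::-1], axis=0)[::-1]
    W = rc_w[first]
    S1 = rc_wx[first]
    mu = S1 / W[:, None]

    ll = float(np.sum(eta[e_s] - np.log(W[e_s])))
    grad = Xs[e_s].sum(axis=0) - mu[e_s].sum(axis=0)
    if not hess:
        return ll, grad, None

    # Hessian: iterate tied-time groups from the latest time backwards,
    # maintaining S2 = sum over the risk set of w * x x^T.
    H = np.zeros((p, p))
    starts = np.unique(first)
    ends = np.append(starts[1:], n)
    S2 = np.zeros((p, p))
    prev = n
    for s, grp_end in zip(starts[::-1], ends[::-1]):
        blk = slice(s, prev)
        S2 += Xs[blk].T @ wx[blk]
        prev = s
        d = int(e_s[s:grp_end].sum())  # events in this tied-time group
        if d:
            m = mu[s]
            H += d * (S2 / W[s] - np.outer(m, m))
    return ll, grad, H


@dataclasses.dataclass
class NewtonResult:
    beta: np.ndarray
    loglik: float
    converged: bool
    n_iter: int


def newton_cox(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    *,
    l2: float = 0.0,
    beta0: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-9,
) -> NewtonResult:
    """Damped Newton–Raphson maximizer of the (ridge-penalized) Breslow
    partial likelihood: maximizes ``loglik(beta) - l2/2 * ||beta||^2``.
    """
    X = np.asarray(X, float)
    n, p = X.shape
    if int(np.sum(event)) < 1:
        raise ValueError("at least one event is required to fit a Cox model")
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, float).copy()
    eye = np.eye(p)

    def objective(b: np.ndarray) -> float:
        return -breslow_loglik(X @ b, time, event) + 0.5 * l2 * float(b @ b)

    f = objective(beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        ll, g, H = loglik_grad_hess(beta, X, time, event)
        g_pen = -g + l2 * beta
        H_pen = H + l2 * eye
        if np.max(np.abs(g_pen)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(H_pen + 1e-10 * eye, g_pen)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H_pen, g_pen, rcond=None)[0]
        # backtracking line search on the penalized objective
        alpha = 1.0
        for _ in range(40):
            cand = beta - alpha * step
            fc = objective(cand)
            if fc <= f - 1e-10 * alpha * float(g_pen @ step):
                beta, f = cand, fc
                break
            alpha *= 0.5
        else:
            break  # no descent possible at machine precision
    else:
        it = max_iter
    if not converged:
        _, g, _ = loglik_grad_hess(beta, X, time, event, hess=False)
        converged = bool(np.max(np.abs(-g + l2 * beta)) < max(tol, 1e-6))
    return NewtonResult(
        beta=beta, loglik=breslow_loglik(X @ beta, time, event),
        converged=converged, n_iter=it,
    )


def vvh_deviance(
    beta: np.ndarray,
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    train_idx: np.ndarray,
) -> float:
    """Verweij–Van Houwelingen cross-validated partial-likelihood deviance
    of a held-out fold: ``-2 * (ll_full(beta) - ll_train(beta))``.

    Evaluates the full-data and training-fold Breslow log partial
    likelihoods at the training-fold estimate; their difference is the
    held-out fold's contribution without breaking risk sets.
    """
    eta = np.asarray(X, float) @ beta
    ll_full = breslow_loglik(eta, time, event)
    ll_train = breslow_loglik(eta[train_idx], np.asarray(time)[train_idx],
                              np.asarray(event)[train_idx])
    return -2.0 * (ll_full - ll_train)
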