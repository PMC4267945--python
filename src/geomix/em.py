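"""EM estimation of ancestor locations (and optionally proportions) for a
haploid admixed genome.

The E step is the scaled forward-backward pass of :mod:`geomix.hmm`. The
M step separates over ancestors: each location x_j maximizes the
posterior-weighted logistic log-likelihood

    Q_j(x) = sum_i C_ij * [ h_i log f_i(x) + (1 - h_i) log(1 - f_i(x)) ]

which is concave in x, solved by damped Newton on the analytic gradient and
2x2 Hessian. The proportion update maximizes

    sum_j (sum_i D_ij) log pi_j + sum_{i,j} E_ij log(1 - tau_i (1 - pi_j))

over the simplex. By default proportions are held fixed (uniform), which
mirrors the usual study design where the contribution of each ancestry is
treated as known; pass ``pi_fixed=False`` to optimize them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .gradients import GradientSet
from .hmm import (AncestryModel, PosteriorTables, TransitionModel,
                  forward_backward, _clean_haplotype)

__all__ = ["EMResult", "q_location", "m_step_locations", "m_step_proportions", "run_em"]


@dataclass
class EMResult:
    """Outcome of one EM fit (best restart)."""

    model: AncestryModel
    loglik: float
    loglik_trace: np.ndarray
    n_iter: int
    converged: bool
    restarts_used: int
    posteriors: PosteriorTables


def q_location(x, w, h01, grad: GradientSet, idx) -> float:
    """The per-ancestor expected complete-data objective Q_j at location x.

    ``w`` are posterior weights and ``h01`` the observed alleles, both
    restricted to the non-missing sites ``idx``.
    """
    u = grad.a[idx] @ np.asarray(x, dtype=float) + grad.b[idx]
    # h log f + (1-h) log(1-f) = -log(1 + exp(u * (1 - 2h)))  up to sign of u
    sgn = 1.0 - 2.0 * h01
    return float(-(w * np.logaddexp(0.0, sgn * u)).sum())


def _newton_location(x0, w, h01, A, b, max_iter=100, tol=1e-12):
    """Damped Newton ascent of the weighted logistic log-likelihood in x.

    Falls back to a gradient step when the 2x2 Hessian is (numerically)
    singular. Guaranteed not to decrease the objective.
    """
    x = np.asarray(x0, dtype=float).copy()
    sgn = 1.0 - 2.0 * h01

    def obj(xx):
        return float(-(w * np.logaddexp(0.0, sgn * (A @ xx + b))).sum())

    f_cur = obj(x)
    for _ in range(max_iter):
        p = expit(A @ x + b)
        r = w * (h01 - p)
        g = A.T @ r
        if np.linalg.norm(g) < 1e-12 * (1.0 + len(w)):
            break
        wpp = w * p * (1.0 - p)
        H = -(A.T * wpp) @ A
        try:
            step = np.linalg.solve(H, -g)
            if step @ g <= 0:  # not an ascent direction; revert to gradient
                step = g
        except np.linalg.LinAlgError:
            step = g
        scale = 1.0
        improved = False
        for _ in range(50):
            cand = x + scale * step
            f_new = obj(cand)
            if f_new >= f_cur:
                improved = f_new > f_cur + tol * (abs(f_cur) + 1.0)
                x, f_cur = cand, f_new
                break
            scale *= 0.5
        else:
            break
        if not improved:
            break
    return x


def m_step_locations(C: np.ndarray, h, grad: GradientSet, X_init: np.ndarray) -> np.ndarray:
    """Update every ancestor location given posterior weights C (L, M).

    Each column is an independent concave 2-D problem. A column with zero
    total weight (no data supports that ancestry) leaves its location
    unchanged, with a warning.
    """
    h = _clean_haplotype(h, grad.n_snps)
    C = np.asarray(C, dtype=float)
    X = np.atleast_2d(np.asarray(X_init, dtype=float)).copy()
    M = X.shape[0]
    if C.shape != (grad.n_snps, M):
        raise ValueError("posterior weight table has the wrong shape")
    obs = h >= 0
    idx = np.flatnonzero(obs)
    if idx.size == 0:
        return X
    A = grad.a[idx]
    b = grad.b[idx]
    h01 = h[idx].astype(float)
    for j in range(M):
        w = C[idx, j]
        if w.sum() <= 0:
            warnings.warn(f"no posterior weight for ancestry {j}; location left unchanged",
                          RuntimeWarning, stacklevel=2)
            continue
        X[j] = _newton_location(X[j], w, h01, A, b)
    return X


def _proportion_objective(pi, d, E, tau):
    """Value and gradient of the proportion Q-function (to maximize)."""
    pi = np.asarray(pi, dtype=float)
    stay = 1.0 - tau[:, None] * (1.0 - pi[None, :])
    stay = np.maximum(stay, 1e-300)
    val = float(d @ np.log(np.maximum(pi, 1e-300)) + (E * np.log(stay)).sum())
    grad = d / np.maximum(pi, 1e-300) + (E * (tau[:, None] / stay)).sum(axis=0)
    return val, grad


def m_step_proportions(D: np.ndarray, E: np.ndarray, trans: TransitionModel) -> np.ndarray:
    """Maximize the proportion Q-function over the probability simplex.

    With every tau_i = 1 the objective is multinomial and the optimum is the
    normalized expected counts; in general it is concave and solved by SLSQP
    with the analytic gradient.
    """
    D = np.asarray(D, dtype=float)
    E = np.asarray(E, dtype=float)
    M = D.shape[1]
    if M == 1:
        return np.array([1.0])
    d = D.sum(axis=0)
    tau = trans.tau
    if d.sum() + E.sum() <= 0:
        return np.full(M, 1.0 / M)
    if np.all(tau >= 1.0 - 1e-12):
        tot = d + E.sum(axis=0)
        return tot / tot.sum()

    uniform = np.full(M, 1.0 / M)

    def neg(pi):
        v, g = _proportion_objective(pi, d, E, tau)
        return -v, -g

    res = minimize(neg, uniform, jac=True, method="SLSQP",
                   bounds=[(1e-9, 1.0)] * M,
                   constraints=[{"type": "eq", "fun": lambda p: p.sum() - 1.0,
                                 "jac": lambda p: np.ones(M)}],
                   options={"maxiter": 200, "ftol": 1e-14})
    pi = np.clip(res.x, 0.0, None)
    pi /= pi.sum()
    # never return something worse than the uniform start
    if _proportion_objective(pi, d, E, tau)[0] < _proportion_objective(uniform, d, E, tau)[0]:
        return uniform
    return pi


def _init_locations(M, box, rng):
    (x1lo, x1hi), (x2lo, x2hi) = box
    return np.column_stack([rng.uniform(x1lo, x1hi, size=M),
                            rng.uniform(x2lo, x2hi, size=M)])


def run_em(h, grad: GradientSet, M: int, trans: TransitionModel, *,
           pi_fixed: bool = True, Pi0=None, restarts: int = 5, seed=None,
           tol: float = 1e-6, max_iter: int = 200, init_box=None,
           X_init=None) -> EMResult:
    """Fit ancestor locations for a haploid genome by EM.

    Parameters
    ----------
    h : length-L haplotype over {0, 1, missing}.
    grad : fitted gradient set (fixed during inference).
    M : number of ancestry locations to infer.
    trans : per-interval switch probabilities.
    pi_fixed : hold proportions at ``Pi0`` (default uniform) instead of
        optimizing them.
    restarts : number of random initializations; the fit with the best final
        log-likelihood wins.
    init_box : bounding box for random initial locations; defaults to the
        gradient set's ``extent`` and finally to the unit square.
    X_init : explicit initial locations (overrides restarts > 1).

    Returns the best :class:`EMResult`; its ``loglik_trace`` is
    non-decreasing up to a 1e-8 tolerance by construction of the M steps.
    """
    h = _clean_haplotype(h, grad.n_snps)
    L = grad.n_snps
    if M < 1:
        raise ValueError("the number of ancestries must be >= 1")
    if M > L:
        raise ValueError("more ancestries than SNPs is not identifiable")
    if Pi0 is None:
        Pi0 = np.full(M, 1.0 / M)
    Pi0 = np.asarray(Pi0, dtype=float)
    if init_box is None:
        init_box = grad.extent if grad.extent is not None else ((-1.0, 1.0), (-1.0, 1.0))
    rng = np.random.default_rng(seed)

    if X_init is not None:
        starts = [np.atleast_2d(np.asarray(X_init, dtype=float))]
    else:
        starts = [_init_locations(M, init_box, rng) for _ in range(max(1, restarts))]

    best = None
    for X0 in starts:
        model = AncestryModel(X=X0, Pi=Pi0.copy(), pi_fixed=pi_fixed)
        trace = []
        converged = False
        post = forward_backward(h, grad, model, trans)
        trace.append(post.loglik)
        for _ in range(max_iter):
            X_new = m_step_locations(post.C, h, grad, model.X)
            Pi_new = model.Pi if pi_fixed else m_step_proportions(post.D, post.E, trans)
            model = AncestryModel(X=X_new, Pi=Pi_new, pi_fixed=pi_fixed)
            post = forward_backward(h, grad, model, trans)
            trace.append(post.loglik)
            if abs(trace[-1] - trace[-2]) <= tol * (abs(trace[-2]) + 1.0):
                converged = True
                break
        result = EMResult(model=model, loglik=trace[-1],
                          loglik_trace=np.asarray(trace), n_iter=len(trace) - 1,
                          converged=converged, restarts_used=len(starts),
                          posteriors=post)
        if best is None or result.loglik > best.loglik:
            best = result
    return best
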