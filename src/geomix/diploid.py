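"""Diploid admixture model: paired paternal/maternal ancestry chains.

The hidden state at locus i is the pair (z_i^p, z_i^m) on an M x N grid:
the paternal chain follows proportions Pi, the maternal chain Omega, and
both share the per-interval switch probabilities tau_i, so the joint
transition kernel is the product of the two haploid redraw kernels. The
genotype g_i in {0, 1, 2} is modeled as two Bernoulli draws, one from the
paternal frequency f_i(x_j) and one from the maternal frequency f_i(y_k):

    P(g_i = 0) = (1 - fx)(1 - fy)
    P(g_i = 1) = fx (1 - fy) + (1 - fx) fy
    P(g_i = 2) = fx fy

EM alternates the joint forward-backward E step with M steps in the
locations (X, Y), then Pi, then Omega. The location objective couples x_j
and y_k only through heterozygous sites (the g_i = 1 term, which is not
concave in general); it is maximized by L-BFGS on the analytic gradient
with a guard that never accepts a decrease. The ``homogeneous`` option
ties X = Y (same ancestries on both sides) by optimizing a single shared
location vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .gradients import GradientSet
from .hmm import MISSING, TransitionModel
from .em import EMResult, m_step_proportions, _init_locations

__all__ = [
    "DiploidAncestryModel",
    "DiploidPosteriors",
    "diploid_emission",
    "diploid_emission_matrix",
    "diploid_forward_backward",
    "diploid_loglikelihood",
    "diploid_m_step_locations",
    "diploid_viterbi",
    "run_em_diploid",
]


def _clean_genotype(g, L: int) -> np.ndarray:
    g = np.asarray(g, dtype=float).ravel()
    if g.size == 0:
        raise ValueError("empty genotype")
    if L is not None and g.size != L:
        raise ValueError(f"genotype length {g.size} does not match the {L}-SNP gradient set")
    out = np.full(g.size, MISSING, dtype=np.int8)
    obs = np.isfinite(g)
    vals = g[obs]
    if np.any(~np.isin(vals, (0.0, 1.0, 2.0))):
        raise ValueError("genotype calls must be 0, 1, 2 or missing")
    out[obs] = vals.astype(np.int8)
    return out


@dataclass
class DiploidAncestryModel:
    """Paternal locations X (M, 2) / proportions Pi and maternal locations
    Y (N, 2) / Omega; ``homogeneous`` requires M == N and X == Y."""

    X: np.ndarray
    Y: np.ndarray
    Pi: np.ndarray = None
    Omega: np.ndarray = None
    homogeneous: bool = False

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        if self.X.shape[1] != 2 or self.Y.shape[1] != 2:
            raise ValueError("ancestor locations must be 2-D map coordinates")
        M, N = self.X.shape[0], self.Y.shape[0]
        if self.Pi is None:
            self.Pi = np.full(M, 1.0 / M)
        if self.Omega is None:
            self.Omega = np.full(N, 1.0 / N)
        self.Pi = np.asarray(self.Pi, dtype=float).ravel()
        self.Omega = np.asarray(self.Omega, dtype=float).ravel()
        for p, n, name in ((self.Pi, M, "Pi"), (self.Omega, N, "Omega")):
            if p.size != n or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
                raise ValueError(f"{name} must be a length-{n} probability vector")
        if self.homogeneous and (M != N or not np.array_equal(self.X, self.Y)):
            raise ValueError("homogeneous ancestry requires M == N and X == Y")

    @property
    def M(self) -> int:
        return self.X.shape[0]

    @property
    def N(self) -> int:
        return self.Y.shape[0]


@dataclass
class DiploidPosteriors:
    """Joint posteriors C (L, M, N), their chain marginals, and the expected
    transition counts feeding each chain's proportion update."""

    C: np.ndarray
    paternal: np.ndarray  # (L, M)
    maternal: np.ndarray  # (L, N)
    D_p: np.ndarray
    E_p: np.ndarray
    D_m: np.ndarray
    E_m: np.ndarray
    loglik: float


def diploid_emission(g_i, fx: float, fy: float) -> float:
    """Two-Bernoulli genotype emission; a missing call contributes 1."""
    if g_i is None or (isinstance(g_i, float) and np.isnan(g_i)) or g_i == MISSING:
        return 1.0
    if not (0.0 < fx < 1.0 and 0.0 < fy < 1.0):
        raise ValueError("allele frequencies must lie strictly inside (0, 1)")
    if g_i == 0:
        return (1.0 - fx) * (1.0 - fy)
    if g_i == 1:
        return fx * (1.0 - fy) + (1.0 - fx) * fy
    if g_i == 2:
        return fx * fy
    raise ValueError(f"genotype must be 0, 1, 2 or missing, got {g_i!r}")


def diploid_emission_matrix(g, grad: GradientSet, X, Y) -> np.ndarray:
    """Emission tensor (L, M, N) over all joint states."""
    g = _clean_genotype(g, grad.n_snps)
    FX = np.atleast_2d(grad.frequencies(np.atleast_2d(np.asarray(X, dtype=float))))
    FY = np.atleast_2d(grad.frequencies(np.atleast_2d(np.asarray(Y, dtype=float))))
    L, M = FX.shape
    N = FY.shape[1]
    E = np.ones((L, M, N))
    m0, m1, m2 = g == 0, g == 1, g == 2
    E[m0] = (1 - FX[m0])[:, :, None] * (1 - FY[m0])[:, None, :]
    E[m1] = (FX[m1][:, :, None] * (1 - FY[m1])[:, None, :]
             + (1 - FX[m1])[:, :, None] * FY[m1][:, None, :])
    E[m2] = FX[m2][:, :, None] * FY[m2][:, None, :]
    return E


def _predict(arr, t, pi, om):
    """Apply both redraw kernels forward: sum_{j,k} A_p(j,j') A_m(k,k') arr[j,k]."""
    tmp = (1.0 - t) * arr + t * pi[:, None] * arr.sum(axis=0)[None, :]
    return (1.0 - t) * tmp + t * tmp.sum(axis=1)[:, None] * om[None, :]


def _backsum(gam, t, pi, om):
    """Apply both kernels backward: sum_{j',k'} A_p(j,j') A_m(k,k') gam[j',k']."""
    tmp = (1.0 - t) * gam + t * (pi @ gam)[None, :]
    return (1.0 - t) * tmp + t * (tmp @ om)[:, None]


def diploid_forward_backward(g, grad: GradientSet, model: DiploidAncestryModel,
                             trans: TransitionModel) -> DiploidPosteriors:
    """Joint-chain scaled forward-backward pass over the M x N state grid."""
    E = diploid_emission_matrix(g, grad, model.X, model.Y)
    L, M, N = E.shape
    if trans.tau.size != L - 1:
        raise ValueError("transition model does not match the number of SNPs")
    pi, om, tau = model.Pi, model.Omega, trans.tau

    alpha = np.empty((L, M, N))
    c = np.empty(L)
    a = pi[:, None] * om[None, :] * E[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for i in range(1, L):
        t = tau[i - 1]
        a = _predict(alpha[i - 1], t, pi, om) * E[i]
        c[i] = a.sum()
        alpha[i] = a / c[i]
    loglik = float(np.log(c).sum())

    beta = np.empty((L, M, N))
    beta[L - 1] = 1.0
    for i in range(L - 2, -1, -1):
        t = tau[i]
        beta[i] = _backsum(E[i + 1] * beta[i + 1], t, pi, om) / c[i + 1]

    C = alpha * beta
    C /= C.sum(axis=(1, 2), keepdims=True)

    # Expected transition counts for each chain. With
    #   gam = E_{i+1} * beta_{i+1} / c_{i+1}
    # the paternal pairwise marginal is
    #   xi^p(j, j') = A_p(j, j') * S(j, j'),
    #   S(j, j') = (1-t) (alpha_i gam^T)(j, j') + t rowsum(alpha_i)(j) (gam om)(j')
    # (the maternal chain is collapsed analytically), and symmetrically for
    # the maternal chain with alpha^T, gam^T and pi.
    D_p = np.zeros((L, M))
    E_p = np.zeros((L - 1, M))
    D_m = np.zeros((L, N))
    E_m = np.zeros((L - 1, N))
    D_p[0] = C[0].sum(axis=1)
    D_m[0] = C[0].sum(axis=0)
    for i in range(L - 1):
        t = tau[i]
        gam = E[i + 1] * beta[i + 1] / c[i + 1]
        for (a_i, g_i, props, other, Dc, Ec) in (
            (alpha[i], gam, pi, om, D_p, E_p),
            (alpha[i].T, gam.T, om, pi, D_m, E_m),
        ):
            S = (1.0 - t) * (a_i @ g_i.T) + t * np.outer(a_i.sum(axis=1), g_i @ other)
            diag = np.diag(S)
            stay = ((1.0 - t) + t * props) * diag
            arrive = (1.0 - t) * diag + t * props * S.sum(axis=0)
            Ec[i] = stay
            Dc[i + 1] = arrive - stay
    return DiploidPosteriors(C=C, paternal=C.sum(axis=2), maternal=C.sum(axis=1),
                             D_p=D_p, E_p=E_p, D_m=D_m, E_m=E_m, loglik=loglik)


def diploid_loglikelihood(g, grad: GradientSet, model: DiploidAncestryModel,
                          trans: TransitionModel) -> float:
    """Log of the marginal genotype likelihood (forward pass only)."""
    E = diploid_emission_matrix(g, grad, model.X, model.Y)
    L = E.shape[0]
    if trans.tau.size != L - 1:
        raise ValueError("transition model does not match the number of SNPs")
    pi, om = model.Pi, model.Omega
    a = pi[:, None] * om[None, :] * E[0]
    c = a.sum()
    ll = np.log(c)
    a /= c
    for i in range(1, L):
        a = _predict(a, trans.tau[i - 1], pi, om) * E[i]
        c = a.sum()
        ll += np.log(c)
        a /= c
    return float(ll)


def _q_objective(theta, C, g, grad, M, N, homogeneous):
    """Negative diploid location Q-function and its gradient.

    theta stacks the free coordinates: M shared locations when homogeneous,
    else M paternal followed by N maternal locations.
    """
    if homogeneous:
        X = theta.reshape(M, 2)
        Y = X
    else:
        X = theta[: 2 * M].reshape(M, 2)
        Y = theta[2 * M:].reshape(N, 2)
    A, b = grad.a, grad.b
    UX = A @ X.T + b[:, None]  # (L, M)
    UY = A @ Y.T + b[:, None]  # (L, N)
    FX, FY = expit(UX), expit(UY)

    obs = g >= 0
    m0 = g == 0
    m1 = g == 1
    m2 = g == 2
    Cp = C.sum(axis=2)  # (L, M)
    Cm = C.sum(axis=1)  # (L, N)

    val = 0.0
    dUX = np.zeros_like(UX)
    dUY = np.zeros_like(UY)

    # homozygous sites: the two draws separate into per-chain terms
    if m0.any():
        val += -(Cp[m0] * np.logaddexp(0.0, UX[m0])).sum()
        val += -(Cm[m0] * np.logaddexp(0.0, UY[m0])).sum()
        dUX[m0] += -Cp[m0] * FX[m0]
        dUY[m0] += -Cm[m0] * FY[m0]
    if m2.any():
        val += -(Cp[m2] * np.logaddexp(0.0, -UX[m2])).sum()
        val += -(Cm[m2] * np.logaddexp(0.0, -UY[m2])).sum()
        dUX[m2] += Cp[m2] * (1.0 - FX[m2])
        dUY[m2] += Cm[m2] * (1.0 - FY[m2])
    # heterozygous sites couple the chains
    if m1.any():
        fx = FX[m1][:, :, None]  # (l, M, 1)
        fy = FY[m1][:, None, :]  # (l, 1, N)
        P1 = np.clip(fx * (1.0 - fy) + (1.0 - fx) * fy, 1e-300, None)
        C1 = C[m1]
        val += (C1 * np.log(P1)).sum()
        r = C1 * (1.0 - 2.0 * fy) / P1  # d q / d fx
        dUX[m1] += r.sum(axis=2) * FX[m1] * (1.0 - FX[m1])
        ry = C1 * (1.0 - 2.0 * fx) / P1
        dUY[m1] += ry.sum(axis=1) * FY[m1] * (1.0 - FY[m1])

    gX = np.einsum("lm,ld->md", dUX, A)
    gY = np.einsum("ln,ld->nd", dUY, A)
    if homogeneous:
        grad_theta = (gX + gY).ravel()
    else:
        grad_theta = np.concatenate([gX.ravel(), gY.ravel()])
    return -val, -grad_theta


def diploid_m_step_locations(C: np.ndarray, g, grad: GradientSet,
                             X_init, Y_init, *, homogeneous: bool = False):
    """Maximize the joint location Q-function; returns (X, Y).

    Quasi-Newton (L-BFGS) on the analytic gradient of the stacked location
    vector. The heterozygous term can make the objective non-concave, so the
    update is guarded: if the optimizer fails to improve on the initial
    value, the initial locations are returned.
    """
    C = np.asarray(C, dtype=float)
    g = _clean_genotype(g, grad.n_snps)
    X0 = np.atleast_2d(np.asarray(X_init, dtype=float))
    Y0 = np.atleast_2d(np.asarray(Y_init, dtype=float))
    M, N = X0.shape[0], Y0.shape[0]
    if C.shape != (grad.n_snps, M, N):
        raise ValueError("joint posterior table has the wrong shape")

    wp = C.sum(axis=(0, 2))
    wm = C.sum(axis=(0, 1))
    if np.any(wp <= 0) or np.any(wm <= 0):
        warnings.warn("an ancestry received no posterior weight; its location is "
                      "left unchanged", RuntimeWarning, stacklevel=2)

    if homogeneous:
        if M != N or not np.array_equal(X0, Y0):
            raise ValueError("homogeneous update requires M == N and X_init == Y_init")
        theta0 = X0.ravel().copy()
    else:
        theta0 = np.concatenate([X0.ravel(), Y0.ravel()])

    f0, _ = _q_objective(theta0, C, g, grad, M, N, homogeneous)
    res = minimize(_q_objective, theta0, args=(C, g, grad, M, N, homogeneous),
                   jac=True, method="L-BFGS-B",
                   options={"maxiter": 500, "gtol": 1e-10, "ftol": 1e-14})
    theta = res.x if res.fun <= f0 else theta0
    if homogeneous:
        X = theta.reshape(M, 2)
        return X.copy(), X.copy()
    return theta[: 2 * M].reshape(M, 2).copy(), theta[2 * M:].reshape(N, 2).copy()


def diploid_viterbi(g, grad: GradientSet, model: DiploidAncestryModel,
                    trans: TransitionModel):
    """Most probable joint path; returns (paternal, maternal) index arrays.

    Ties are broken lexicographically: lower paternal index first, then
    lower maternal index.
    """
    E = diploid_emission_matrix(g, grad, model.X, model.Y)
    L, M, N = E.shape
    if trans.tau.size != L - 1:
        raise ValueError("transition model does not match the number of SNPs")
    S = M * N
    pi, om = model.Pi, model.Omega
    with np.errstate(divide="ignore"):
        logE = np.log(E.reshape(L, S))
        logp0 = np.log(np.outer(pi, om).reshape(S))
    delta = logp0 + logE[0]
    back = np.zeros((L, S), dtype=np.int64)
    eyeM, eyeN = np.eye(M), np.eye(N)
    for i in range(1, L):
        t = trans.tau[i - 1]
        Ap = (1.0 - t) * eyeM + t * pi[None, :]
        Am = (1.0 - t) * eyeN + t * om[None, :]
        A = np.kron(Ap, Am)  # row-major joint index s = j * N + k
        with np.errstate(divide="ignore"):
            scores = delta[:, None] + np.log(np.maximum(A, 0.0))
        back[i] = np.argmax(scores, axis=0)  # first occurrence = lexicographic
        delta = scores[back[i], np.arange(S)] + logE[i]
    path = np.empty(L, dtype=np.int64)
    path[L - 1] = int(np.argmax(delta))
    for i in range(L - 2, -1, -1):
        path[i] = back[i + 1][path[i + 1]]
    return path // N, path % N


def run_em_diploid(g, grad: GradientSet, M: int, N: int, trans: TransitionModel, *,
                   homogeneous: bool = False, pi_fixed: bool = True,
                   Pi0=None, Omega0=None, restarts: int = 5, seed=None,
                   tol: float = 1e-6, max_iter: int = 200, init_box=None,
                   X_init=None, Y_init=None) -> EMResult:
    """Fit paternal and maternal ancestor locations for a genotype by EM.

    Mirrors :func:`geomix.em.run_em`; the M step cycles locations (X, Y
    jointly), then Pi, then Omega. With ``homogeneous=True`` a single
    location vector is shared by both chains (requires M == N).
    """
    g = _clean_genotype(g, grad.n_snps)
    if M < 1 or N < 1:
        raise ValueError("the numbers of ancestries must be >= 1")
    if homogeneous and M != N:
        raise ValueError("homogeneous ancestry requires M == N")
    if max(M, N) > grad.n_snps:
        raise ValueError("more ancestries than SNPs is not identifiable")
    Pi0 = np.full(M, 1.0 / M) if Pi0 is None else np.asarray(Pi0, dtype=float)
    Omega0 = np.full(N, 1.0 / N) if Omega0 is None else np.asarray(Omega0, dtype=float)
    if init_box is None:
        init_box = grad.extent if grad.extent is not None else ((-1.0, 1.0), (-1.0, 1.0))
    rng = np.random.default_rng(seed)

    if X_init is not None:
        X0 = np.atleast_2d(np.asarray(X_init, dtype=float))
        Y0 = X0 if homogeneous else np.atleast_2d(np.asarray(Y_init, dtype=float))
        starts = [(X0, Y0)]
    else:
        starts = []
        for _ in range(max(1, restarts)):
            X0 = _init_locations(M, init_box, rng)
            Y0 = X0 if homogeneous else _init_locations(N, init_box, rng)
            starts.append((X0, Y0))

    best = None
    for X0, Y0 in starts:
        model = DiploidAncestryModel(X=X0, Y=Y0, Pi=Pi0.copy(), Omega=Omega0.copy(),
                                     homogeneous=homogeneous)
        trace = []
        converged = False
        post = diploid_forward_backward(g, grad, model, trans)
        trace.append(post.loglik)
        for _ in range(max_iter):
            X_new, Y_new = diploid_m_step_locations(post.C, g, grad, model.X, model.Y,
                                                    homogeneous=homogeneous)
            Pi_new = model.Pi if pi_fixed else m_step_proportions(post.D_p, post.E_p, trans)
            Om_new = model.Omega if pi_fixed else m_step_proportions(post.D_m, post.E_m, trans)
            model = DiploidAncestryModel(X=X_new, Y=Y_new, Pi=Pi_new, Omega=Om_new,
                                         homogeneous=homogeneous)
            post = diploid_forward_backward(g, grad, model, trans)
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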