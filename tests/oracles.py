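"""Independent reference implementations used only by the tests.

Everything here is deliberately naive: exhaustive path enumeration, dense
grid search, direct product formulas. These never call into the recursive
or Newton-based code paths they are used to check.
"""

import itertools

import numpy as np

from geomix.diploid import diploid_emission_matrix
from geomix.hmm import emission_matrix


def transition_prob(tau_i, pi, prev, nxt):
    p = tau_i * pi[nxt]
    if nxt == prev:
        p += 1.0 - tau_i
    return p


def enumerate_haploid(h, grad, model, trans):
    """Exhaustive sum over all M^L ancestry paths.

    Returns (loglik, posteriors C, expected counts D, expected stays E,
    best path) with D/E defined as the initial-state/switch-into and
    stay-in expected counts.
    """
    E = emission_matrix(h, grad, model.X)
    L, M = E.shape
    pi, tau = model.Pi, trans.tau
    tot = 0.0
    C = np.zeros((L, M))
    D = np.zeros((L, M))
    Es = np.zeros((L - 1, M))
    best_p, best_path = -1.0, None
    for path in itertools.product(range(M), repeat=L):
        p = pi[path[0]] * E[0, path[0]]
        for i in range(1, L):
            p *= transition_prob(tau[i - 1], pi, path[i - 1], path[i]) * E[i, path[i]]
        tot += p
        D[0, path[0]] += p
        for i in range(L):
            C[i, path[i]] += p
        for i in range(L - 1):
            if path[i + 1] == path[i]:
                Es[i, path[i]] += p
            else:
                D[i + 1, path[i + 1]] += p
        if p > best_p:
            best_p, best_path = p, path
    return np.log(tot), C / tot, D / tot, Es / tot, np.array(best_path)


def enumerate_diploid(g, grad, model, trans):
    """Exhaustive sum over all (M*N)^L joint paths."""
    E = diploid_emission_matrix(g, grad, model.X, model.Y)
    L, M, N = E.shape
    pi, om, tau = model.Pi, model.Omega, trans.tau
    tot = 0.0
    C = np.zeros((L, M, N))
    best_p, best_path = -1.0, None
    for pp in itertools.product(range(M), repeat=L):
        # probability of the paternal path alone (reused across maternal paths)
        pp_prob = pi[pp[0]]
        for i in range(1, L):
            pp_prob *= transition_prob(tau[i - 1], pi, pp[i - 1], pp[i])
        for mm in itertools.product(range(N), repeat=L):
            p = pp_prob * om[mm[0]] * E[0, pp[0], mm[0]]
            for i in range(1, L):
                p *= transition_prob(tau[i - 1], om, mm[i - 1], mm[i]) * E[i, pp[i], mm[i]]
            tot += p
            for i in range(L):
                C[i, pp[i], mm[i]] += p
            if p > best_p:
                best_p, best_path = p, (pp, mm)
    return np.log(tot), C / tot, best_path


def naive_loglik(h, grad, model):
    """Independent-SNP mixture likelihood: prod_i sum_j pi_j P(h_i | j)."""
    E = emission_matrix(h, grad, model.X)
    return float(np.log(E @ model.Pi).sum())


def grid_search_location(weights, h, grad, box, step=0.05):
    """Dense grid argmax of the weighted per-ancestor Q objective."""
    (x1lo, x1hi), (x2lo, x2hi) = box
    g1 = np.arange(x1lo, x1hi + step / 2, step)
    g2 = np.arange(x2lo, x2hi + step / 2, step)
    obs = h >= 0
    A, b = grad.a[obs], grad.b[obs]
    w, hh = np.asarray(weights)[obs], h[obs].astype(float)
    sgn = 1.0 - 2.0 * hh
    best, best_val = None, -np.inf
    for u in g1:
        U = A[:, 0] * u
        for v in g2:
            q = -(w * np.logaddexp(0.0, sgn * (U + A[:, 1] * v + b))).sum()
            if q > best_val:
                best_val, best = q, (u, v)
    return np.array(best), best_val


def grid_search_proportion(D, E, tau, step=1e-4):
    """1-D grid argmax of the two-ancestry proportion objective."""
    d = D.sum(axis=0)
    grid = np.arange(step, 1.0, step)
    best, best_val = None, -np.inf
    for p1 in grid:
        pi = np.array([p1, 1.0 - p1])
        stay = 1.0 - tau[:, None] * (1.0 - pi[None, :])
        val = d @ np.log(pi) + (E * np.log(stay)).sum()
        if val > best_val:
            best_val, best = val, pi
    return best, best_val


def finite_diff_grad(fun, x, eps=1e-6):
    x = np.asarray(x, dtype=float)
    g = np.zeros_like(x)
    for i in range(x.size):
        e = np.zeros_like(x)
        e[i] = eps
        g[i] = (fun(x + e) - fun(x - e)) / (2 * eps)
    return g
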