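"""Inner HMM recursions.

The ancestry chain redraws its state from pi with probability tau[i] between
loci, so every kernel is a rank-one update plus a diagonal:

    A_i(j, k) = (1 - tau[i]) * delta_jk + tau[i] * pi[k]

which keeps all recursions O(L*M). The loops are JIT-compiled with numba
when it is available; the same functions run as plain Python otherwise.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


@njit(cache=True)
def forward(E, pi, tau):
    """Scaled forward pass. Returns (alpha, c) with rows of alpha summing to 1."""
    L, M = E.shape
    alpha = np.empty((L, M))
    c = np.empty(L)
    s = 0.0
    for j in range(M):
        alpha[0, j] = pi[j] * E[0, j]
        s += alpha[0, j]
    c[0] = s
    for j in range(M):
        alpha[0, j] /= s
    for i in range(1, L):
        t = tau[i - 1]
        s = 0.0
        for j in range(M):
            a = ((1.0 - t) * alpha[i - 1, j] + t * pi[j]) * E[i, j]
            alpha[i, j] = a
            s += a
        c[i] = s
        for j in range(M):
            alpha[i, j] /= s
    return alpha, c


@njit(cache=True)
def backward(E, pi, tau, c):
    """Scaled backward pass matching the forward scaling constants."""
    L, M = E.shape
    beta = np.empty((L, M))
    for j in range(M):
        beta[L - 1, j] = 1.0
    for i in range(L - 2, -1, -1):
        t = tau[i]
        dot = 0.0
        for j in range(M):
            dot += pi[j] * E[i + 1, j] * beta[i + 1, j]
        for j in range(M):
            beta[i, j] = ((1.0 - t) * E[i + 1, j] * beta[i + 1, j] + t * dot) / c[i + 1]
    return beta


@njit(cache=True)
def pair_counts(alpha, beta, E, pi, tau, c):
    """Expected switch-into (D) and stay (Estay) counts from the posteriors."""
    L, M = E.shape
    D = np.zeros((L, M))
    Estay = np.zeros((L - 1, M))
    for j in range(M):
        D[0, j] = alpha[0, j] * beta[0, j]
    s = 0.0
    for j in range(M):
        s += D[0, j]
    for j in range(M):
        D[0, j] /= s
    for i in range(L - 1):
        t = tau[i]
        for k in range(M):
            g = E[i + 1, k] * beta[i + 1, k] / c[i + 1]
            arrive = ((1.0 - t) * alpha[i, k] + t * pi[k]) * g
            stay = alpha[i, k] * ((1.0 - t) + t * pi[k]) * g
            Estay[i, k] = stay
            D[i + 1, k] = arrive - stay
    return D, Estay


@njit(cache=True)
def viterbi_path(logE, pi, tau):
    """Most probable path; ties broken toward the lower state index."""
    L, M = logE.shape
    NEG = -1.0e300
    delta = np.empty(M)
    back = np.zeros((L, M), dtype=np.int64)
    for j in range(M):
        lp = np.log(pi[j]) if pi[j] > 0.0 else NEG
        delta[j] = lp + logE[0, j]
    new = np.empty(M)
    for i in range(1, L):
        t = tau[i - 1]
        for k in range(M):
            best = NEG
            arg = 0
            for j in range(M):
                a = t * pi[k]
                if j == k:
                    a += 1.0 - t
                s = delta[j] + (np.log(a) if a > 0.0 else NEG)
                if s > best:
                    best = s
                    arg = j
            new[k] = best + logE[i, k]
            back[i, k] = arg
        for k in range(M):
            delta[k] = new[k]
    path = np.empty(L, dtype=np.int64)
    best = NEG
    arg = 0
    for j in range(M):
        if delta[j] > best:
            best = delta[j]
            arg = j
    path[L - 1] = arg
    for i in range(L - 2, -1, -1):
        path[i] = back[i + 1, path[i + 1]]
    return path
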