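"""Haploid admixture hidden Markov model.

The hidden state z_i in {1..M} is the ancestry of locus i. The chain starts
from the ancestry proportions Pi and, between adjacent loci, redraws the
ancestry from Pi with probability tau_i (so a "switch" may land on the same
state):

    P(z_1 = j)            = pi_j
    P(z_{i+1} = j | z_i)  = (1 - tau_i) * [j == z_i] + tau_i * pi_j

tau_i approximates the probability of at least one recombination in the
interval within the last g generations, tau_i ~= (g - 1) * phi * delta_bp,
optionally down-weighted by an adjustment factor that compensates for
residual background LD after pruning. Emissions are Bernoulli draws from
the logistic allele-frequency surface evaluated at the ancestor locations.

Setting every tau_i = 1 removes the linkage structure entirely: each locus
is an independent draw from the ancestry mixture, which is the "naive"
independent-SNP baseline.

All recursions are scaled (normalized) rather than log-space; the scaling
constants are accumulated in log space to produce the log-likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .gradients import GradientSet

__all__ = [
    "TransitionModel",
    "AncestryModel",
    "PosteriorTables",
    "build_transition",
    "emission_matrix",
    "forward_backward",
    "loglikelihood",
    "viterbi",
]

MISSING = -1  # sentinel for missing alleles/genotypes in integer vectors


def _clean_haplotype(h, L: int) -> np.ndarray:
    """Validate and convert a haplotype to an int8 vector with MISSING = -1."""
    h = np.asarray(h, dtype=float).ravel()
    if h.size == 0:
        raise ValueError("empty haplotype")
    if L is not None and h.size != L:
        raise ValueError(f"haplotype length {h.size} does not match the {L}-SNP gradient set")
    out = np.full(h.size, MISSING, dtype=np.int8)
    obs = np.isfinite(h)
    vals = h[obs]
    if np.any((vals != 0) & (vals != 1)):
        raise ValueError("haplotype alleles must be 0, 1 or missing")
    out[obs] = vals.astype(np.int8)
    return out


@dataclass
class TransitionModel:
    """Per-interval ancestry-switch probabilities tau_i (length L-1)."""

    tau: np.ndarray
    generations: int = 1
    phi: float = 1e-8
    adjust: float = 1.0

    def __post_init__(self):
        self.tau = np.asarray(self.tau, dtype=float).ravel()
        if np.any((self.tau < 0) | (self.tau > 1)):
            raise ValueError("every switch probability must lie in [0, 1]")


@dataclass
class AncestryModel:
    """Ancestor locations X (M, 2) and mixture proportions Pi (M,)."""

    X: np.ndarray
    Pi: np.ndarray = None
    pi_fixed: bool = True

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[1] != 2:
            raise ValueError("ancestor locations must be 2-D map coordinates")
        M = self.X.shape[0]
        if self.Pi is None:
            self.Pi = np.full(M, 1.0 / M)
        self.Pi = np.asarray(self.Pi, dtype=float).ravel()
        if self.Pi.size != M:
            raise ValueError("proportions must match the number of ancestors")
        if np.any(self.Pi < 0) or abs(self.Pi.sum() - 1.0) > 1e-12:
            raise ValueError("proportions must be non-negative and sum to 1")

    @property
    def M(self) -> int:
        return self.X.shape[0]


@dataclass
class PosteriorTables:
    """Posterior summaries from the forward-backward pass.

    C[i, j]  = P(z_i = j | h)
    D[0, j]  = P(z_1 = j | h); D[i, j] = P(z_{i-1} != j, z_i = j | h) for i >= 1
    E[i, j]  = P(z_i = j, z_{i+1} = j | h)  (one row per interval)

    D and E are the expected-count sufficient statistics for the proportion
    update: the expected complete-data log-probability of the path is
    sum_j (sum_i D[i,j]) log pi_j + sum_{i,j} E[i,j] log(1 - tau_i (1 - pi_j))
    up to terms constant in Pi.
    """

    C: np.ndarray
    D: np.ndarray
    E: np.ndarray
    loglik: float


def build_transition(grad: GradientSet, generations: int, phi: float = 1e-8,
                     adjust: float = 1.0) -> TransitionModel:
    """Switch probabilities from base-pair gaps: tau_i = adjust*(g-1)*phi*Δd.

    Values are capped just below 1; intervals crossing a chromosome boundary
    get tau = 1 exactly (the ancestry is redrawn from Pi on each chromosome).
    generations = 1 gives tau = 0 everywhere within chromosomes.
    """
    if generations < 1:
        raise ValueError("generations must be >= 1")
    if phi <= 0 or adjust <= 0:
        raise ValueError("phi and adjust must be positive")
    L = grad.n_snps
    if L < 1:
        raise ValueError("empty gradient set")
    tau = np.ones(L - 1)
    same = grad.chrom[1:] == grad.chrom[:-1]
    dd = np.diff(grad.pos).astype(float)
    if np.any(dd[same] <= 0):
        raise ValueError("positions must be strictly increasing within a chromosome")
    tau[same] = np.minimum(1.0 - 1e-12, adjust * (generations - 1) * phi * dd[same])
    return TransitionModel(tau=tau, generations=generations, phi=phi, adjust=adjust)


def emission_matrix(h, grad: GradientSet, X) -> np.ndarray:
    """Per-locus emission probabilities, shape (L, M).

    P(h_i | z_i = j) = f_i(x_j)^h_i (1 - f_i(x_j))^(1 - h_i); a missing
    allele contributes 1 for every state (marginalized, never imputed).
    """
    h = _clean_haplotype(h, grad.n_snps)
    F = np.atleast_2d(grad.frequencies(np.atleast_2d(np.asarray(X, dtype=float))))
    E = np.ones_like(F)
    ones = h == 1
    zeros = h == 0
    E[ones] = F[ones]
    E[zeros] = 1.0 - F[zeros]
    return E


def _check_dims(model: AncestryModel, trans: TransitionModel, L: int):
    if trans.tau.size != L - 1:
        raise ValueError(f"transition model has {trans.tau.size} intervals, expected {L - 1}")


def forward_backward(h, grad: GradientSet, model: AncestryModel,
                     trans: TransitionModel) -> PosteriorTables:
    """Scaled forward-backward pass; returns posteriors, expected transition
    counts and the log-likelihood."""
    E = emission_matrix(h, grad, model.X)
    L, M = E.shape
    _check_dims(model, trans, L)
    alpha, c = _kernels.forward(E, model.Pi, trans.tau)
    loglik = float(np.log(c).sum())
    beta = _kernels.backward(E, model.Pi, trans.tau, c)
    C = alpha * beta
    C /= C.sum(axis=1, keepdims=True)
    D, Estay = _kernels.pair_counts(alpha, beta, E, model.Pi, trans.tau, c)
    return PosteriorTables(C=C, D=D, E=Estay, loglik=loglik)


def loglikelihood(h, grad: GradientSet, model: AncestryModel,
                  trans: TransitionModel) -> float:
    """Log of the marginal haplotype likelihood (forward pass only)."""
    E = emission_matrix(h, grad, model.X)
    L, M = E.shape
    _check_dims(model, trans, L)
    _, c = _kernels.forward(E, model.Pi, trans.tau)
    return float(np.log(c).sum())


def viterbi(h, grad: GradientSet, model: AncestryModel,
            trans: TransitionModel) -> np.ndarray:
    """Most probable ancestry path (0-based state indices, length L).

    Ties are broken toward the lower state index.
    """
    E = emission_matrix(h, grad, model.X)
    L, M = E.shape
    _check_dims(model, trans, L)
    with np.errstate(divide="ignore"):
        logE = np.log(E)
    return _kernels.viterbi_path(logE, model.Pi, trans.tau)
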