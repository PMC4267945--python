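"""Logistic allele-frequency surfaces over a 2-D map.

Each SNP j carries a logistic gradient: the frequency of the reference
allele at map position x = (x1, x2) is

    f_j(x) = 1 / (1 + exp(-a_j . x - b_j))

with a 2-vector slope ``a_j`` (per map unit) and intercept ``b_j``.
Coefficients are fitted per SNP, by maximum likelihood, from a training
panel of individuals with known (homogeneous) locations; alleles are
treated as independent Bernoulli draws from the local frequency, so a
diploid genotype contributes two draws (Hardy-Weinberg at each location).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

#: Frequencies are clamped to [FREQ_EPS, 1 - FREQ_EPS] before entering any
#: likelihood, so that log-emissions stay finite.
FREQ_EPS = 1e-12

__all__ = [
    "FREQ_EPS",
    "MapLocation",
    "SnpGradient",
    "GradientSet",
    "TrainingPanel",
    "allele_freq",
    "fit_gradients",
]


def _as_location(loc) -> np.ndarray:
    loc = np.asarray(loc, dtype=float)
    if loc.shape != (2,):
        raise ValueError(f"a map location must have exactly 2 coordinates, got shape {loc.shape}")
    if not np.all(np.isfinite(loc)):
        raise ValueError("map location coordinates must be finite")
    return loc


@dataclass(frozen=True)
class MapLocation:
    """A point on the map: (longitude, latitude) in degrees, or abstract
    planar units for synthetic maps."""

    coord: tuple[float, float]

    def __post_init__(self):
        _as_location(self.coord)

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.coord, dtype=dtype or float)


@dataclass(frozen=True)
class SnpGradient:
    """Logistic gradient coefficients for a single SNP."""

    a: tuple[float, float]
    b: float
    snp_id: str = ""

    def __post_init__(self):
        if not (np.all(np.isfinite(self.a)) and np.isfinite(self.b)):
            raise ValueError("gradient coefficients must be finite")


def allele_freq(gradient: SnpGradient, loc) -> float:
    """Reference-allele frequency at ``loc`` under a single SNP's gradient.

    The logistic value is clamped to [FREQ_EPS, 1 - FREQ_EPS].
    """
    x = _as_location(getattr(loc, "coord", loc))
    a = np.asarray(gradient.a, dtype=float)
    if a.shape != (2,) or not np.all(np.isfinite(a)) or not np.isfinite(gradient.b):
        raise ValueError("gradient coefficients must be two finite slopes and a finite intercept")
    f = expit(a @ x + gradient.b)
    return float(np.clip(f, FREQ_EPS, 1.0 - FREQ_EPS))


@dataclass
class GradientSet:
    """Per-SNP logistic coefficients plus genomic coordinates.

    Attributes
    ----------
    a : (L, 2) float array of slopes.
    b : (L,) float array of intercepts.
    pos : (L,) int array of base-pair positions (1-based), strictly
        increasing within each chromosome.
    chrom : (L,) array of chromosome labels.
    snp_ids : (L,) array of SNP identifiers.
    flagged : (L,) bool array marking degenerate fits (monomorphic SNPs,
        separation, non-convergence).
    extent : optional map bounding box ((x1_min, x1_max), (x2_min, x2_max)),
        used to seed location searches.
    """

    a: np.ndarray
    b: np.ndarray
    pos: np.ndarray
    chrom: np.ndarray
    snp_ids: np.ndarray
    flagged: np.ndarray = None
    extent: tuple | None = None

    def __post_init__(self):
        self.a = np.atleast_2d(np.asarray(self.a, dtype=float))
        self.b = np.asarray(self.b, dtype=float).ravel()
        self.pos = np.asarray(self.pos, dtype=np.int64).ravel()
        self.chrom = np.asarray(self.chrom).astype(str).ravel()
        self.snp_ids = np.asarray(self.snp_ids).astype(str).ravel()
        L = len(self.b)
        if self.a.shape != (L, 2):
            raise ValueError(f"slope array must have shape ({L}, 2), got {self.a.shape}")
        if not (len(self.pos) == len(self.chrom) == len(self.snp_ids) == L):
            raise ValueError("all per-SNP arrays must have equal length")
        if self.flagged is None:
            self.flagged = np.zeros(L, dtype=bool)
        else:
            self.flagged = np.asarray(self.flagged, dtype=bool).ravel()
            if len(self.flagged) != L:
                raise ValueError("flag array length mismatch")
        if np.any(self.pos < 0):
            raise ValueError("base-pair positions must be non-negative")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions must be strictly increasing within chromosome {c!r}")

    def __len__(self) -> int:
        return len(self.b)

    @property
    def n_snps(self) -> int:
        return len(self.b)

    def frequencies(self, locations) -> np.ndarray:
        """Allele frequencies at one or more locations.

        Parameters
        ----------
        locations : (2,) or (M, 2) array of map coordinates.

        Returns
        -------
        (L,) array for a single location, (L, M) for M locations; values
        clamped to [FREQ_EPS, 1 - FREQ_EPS].
        """
        X = np.asarray(locations, dtype=float)
        single = X.ndim == 1
        X = np.atleast_2d(X)
        if X.shape[1] != 2:
            raise ValueError("locations must be 2-D map coordinates")
        F = expit(self.a @ X.T + self.b[:, None])
        np.clip(F, FREQ_EPS, 1.0 - FREQ_EPS, out=F)
        return F[:, 0] if single else F

    def subset(self, idx) -> "GradientSet":
        idx = np.asarray(idx)
        return GradientSet(
            a=self.a[idx], b=self.b[idx], pos=self.pos[idx], chrom=self.chrom[idx],
            snp_ids=self.snp_ids[idx], flagged=self.flagged[idx], extent=self.extent,
        )

    def gradient(self, i: int) -> SnpGradient:
        return SnpGradient(a=tuple(self.a[i]), b=float(self.b[i]), snp_id=str(self.snp_ids[i]))


@dataclass
class TrainingPanel:
    """Reference individuals with known homogeneous locations.

    ``genotypes`` is an (n, L) float matrix with values in {0, 1, ..., ploidy}
    and NaN for missing calls; ``locations`` is (n, 2).
    """

    genotypes: np.ndarray
    locations: np.ndarray
    sample_ids: np.ndarray = None
    snp_ids: np.ndarray = None
    ploidy: int = 2

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        self.locations = np.asarray(self.locations, dtype=float)
        n, L = self.genotypes.shape
        if self.locations.shape != (n, 2):
            raise ValueError(f"locations must have shape ({n}, 2)")
        if not np.all(np.isfinite(self.locations)):
            raise ValueError("training locations must be finite")
        if self.sample_ids is None:
            self.sample_ids = np.array([f"sample_{i}" for i in range(n)])
        if self.snp_ids is None:
            self.snp_ids = np.array([f"snp_{j}" for j in range(L)])
        self.sample_ids = np.asarray(self.sample_ids).astype(str)
        self.snp_ids = np.asarray(self.snp_ids).astype(str)
        if self.ploidy not in (1, 2):
            raise ValueError("ploidy must be 1 or 2")
        obs = self.genotypes[np.isfinite(self.genotypes)]
        if obs.size and (obs.min() < 0 or obs.max() > self.ploidy):
            raise ValueError(f"genotype calls must lie in 0..{self.ploidy} or be NaN")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]


def _fit_one_snp(x: np.ndarray, successes: np.ndarray, trials: float, ridge: float,
                 max_iter: int = 100, tol: float = 1e-10):
    """Damped-Newton ML fit of a single logistic gradient.

    ``x`` is (n, 2); each row contributes ``trials`` Bernoulli draws with
    ``successes`` observed reference alleles. Ridge penalizes the slope only.
    Returns (a, b, flagged).
    """
    n = len(successes)
    Z = np.column_stack([x, np.ones(n)])
    t = np.full(n, float(trials))
    total_s, total_t = successes.sum(), t.sum()

    # Monomorphic: closed-form degenerate fit.
    if total_s == 0 or total_s == total_t:
        p = np.clip(total_s / total_t, FREQ_EPS, 1 - FREQ_EPS)
        return np.zeros(2), float(logit(p)), True

    p0 = np.clip(total_s / total_t, FREQ_EPS, 1 - FREQ_EPS)
    theta = np.array([0.0, 0.0, float(logit(p0))])
    pen = np.array([2 * ridge, 2 * ridge, 0.0])

    def loglik(th):
        u = Z @ th
        # Bernoulli log-lik written with log1p(exp(.)) for stability.
        return float(successes @ u - t @ np.logaddexp(0.0, u) - ridge * (th[0] ** 2 + th[1] ** 2))

    ll = loglik(theta)
    flagged = False
    for _ in range(max_iter):
        p = expit(Z @ theta)
        g = Z.T @ (successes - t * p) - pen * theta
        w = t * p * (1 - p)
        H = -(Z.T * w) @ Z - np.diag(pen)
        try:
            step = np.linalg.solve(H, -g)
        except np.linalg.LinAlgError:
            step = g  # fall back to gradient ascent on a singular Hessian
        # damped update: halve until the penalized log-likelihood improves
        scale, ll_new, theta_new = 1.0, -np.inf, theta
        for _ in range(40):
            cand = theta + scale * step
            ll_cand = loglik(cand)
            if ll_cand >= ll:
                ll_new, theta_new = ll_cand, cand
                break
            scale *= 0.5
        else:
            break  # no ascent direction left
        converged = ll_new - ll <= tol * (abs(ll) + 1.0)
        theta, ll = theta_new, ll_new
        if converged:
            break
    else:
        flagged = True

    # a polymorphic SNP fitted essentially perfectly implies separation:
    # the unpenalized likelihood has no finite maximum there
    if -(loglik(theta) + ridge * (theta[0] ** 2 + theta[1] ** 2)) < 1e-6 * total_t:
        flagged = True
    return theta[:2].copy(), float(theta[2]), flagged


def fit_gradients(panel: TrainingPanel, ridge: float = 1e-4, *,
                  pos: np.ndarray | None = None,
                  chrom: np.ndarray | None = None) -> GradientSet:
    """Fit per-SNP logistic gradients from a training panel.

    Each diploid genotype contributes two Bernoulli draws with success
    probability f_j at the individual's location (one draw if
    ``panel.ploidy == 1``); missing calls are skipped. The slope is ridge
    penalized (the intercept is not). Monomorphic SNPs and fits showing
    separation or non-convergence come back with ``flagged`` set; for
    monomorphic SNPs the slope is zero and the intercept is the logit of
    the clamped empirical frequency.

    Parameters
    ----------
    panel : training genotypes plus known locations.
    ridge : non-negative L2 penalty on the slope vector.
    pos, chrom : optional genomic coordinates to attach to the result
        (defaults: 1-based index positions on chromosome "1").
    """
    if ridge < 0:
        raise ValueError("ridge must be non-negative")
    n, L = panel.genotypes.shape
    A = np.zeros((L, 2))
    b = np.zeros(L)
    flagged = np.zeros(L, dtype=bool)
    n_separation = 0
    for j in range(L):
        gj = panel.genotypes[:, j]
        mask = np.isfinite(gj)
        if mask.sum() == 0:
            A[j], b[j], flagged[j] = 0.0, 0.0, True
            continue
        aj, bj, fl = _fit_one_snp(panel.locations[mask], gj[mask], panel.ploidy, ridge)
        A[j], b[j], flagged[j] = aj, bj, fl
        if fl and not (gj[mask].sum() in (0, panel.ploidy * mask.sum())):
            n_separation += 1
    if n_separation:
        warnings.warn(
            f"{n_separation} SNP(s) showed separation or non-convergence during "
            "gradient fitting and were flagged", RuntimeWarning, stacklevel=2)

    if pos is None:
        pos = np.arange(1, L + 1)
    if chrom is None:
        chrom = np.full(L, "1")
    lo = panel.locations.min(axis=0)
    hi = panel.locations.max(axis=0)
    extent = ((float(lo[0]), float(hi[0])), (float(lo[1]), float(hi[1])))
    return GradientSet(a=A, b=b, pos=pos, chrom=chrom, snp_ids=panel.snp_ids,
                       flagged=flagged, extent=extent)
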