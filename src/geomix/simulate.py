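"""Synthetic maps, gradients, ancestors and admixed genomes.

The generator is the package's study-condition module: it draws per-SNP
logistic gradients over a bounded planar map, samples "ancestor"
haplotypes as independent Bernoulli draws from the gradient frequencies at
chosen locations, and produces admixed offspring by the Markov
recombination process used throughout: the ancestry of the first locus is
drawn from the proportions, and between adjacent SNPs the ancestry is
redrawn from the proportions with probability (g - 1) * phi * delta_bp
(a redraw may land on the current state, matching the inference HMM's
transition law exactly). Truth tracks (ancestor locations, per-locus
ancestry paths, redraw events) are recorded for evaluation.

Two admixture modes are provided: copying alleles from explicit ancestor
haplotypes (the analogue of simulating from real phased reference
haplotypes), and drawing alleles directly from the logistic surface at the
ancestral location of each locus (the idealized, model-faithful mode).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

from .gradients import GradientSet

__all__ = [
    "SimConfig",
    "SimTruth",
    "make_synthetic_gradients",
    "simulate_ancestor_haplotype",
    "simulate_admixed_haplotype",
    "simulate_admixed_genotype",
]

DEFAULT_EXTENT = ((0.0, 30.0), (0.0, 30.0))


@dataclass
class SimConfig:
    """Settings for one simulated admixed individual.

    ``ancestor_locations`` plays the role of the "country centers" the
    ancestors are drawn from: paternal ancestors are rows 0..M-1 and, unless
    ``homogeneous``, maternal ancestors are separate rows (N of them). The
    proportions default to uniform. ``phi`` is the per-bp per-generation
    recombination probability; ``steepness`` the mean slope magnitude of
    informative gradients (per map unit).
    """

    L: int
    generations: int
    ancestor_locations: np.ndarray
    maternal_locations: np.ndarray = None
    proportions: np.ndarray = None
    maternal_proportions: np.ndarray = None
    phi: float = 1e-8
    homogeneous: bool = False
    map_extent: tuple = DEFAULT_EXTENT
    steepness: float = 0.5
    informative_fraction: float = 1.0
    spacing_bp: int = 20_000
    seed: int = None

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducible simulation")
        self.ancestor_locations = np.atleast_2d(np.asarray(self.ancestor_locations, dtype=float))
        if self.maternal_locations is not None:
            self.maternal_locations = np.atleast_2d(
                np.asarray(self.maternal_locations, dtype=float))
        M = self.ancestor_locations.shape[0]
        if self.proportions is None:
            self.proportions = np.full(M, 1.0 / M)
        self.proportions = np.asarray(self.proportions, dtype=float)
        if abs(self.proportions.sum() - 1.0) > 1e-9 or np.any(self.proportions < 0):
            raise ValueError("proportions must be non-negative and sum to 1")
        if self.maternal_proportions is not None:
            self.maternal_proportions = np.asarray(self.maternal_proportions, dtype=float)


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated haplotype or genotype."""

    ancestor_locations: np.ndarray   # (M, 2) paternal (or the only) set
    path: np.ndarray                 # (L,) 0-based ancestry indices
    breakpoints: np.ndarray          # interval indices where ancestry was redrawn
    maternal_locations: np.ndarray = None
    maternal_path: np.ndarray = None
    maternal_breakpoints: np.ndarray = None


def make_synthetic_gradients(L: int, map_extent=DEFAULT_EXTENT, steepness: float = 0.5,
                             informative_fraction: float = 1.0, seed=None, *,
                             spacing_bp: int = 20_000, chrom: str = "1") -> GradientSet:
    """Draw a synthetic set of per-SNP logistic gradients.

    Informative SNPs get a slope direction uniform on the circle and a
    magnitude Gamma(2, steepness/2) (mean ``steepness`` per map unit); the
    intercept is solved so that the frequency averaged over the map is
    Uniform(0.05, 0.95). The remaining SNPs are flat (zero slope) with the
    same map-average frequency law, so they carry no geographic signal.
    Positions are evenly spaced (default 1 SNP / 20 kb) on one chromosome.
    """
    if L < 1:
        raise ValueError("at least one SNP is required")
    if not 0.0 <= informative_fraction <= 1.0:
        raise ValueError("informative_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0.0, 2.0 * np.pi, size=L)
    mag = rng.gamma(shape=2.0, scale=steepness / 2.0, size=L)
    informative = rng.random(L) < informative_fraction
    mag[~informative] = 0.0
    a = np.column_stack([mag * np.cos(theta), mag * np.sin(theta)])
    target = rng.uniform(0.05, 0.95, size=L)

    # quadrature grid over the map for the mean-frequency constraint
    (x1lo, x1hi), (x2lo, x2hi) = map_extent
    g1 = np.linspace(x1lo, x1hi, 16)
    g2 = np.linspace(x2lo, x2hi, 16)
    G = np.array([(u, v) for u in g1 for v in g2])  # (256, 2)
    proj = a @ G.T  # (L, 256)

    # vectorized bisection for b: mean_x expit(a.x + b) is increasing in b
    span = np.abs(proj).max(axis=1) + 10.0
    lo, hi = -span, span
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        mean_f = expit(proj + mid[:, None]).mean(axis=1)
        too_high = mean_f > target
        hi = np.where(too_high, mid, hi)
        lo = np.where(too_high, lo, mid)
    b = 0.5 * (lo + hi)
    b[~informative] = logit(target[~informative])

    pos = spacing_bp * np.arange(1, L + 1)
    return GradientSet(
        a=a, b=b, pos=pos, chrom=np.full(L, chrom),
        snp_ids=np.array([f"snp_{i}" for i in range(L)]),
        flagged=~informative, extent=map_extent,
    )


def simulate_ancestor_haplotype(loc, grad: GradientSet, seed=None) -> np.ndarray:
    """One haplotype drawn Bernoulli(f_i(loc)) independently per site."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    f = grad.frequencies(np.asarray(loc, dtype=float))
    return (rng.random(grad.n_snps) < f).astype(np.int8)


def _ancestry_path(grad: GradientSet, generations: int, phi: float,
                   proportions: np.ndarray, rng) -> tuple[np.ndarray, np.ndarray]:
    """Markov ancestry path plus the interval indices of redraw events.

    A redraw happens with probability (g-1)*phi*delta_bp in each
    intra-chromosome interval and with certainty across chromosome
    boundaries; the redrawn state may equal the current one.
    """
    L = grad.n_snps
    K = len(proportions)
    p_switch = np.ones(L - 1)
    same = grad.chrom[1:] == grad.chrom[:-1]
    dd = np.diff(grad.pos).astype(float)
    p_switch[same] = np.minimum(1.0, (generations - 1) * phi * dd[same])
    events = rng.random(L - 1) < p_switch
    z = np.empty(L, dtype=np.int64)
    z[0] = rng.choice(K, p=proportions)
    current = z[0]
    # redraws are sparse; fill runs between events
    idx = np.flatnonzero(events)
    start = 0
    for e in idx:
        z[start:e + 1] = current
        current = rng.choice(K, p=proportions)
        start = e + 1
    z[start:] = current
    return z, idx


def simulate_admixed_haplotype(grad: GradientSet, generations: int, *,
                               phi: float = 1e-8, proportions=None,
                               ancestor_haplotypes=None, ancestor_locations=None,
                               seed=None) -> tuple[np.ndarray, SimTruth]:
    """Simulate one admixed haplotype with its truth track.

    Exactly one of ``ancestor_haplotypes`` (list of 0/1 vectors: alleles are
    copied from the ancestor active at each locus) or ``ancestor_locations``
    ((K, 2) array: alleles are drawn Bernoulli from the gradient frequency
    at the active ancestral location) must be given.
    """
    if (ancestor_haplotypes is None) == (ancestor_locations is None):
        raise ValueError("give exactly one of ancestor_haplotypes or ancestor_locations")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = grad.n_snps
    if ancestor_haplotypes is not None:
        H = np.atleast_2d(np.asarray(ancestor_haplotypes))
        if H.shape[1] != L:
            raise ValueError("ancestor haplotypes do not match the gradient set length")
        K = H.shape[0]
        locations = None
    else:
        locations = np.atleast_2d(np.asarray(ancestor_locations, dtype=float))
        K = locations.shape[0]
    if proportions is None:
        proportions = np.full(K, 1.0 / K)
    proportions = np.asarray(proportions, dtype=float)
    if proportions.size != K:
        raise ValueError("proportions do not match the number of ancestors")

    z, events = _ancestry_path(grad, generations, phi, proportions, rng)
    if locations is None:
        h = H[z, np.arange(L)].astype(np.int8)
        truth_loc = None
    else:
        F = grad.frequencies(locations)  # (L, K)
        h = (rng.random(L) < F[np.arange(L), z]).astype(np.int8)
        truth_loc = locations
    return h, SimTruth(ancestor_locations=truth_loc, path=z, breakpoints=events)


def simulate_admixed_genotype(config: SimConfig,
                              grad: GradientSet = None) -> tuple[np.ndarray, SimTruth, GradientSet]:
    """Simulate an admixed diploid genotype (two independent haplotypes).

    The paternal haplotype mixes ``config.ancestor_locations``; the maternal
    haplotype mixes ``config.maternal_locations`` unless ``homogeneous``, in
    which case both chains share the paternal ancestry set. Returns
    (genotype 0/1/2, truth, gradient set); a gradient set is generated from
    the config when not supplied.
    """
    rng = np.random.default_rng(config.seed)
    if grad is None:
        grad = make_synthetic_gradients(
            config.L, config.map_extent, config.steepness,
            config.informative_fraction, rng, spacing_bp=config.spacing_bp)
    pat_loc = config.ancestor_locations
    if config.homogeneous or config.maternal_locations is None:
        mat_loc = pat_loc
        mat_prop = config.proportions
    else:
        mat_loc = config.maternal_locations
        mat_prop = config.maternal_proportions
        if mat_prop is None:
            mat_prop = np.full(mat_loc.shape[0], 1.0 / mat_loc.shape[0])
    hp, tp = simulate_admixed_haplotype(
        grad, config.generations, phi=config.phi, proportions=config.proportions,
        ancestor_locations=pat_loc, seed=rng)
    hm, tm = simulate_admixed_haplotype(
        grad, config.generations, phi=config.phi, proportions=mat_prop,
        ancestor_locations=mat_loc, seed=rng)
    geno = (hp + hm).astype(np.int8)
    truth = SimTruth(ancestor_locations=tp.ancestor_locations, path=tp.path,
                     breakpoints=tp.breakpoints,
                     maternal_locations=tm.ancestor_locations,
                     maternal_path=tm.path, maternal_breakpoints=tm.breakpoints)
    return geno, truth, grad
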