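# Methods

## Allele-frequency surfaces

Each SNP's reference-allele frequency is a logistic function of 2-D map
position, f_j(x) = expit(a_jᵀx + b_j). Coordinates enter the likelihood
raw — longitude/latitude degrees, or abstract planar units in synthetic
mode — with no projection; great-circle distances are used only for
*reporting* errors in geographic mode. Frequencies are clamped to
[10⁻¹², 1 − 10⁻¹²] before any likelihood so log-emissions stay finite.

Fitting (`fit_gradients`) maximizes, per SNP, the Bernoulli log-likelihood
of the observed allele counts (a diploid genotype is two draws under
Hardy-Weinberg at its location; a haploid panel one draw), minus a ridge
penalty on the slope only (default 10⁻⁴ per squared map-unit⁻¹). The ridge
tames quasi-separation when few distinct locations are sampled; the
intercept is never penalized so the fitted overall frequency is unbiased.
The solver is a damped Newton iteration on the analytic 3 × 3 system
(step-halving line search, gradient-ascent fallback on a singular
Hessian), converging when the relative log-likelihood change drops below
10⁻¹⁰ or after 100 iterations. Monomorphic SNPs return a zero slope, the
logit of the clamped empirical frequency, and a flag. A polymorphic SNP
fitted to essentially zero deviance (mean negative log-likelihood per
trial < 10⁻⁶) indicates perfect separation — the unpenalized MLE does not
exist — and is flagged with a warning rather than silently diverging. How
poorly-fitting SNPs should be treated downstream is genuinely open; we fit
everything and let the caller filter on the flag.

## The admixture HMM

The hidden ancestry chain redraws its state from the proportions with
probability τ_i between adjacent loci, so a "switch" may land on the
current state. τ_i = adjust · (g − 1) · φ · Δd_i, capped just below 1,
models at least one recombination in the interval over the last g
generations at a flat rate φ = 10⁻⁸ per bp per generation. The
adjustment factor (default 10⁻², paired with r² < 0.2 LD pruning) damps
spurious short ancestry segments caused by residual background LD, which
the emission model ignores (alleles are independent given local
ancestry). Chromosome boundaries get τ = 1 — the state is redrawn from Π,
equivalent to independent chains per chromosome with shared parameters.

Numerics: scaled (normalized) forward-backward rather than log-space, with
the scaling constants accumulated in log space; the rank-one-plus-diagonal
structure of the transition kernel keeps every pass O(L·M) (haploid) and
O(L·M·N) (diploid). The inner loops are numba-compiled when numba is
importable and run as plain Python otherwise, with identical results.
Missing alleles contribute emission 1 for every state (marginalized, never
imputed). Viterbi ties break toward the lower state index; diploid ties
lexicographically (paternal index first). The expected-count tables D
(initial state plus switch-into events) and E (stay events) are the
sufficient statistics of the complete-data log-probability in Π,

  Σ_j (Σ_i D_ij) ln π_j + Σ_{i,j} E_ij ln(1 − τ_i(1 − π_j)),

and are validated against exhaustive path enumeration in the tests.

## EM

The location M step separates over ancestors into concave 2-D weighted
logistic problems, solved by damped Newton with analytic gradient and 2 × 2
Hessian (step-halving; gradient ascent if the Hessian is numerically
singular, as with flat gradients). The proportion M step maximizes the
concave simplex objective above by SLSQP with analytic gradient, with two
closed-form shortcuts: normalized counts when every τ_i = 1, and uniform
for degenerate all-zero counts; the result is never accepted if it scores
below the uniform start. Proportions are held fixed (uniform by default)
unless `pi_fixed=False` — the usual study design treats contributions as
known, and the flag makes optimizing them opt-in.

The diploid location objective couples x_j and y_k only through
heterozygous sites, whose term log(f_x(1−f_y) + (1−f_x)f_y) is not concave
in general. It is maximized by L-BFGS on the analytic gradient of the
stacked 2(M+N)-vector, guarded so the update is rejected if it fails to
improve the objective — together with the exact E step this preserves the
EM monotonicity guarantee, which the test suite asserts on random
instances. The homogeneous option ties X = Y by optimizing a single shared
vector (parameter tying, not a penalty), so the constraint holds exactly
at output. Note that a perfectly symmetric initialization X = Y is a fixed
point of the coupled term; random restarts are asymmetric with probability
one, so this does not arise in practice.

Initialization draws ancestor locations uniformly from the gradient set's
map extent (the training bounding box, recorded when gradients are fitted
or generated), with 5 restarts by default; the best final log-likelihood
wins. Convergence: relative log-likelihood change below 10⁻⁶ or 200
iterations. Labels are arbitrary — all evaluation metrics first match
inferred to true ancestries by the distance-minimizing permutation
(exhaustive and lexicographically tie-broken up to M = 6, Hungarian
beyond).

## Model-order selection

AIC = 2k − 2 log L with k = 2 coordinates per distinct location plus
(M − 1) free proportions when those are optimized; ties go to the smaller
count, and candidates whose fit fails are flagged and excluded. With flat
gradients all candidates tie in likelihood and the penalty selects one
ancestry.

## Synthetic data

The generator emulates a pruned SNP panel over a bounded planar map.
Informative SNPs draw a slope direction uniformly on the circle, a
magnitude from Gamma(2, steepness/2) — mean `steepness` per map unit, a
realistic spread of weak and steep clines — and an intercept solved by
bisection so the frequency averaged over a 16 × 16 quadrature grid of the
map is Uniform(0.05, 0.95), mimicking a common-variant panel without
fixed alleles. The remaining fraction is flat (zero slope): geographically
uninformative noise. Positions are evenly spaced on one synthetic
chromosome; the default 20 kb spacing matches a post-pruning density of
roughly 10⁵ SNPs across a genome. Where tests use fewer SNPs they widen
the spacing instead (up to 1 Mb), preserving the total genetic length —
and hence the number of ancestry switches, which is what the admixture
signal depends on — rather than the marker count.

Admixed haplotypes follow exactly the inference model's transition law
(redraw-from-Π switches, so simulator and model are conjugate), with two
allele modes: copy from explicit ancestor haplotypes (the analogue of
simulating from real phased panels) or draw Bernoulli from the gradient at
the active ancestor's location (the idealized, model-faithful mode).
Genotypes are two independent haplotype simulations summed, sharing the
ancestry set when homogeneous. Truth tracks record ancestor locations,
per-locus paths and redraw events. All randomness flows through one
`numpy.random.default_rng(seed)` Generator (PCG64), so outputs are
bit-reproducible for a fixed seed and library version; seeds are
mandatory.

What the simulator does *not* emulate: background LD within ancestries,
variable recombination maps, genotyping error, phase-switch errors,
multi-modal or poorly-fitting frequency surfaces, and the uneven sampling
density of real reference panels. Passing recovery tests therefore bound
what is attainable when the gradient model is correct; on real data,
gradient misfit and residual LD dominate the error budget and accuracy
will be substantially lower.

## Problem sizes and thresholds in the tests

Exactness checks run at enumeration scale (L ≤ 8, M ≤ 3 haploid; L = 6,
M = N = 2 diploid; tolerance 10⁻¹⁰ relative). Recovery experiments use
L ∈ {1000, 5000, 20000} with steep gradients (steepness 2 per map unit) on
30-unit maps: two ancestors 20 units apart must be recovered within 10% of
their separation (observed: well under 1%), and diploid parents at L = 5000
within 0.15 map units. M-step optimality is checked against dense grid
search (0.05-unit cells for locations, 10⁻⁴ for proportions) and analytic
derivatives against central finite differences (relative error < 10⁻⁶).
Simulator calibration compares mean redraw counts over 2000 replicates
with Σ(g−1)φΔd within three Monte-Carlo standard errors. AIC behavior is
scored as the modal selected count over 100 replicates per true count;
metric trends use mean relative error and local accuracy over eight
fixed-seed replicates at separations {5, 10, 20, 40} map units and assert
strict monotonicity of the bin means.

## Known limitations

- The diploid joint state space is materialized (M·N states); runtime
  grows as O(L·(MN)) per pass and the method is intended for small numbers
  of distinct ancestries (≤ 4 per side).
- The relative prediction error for M > 2 divides by the *mean* pairwise
  distance among true locations (the M = 2 definition has a unique pair;
  the generalization is a design choice documented here).
- Gradient fitting assumes Hardy-Weinberg within locations and one draw
  per haploid allele; family structure or inbreeding in the panel will
  bias coefficients.
- LD pruning uses PLINK-conventional 50-SNP windows with step 5 (window
  sizes are a convention, not an optimum), and the training-derived
  retained set is applied unchanged to test individuals.
- Locations are unconstrained in the plane: nothing forbids an inferred
  ancestor in the sea. Constraining to a landmass or to the convex hull of
  the panel is out of scope.
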