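# geomix

Spatial localization of the recent ancestors of admixed individuals.

Many organisms — humans in Europe being the canonical example — show
isolation-by-distance structure: allele frequencies drift smoothly across
geography. For an individual whose recent ancestors (parents,
grandparents) came from *different* places, the genome is a mosaic of
segments, each tracing back to one ancestral location. `geomix` jointly
infers, from a single genome plus a reference panel, (i) the map
coordinates of those recent ancestors and (ii) the ancestry assignment of
every locus. It is aimed at population geneticists working on
subcontinental ancestry, hybrid-origin inference, or source tracking of
dispersing organisms, wherever a geolocated reference panel is available.

## Model

Allele frequencies are modeled per SNP as logistic gradients over the map:
for SNP *j* at position **x** = (x₁, x₂),

    f_j(x) = 1 / (1 + exp(−a_jᵀ x − b_j)),

with coefficients (a_j, b_j) fitted by maximum likelihood from reference
individuals of known homogeneous origin (`fit_gradients`), treating each
allele as an independent Bernoulli draw.

A haploid genome h = (h₁, …, h_L) is modeled by a hidden Markov model whose
state z_i ∈ {1..M} is the ancestry of locus *i*. The chain starts from the
ancestry proportions Π and redraws its state with probability τ_i between
adjacent loci:

    P(z₁ = j) = π_j,
    P(z_{i+1} = j | z_i) = (1 − τ_i)·1[j = z_i] + τ_i π_j,
    P(h_i | z_i = j) = f_i(x_j)^{h_i} (1 − f_i(x_j))^{1−h_i},

with τ_i ≈ (g − 1)·φ·Δd_i for g generations of admixture, per-bp
recombination probability φ (default 10⁻⁸) and base-pair gap Δd_i, times an
adjustment factor (default 10⁻²) that compensates for residual background
LD after r² < 0.2 pruning. The marginal likelihood L(h; X, Π) = Σ_Z P(Z; Π)
Π_i P(h_i | z_i; X) is maximized over the ancestor locations X (and
optionally Π) by EM: the E step is a scaled forward-backward pass, the M
step solves per-ancestor concave weighted logistic problems by damped
Newton. Viterbi or posterior decoding then yields locus-specific ancestry.
Setting τ_i = 1 everywhere recovers the naive independent-SNP baseline.

Unphased genotypes g_i ∈ {0, 1, 2} are handled by a paired-chain model on
the M × N grid of paternal/maternal ancestries with a two-Bernoulli
emission (P(g_i=1) = f_x(1−f_y) + (1−f_x)f_y, etc.), with optional tying
X = Y when both sides share the same ancestries. The number of ancestries
is chosen by AIC = 2k − 2 log L. A seeded simulator generates synthetic
gradients, ancestor haplotypes and admixed offspring under exactly the
transition law above, with full truth tracks for evaluation.

## Worked example

```python
import numpy as np
from geomix import (make_synthetic_gradients, simulate_admixed_haplotype,
                    build_transition, run_em, viterbi, prediction_errors,
                    local_ancestry_metrics)

grad = make_synthetic_gradients(5000, map_extent=((0, 30), (0, 30)),
                                steepness=1.0, seed=7, spacing_bp=100_000)
truth = np.array([[8.0, 10.0], [24.0, 20.0]])
hap, sim_truth = simulate_admixed_haplotype(grad, generations=4,
                                            ancestor_locations=truth, seed=8)
trans = build_transition(grad, generations=4)
fit = run_em(hap, grad, M=2, trans=trans, restarts=3, seed=9)
pe, rpe = prediction_errors(fit.model.X, truth)
path = viterbi(hap, grad, fit.model, trans)
acc, _ = local_ancestry_metrics(path, sim_truth.path, fit.model.X, truth)
print("inferred ancestor locations:")
print(np.round(fit.model.X, 3))
print(f"log-likelihood: {fit.loglik:.2f} after {fit.n_iter} EM iterations")
print(f"prediction error: {pe:.3f} map units (relative: {rpe:.4f})")
print(f"local-ancestry accuracy: {acc:.4f}")
```

Output:

```
inferred ancestor locations:
[[ 7.978 10.132]
 [23.997 19.833]]
log-likelihood: -846.72 after 4 EM iterations
prediction error: 0.150 map units (relative: 0.0080)
local-ancestry accuracy: 0.9992
```

The two simulated ancestors, 20.8 map units apart, are recovered to within
0.15 map units (0.8% of their separation), and 99.9% of loci are assigned
to the correct ancestry after label matching.

The same pipeline is available from the shell: `geomix simulate`,
`geomix fit-gradients`, `geomix prune`, `geomix localize-haploid`,
`geomix localize-diploid`, `geomix select-n` and `geomix evaluate`; each
run writes a JSON metadata record (version, seed, parameters, input
digests) so outputs are regenerable.

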