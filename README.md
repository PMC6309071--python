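# chromonet

Chromosome 3D structure reconstruction from Hi-C contact maps with a
**per-bead-pair** power-law contact-to-distance conversion inferred from
the topology of the contact network.

## The problem

Hi-C assays count physical contacts `c_ij` between pairs of fixed-size
genomic bins ("beads", e.g. 40 kb). Reconstructing a chromosome's 3D
conformation from a contact matrix usually starts by converting counts
into target Euclidean "wish" distances through a power law
`δ_ij = c_ij^(−α)`, then embedding the beads so their distances match.
The classical choice is a single global exponent `α = 1/3`, derived from
polymer-scaling arguments. But one global exponent compresses exactly
the contact range that modern deep-sequenced Hi-C resolves best: for
`c > 10` the distances `c^(−1/3)` become nearly indistinguishable, and a
single exponent cannot express how wish distances vary with genomic
distance or with topologically associating domain (TAD) structure.

`chromonet` instead gives every bead pair its own exponent

    δ_ij = c_ij^(−α_ij),      α_ij = (w_i α_i + w_j α_j) / (w_i + w_j)

where `w_i` is the i-th row sum of the contact matrix and `α_i` is the
bead's *clustering strength* — a per-bead quantity fitted against the
bead's clustering coefficient `CC_i = 2 e_i / (K_i (K_i − 1))` in the
contact network (a vertex per bead, an edge wherever `c_ij > 0`). The
heuristic: beads whose network neighbourhoods are densely interconnected
sit in spatially compact clusters, so their pairs deserve larger
exponents, i.e. smaller wish distances.

The strengths solve a constrained nonlinear program

    min_α  Σ_i λ₁ (α_i − λ₂ CC_i)²
         + Σ_{(i,j,k)∈PT} λ₃ [(α_i − α_k)² + (α_j − α_k)²]
    s.t.   0 ≤ α_i ≤ 1,
           δ_ij + δ_ik ≥ δ_jk  (and cyclic permutations)
           for all (i, j, k) with |i−j| = 1, k ∉ {i, j},
           c_ij, c_ik, c_jk > 0,

where `PT` is the set of bead triples whose three pairwise
contact-profile Pearson correlations all exceed `p₀ = 0.95`, and the
triangle constraints act on the composite distances `δ(α)` (δ is never a
free variable). A second, unconstrained optimization embeds the wish
distances in 3D by minimizing the capped normalized stress

    Σ_{c_ij>0} (d_ij − δ_ij)²/δ_ij²  +  Σ_{c_ij=0} (d_ij − R)²/R²

with `R` set to the largest wish distance. Kabsch superposition,
resolution coarsening and stratified contact/distance analyses round out
the toolkit, and a synthetic generator produces ground-truth bundles
(chain + planted domains + contacts) so every stage is testable without
external data.

## Worked example

```python
import chromonet as cn
from scipy.stats import pearsonr
import numpy as np

# synthetic ground truth: 80-bead chain, 4 planted domains,
# noise-free contacts, 30% structural zeros
truth = cn.simulate_truth(n=80, noise_cv=0.0, zero_frac=0.3, seed=42)

cfg = cn.OptimizationConfig(max_triples=4000, max_triangles=4000,
                            seed=42, backend="penalty")
res = cn.ClusteringStrengthModel(truth.cm, config=cfg).fit()
print(res.summary())

wd = res.wish_distances()
structure = cn.StructureModel(wd, cn.MdsConfig(seed=42, n_restarts=3)).fit()

ok = np.isfinite(res.alpha)
print(f"r(alpha_hat, alpha*) = {pearsonr(res.alpha[ok], truth.alpha_true[ok])[0]:.3f}")
print(f"r(delta_hat, delta*) = {pearsonr(wd.delta, truth.delta_true[wd.i, wd.j])[0]:.4f}")
sup = cn.kabsch_superpose(truth.coords, structure.coords, fit_scale=True)
print(f"RMSD = {min(sup.rmsd, sup.rmsd_reflection):.3f}")
```

prints

```
Clustering-strength fit
============================================
beads                         80
mappable beads                80
PT triples                     1
triangle constraints        9987
solver status          converged
objective                 0.0101
max triangle viol.      2.33e-05
alpha mean / median   0.7332 / 0.7333
r(alpha_hat, alpha*) = 0.967
r(delta_hat, delta*) = 1.0000
RMSD = 0.654
```

The fitted strengths track the planted profile (r = 0.967), the
inferred wish distances are essentially exact on noise-free input
(r = 1.0000, a direct consequence of the power-law round trip), and the
reconstructed structure superposes onto the planted chain with a small
residual — the chirality-blind, scale-fitted RMSD is reported because
distance data cannot distinguish mirror images.

## Command line

```sh
chromonet simulate -n 100 --seed 7 --out sim/
chromonet infer --matrix sim/contacts.tsv --seed 7 --out fit/
chromonet reconstruct --distances fit/distances.tsv --seed 7 --out 3d/
chromonet evaluate --distances fit/distances.tsv --matrix sim/contacts.tsv \
    --alpha fit/alpha.tsv --tads sim/tads.bed --out eval/
chromonet pipeline --matrix sim/contacts.tsv --seed 7 --out run/
```

Every command writes a `manifest.json` (inputs, outputs, seed, solver
status) so runs are reproducible from the manifest alone. `--alpha-fixed
0.3333` switches `infer` to the classical single-exponent baseline.

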