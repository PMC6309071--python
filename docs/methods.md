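# Methods

This note documents the models implemented in `chromonet`, the choices
made where the design was genuinely open, what the synthetic generator
does and does not emulate, and the known limitations. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The contact network and clustering strength

A chromosome at bin size `b` (default 40 kb) is a chain of `n` beads.
The contact network has a vertex per bead and an edge wherever the
normalized contact `c_ij` exceeds `min_contact` (default 0, i.e. all
strictly positive contacts). Self-contacts are never used: the diagonal
is retained on input but masked everywhere downstream.

The clustering coefficient `CC_i = 2 e_i / (K_i (K_i − 1))` (fraction of
a vertex's neighbour pairs that are themselves connected) is defined as
0 for degree < 2, where the formula is 0/0; this is the standard
convention and keeps the optimization target finite. Average shortest
path length is computed on the largest connected component only —
unmappable bins produce isolated vertices, and the covered fraction is
reported in the diagnostics rather than silently folded in.

`min_contact` is exposed because published vertex/edge counts for real
chromosome networks (about 3 edges per vertex) are far sparser than
"an edge per nonzero 40 kb contact" would produce; no edge-filtering
rule accompanies those counts, so the package takes the stated
construction rule as the default and leaves the threshold to the user.

## The clustering-strength program

Per-bead strengths `α` minimize

    Σ_i λ₁ (α_i − λ₂ CC_i)² + Σ_{(i,j,k)∈PT} λ₃ [(α_i − α_k)² + (α_j − α_k)²]

subject to the box `0 ≤ α_i ≤ 1` and triangle inequalities on the
composite distances `δ_ij(α) = c_ij^(−α_ij(α))` over backbone triangles
(`|i − j| = 1`, any third bead `k` with positive contacts to both). The
objective is convex quadratic in `α`; the constraints are nonlinear
because δ is a deterministic function of α — δ is never an independent
decision variable, which keeps the variable count at `n` and the
distances exactly consistent with the power law at every iterate.

Choices and parameters:

* **λ₁ = λ₂ = λ₃ = 1 by default.** The original tuning of these weights
  used a six-pair imaging benchmark that is not public, so the package
  ships neutral defaults plus `evaluate.tune_lambdas`, a grid search
  against any user-supplied benchmark distance table.
* **PT membership** uses Pearson correlations between contact-matrix
  rows with the diagonal *and both mutual columns* masked symmetrically:
  the shared entry `c_ij` and self-contacts mechanically inflate the
  correlation between rows i and j. Threshold `p₀ = 0.95`. Rows with
  zero variance after masking are excluded. Unordered triples are
  counted once.
* **Caps.** Both the PT set and the triangle set grow combinatorially at
  high resolution; seeded uniform subsampling caps (default 50 000 each)
  bound the program size without changing the model. The triple
  enumeration itself is faithful to the membership rules; the solver
  additionally dedupes triangles that induce identical constraint rows
  (e.g. (0,1,2) and (1,2,0)) before building the Jacobian.
* **Initialization** is `α_i = clamp(λ₂·CC_i, 0, 1)` — the exact
  minimizer of the first term. Unmappable beads (zero contact row) are
  reported and carry `α = NaN`; no pair involving them has a distance.
* **Solvers.** Two backends: hard constraints via scipy's trust-region
  interior-point method with analytic sparse Jacobian and Lagrangian
  Hessian (default), and an increasing quadratic penalty solved with
  L-BFGS-B. Both enforce the box exactly and report the maximum
  triangle residual; convergence is declared only when that residual is
  within the feasibility tolerance (1e-4). When no triangle constraints
  are active the problem is a bound-constrained convex quadratic and is
  solved directly with L-BFGS-B, which avoids the interior-point
  barrier's O(1e-5) bias. On desk-scale problems the penalty backend
  reaches the same feasibility tolerance orders of magnitude faster and
  is used as the pipeline default; the interior-point backend is
  exercised on the 50-bead full-constraint acceptance run. The program
  is non-convex through its constraints, so determinism is guaranteed
  only per (seed, backend, tolerance).

Wish distances are then `δ_ij = c_ij^(−α_ij)` on every pair with
`c_ij > 0`. For `c > 1` the distance is strictly decreasing in the
exponent; for sub-unit contacts (which normalized matrices can contain)
the monotonicity flips — the synthetic generator deliberately avoids
that regime (below), and real sub-unit contacts simply produce δ > 1.

## The embedding program

Coordinates minimize the capped normalized stress

    Σ_{c_ij>0} (d_ij − δ_ij)²/δ_ij² + Σ_{c_ij=0} (d_ij − R)²/R²

with `R` = the largest wish distance by default. Because the target
distances already satisfy box and triangle constraints, this solve is
unconstrained. It is *not* a classical MDS problem (normalized residuals
plus the R-cap term), so the package uses gradient-based local
optimization (L-BFGS-B with an analytic gradient) with multiple
restarts: restart 0 starts from a Torgerson double-centering embedding
of the target-filled distance matrix, the remaining restarts from seeded
Gaussian coordinates scaled to the mean wish distance. The best final
stress wins; the result is centered at the origin. Zero-contact pairs
where both beads are unmappable are excluded; the zero-pair set can be
subsampled (seeded) for tractability at high resolution, though all
pairs are kept by default. An embedding from distances is defined only
up to rigid motion *and reflection*; all distance-based diagnostics are
chirality-blind, and the Kabsch module reports both the proper-rotation
and the reflection-allowed RMSD.

Structure comparison uses the closed-form Kabsch superposition (SVD with
determinant correction; proper rotations by default), with optional
global scale fitting for cross-method comparisons where distance units
differ. Distance matrices are coarsened to a lower resolution by
genomic-coordinate windows, so non-integer bead ratios (40 kb → 500 kb
is 12.5) produce the correct alternating 12/13-bead blocks. Benchmark
scoring against probe-level tables averages all inter-block bead
distances per probe pair before the Pearson correlation.

## The synthetic generator

The generator's purpose is to produce data for which the model's
assumptions hold, so that recovery tests verify the inference machinery.
It emulates, in order:

1. **Geometry** — a smoothed random-walk chain with `n_domains` compact
   blocks (coordinates contracted toward block centroids by
   `compaction`, default 0.3) separated by open linkers (25% of beads).
   `compaction = 1` degenerates to a plain random walk. Planted domains
   are spatially compact: mean intra-domain distance < mean
   cross-domain distance.
2. **Structural zeros** — a seeded sample of `zero_frac` (default 0.3)
   of the `|i − j| > 1` pairs, drawn from the spatially longest
   candidates: contacts between far-apart loci fall below the detection
   floor. The backbone always survives.
3. **Clustering-strength profile** — `α*` is the lightly smoothed
   clustering coefficient of the structural-zero network, clipped to
   [0.05, 0.95]. This makes the model's central assumption (strength ≈
   clustering coefficient) true *by construction*; the profile is
   elevated inside domains because compact blocks are locally
   clique-like. Passing recovery tests therefore certify that the
   optimization recovers a recoverable signal — they are not evidence
   that real chromatin obeys the assumption.
4. **Contacts** — true distances are rescaled so the maximum is
   0.95 < 1 (hence all contacts exceed 1 and the power law is strictly
   decreasing in α; a generator convention, not a claim about real
   data), then inverted: `c_ij = δ_ij^(−1/α*_ij)`. The pair exponent
   uses the same contact-weighted combination as the inference, whose
   row weights depend on the contacts themselves — the matrix is
   therefore computed by fixed-point iteration until the weights are
   self-consistent, which is what makes the noise-free round trip exact
   to machine precision.
5. **Noise** — optional multiplicative lognormal noise with a given
   coefficient of variation, applied symmetrically.

A second instance, `make_clustered_contacts`, plants a single
contact-enriched block (dense strong contacts) on a sparse weak
background — the clustering heuristic's premise stated directly as
data. It exists because in the geometric generator the
top-vs-bottom-exponent contact contrast is confounded: structural zeros
censor precisely the long-range pairs of weakly clustered beads, so
their surviving short-range contacts — amplified by the small exponent,
since `c = δ^(−1/α)` grows as α shrinks — can dominate the bottom-group
median. The planted-cluster instance is free of this censoring artifact
and is the one used to verify the contrast's direction.

What the generator does **not** emulate: read-level simulation
(fragments, enzymes, mappability), normalization biases, sub-unit
contacts, inter-chromosomal contacts, or ensemble heterogeneity (one
conformation generates all contacts). Recovery results on it say
nothing about those effects.

## Verification strategy

Every operation with a closed form is checked against it exactly;
everything else is checked against an independent oracle: clustering
coefficients against exhaustive neighbour-pair enumeration, path lengths
against a hand-rolled Floyd–Warshall, PT triples and backbone triangles
against brute-force scans, the unconstrained fit against the linear
KKT solution of its convex quadratic (the originally envisaged dense
α-lattice search is combinatorially infeasible beyond a few variables;
the KKT solve is exact where it applies, and the constrained case is
cross-checked by backend agreement plus feasibility residuals), the
embedding against exactly embeddable curves, and Kabsch against a
rotation-grid search. Pipeline-level recovery on the generator freezes
three figures: strength correlation ≥ 0.8 and distance correlation
≥ 0.99 at n = 100 noise-free, and |r| < 0.3 for the pure-noise negative
control.

## Known limitations

* **Triangle constraints under noise.** With even 5% multiplicative
  contact noise, thousands of backbone-triangle constraints on
  `δ(α) = c^(−α)` become binding and drag the fitted strengths far from
  the clustering-coefficient target: on noisy synthetic data the
  strength correlation collapses toward zero while the *unconstrained*
  fit retains r ≈ 0.85–0.95, and the wish-distance correlation stays
  ≈ 0.97 either way. For noisy inputs, fitting with `max_triangles = 0`
  (or the penalty backend, which enforces constraints softly) is the
  pragmatic choice; the hard-constraint formulation is best suited to
  internally consistent (normalized, smoothed) matrices.
* **Network density.** On dense matrices the contact network approaches
  completeness and clustering coefficients saturate toward the graph
  density, carrying little positional signal; the method's premise needs
  a sparse network, consistent with the published edge counts being far
  below "all nonzero pairs" (see above).
* **Scale.** The NLP with full constraint sets is practical to a few
  hundred beads on one CPU; at 40 kb chromosome scale the seeded caps on
  PT and triangle sets are required, and the zero-pair term of the
  embedding can be subsampled.
* **Single-structure assumption.** Both optimizations produce one
  conformation; population heterogeneity in the contacts is averaged
  into it.
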