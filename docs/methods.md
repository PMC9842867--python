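# Methods

## Model

hicstruct treats a cis-chromosomal Hi-C map as the adjacency matrix of
an edge-weighted undirected graph over N loci and poses reconstruction
as node regression: assign xyz coordinates to every node so that the
pairwise Euclidean distances reproduce target ("wish") distances
derived from the contacts.

**Contact→distance conversion.**  `d(i,j) = (1/CF_ij)^γ` for observed
pairs (`CF_ij > 0`).  Zero-contact pairs are treated as *unconnected*:
they carry no wish distance and never enter the training loss, rather
than being mapped to an infinite distance (the conversion is undefined
at CF = 0).  The diagonal is likewise excluded — self-distance is
identically zero.  γ is unidentifiable a priori and empirically lies
in [0.1, 2] for common cell types; the fit loops over the 20-value
grid {0.1, …, 2.0} and keeps the model with the highest dSCC against
its own γ's wish distances, ties broken toward smaller γ.

**Node embeddings.**  Second-order LINE on the raw-weight graph: the
model conditional `p2(v_j|v_i) = exp(u'_j·u_i) / Σ_{k∈N(i)} exp(u'_k·u_i)`
is fitted to the empirical edge-weight distribution by edge-sampling
SGD with K = 5 negative samples per edge drawn from the weighted
degree^¾ noise distribution.  Edges are sampled with probability
proportional to their weight.  Defaults: E = 512 (reduced to 64 in the
validation experiments), 10 epochs of min(200·|E_g|, 100 000) samples,
initial rate 0.025 with linear decay.  Samples are processed in
batches whose size is capped at ~4·N so the summed within-batch
updates stay close to sequential SGD — with much larger batches the
repeated per-node contributions act as a multiplied step size and can
diverge.  Embeddings are deterministic given a seed.  A first-order
proximity variant (`order=1`: pairs scored through the node vectors
directly, no separate context vectors) is available behind a flag;
the pipeline default is second-order, which is the conditional
objective the regressor consumes.

**Balancing.**  Knight–Ruiz matrix balancing scales the map to a
doubly stochastic matrix (entries in [0, 1], unit row/column sums),
which both conditions the optimization (raw counts reach 10^5) and
removes per-locus coverage bias.  The implementation is the standard
inner–outer Newton/conjugate-gradient iteration with tol = 1e-6 and a
1000-outer-iteration cap; if the Newton iteration leaves the positive
cone (matrices that are not fully indecomposable after zero-row
removal, or numerically hostile inputs) a damped symmetric
Sinkhorn–Knopp fixed point takes over, and the fallback is recorded in
the result's provenance note.  All-zero rows are removed before
balancing and reported via `kept_indices`.  No additional max-rescale
is applied after balancing: doubly stochastic output already lies in
[0, 1].

**Regressor.**  One consolidate–update graph convolution,
`x'_i = W1 x_i + W2·(Σ_j e_ij x_j / Σ_j e_ij)`, with the neighborhood
`N(i) = {j ≠ i : e_ij > 0}` taken on the balanced matrix and the
diagonal excluded (self-information enters through `W1 x_i`).  W1 and
W2 are E×E and bias-free.  The graph layer is followed by ReLU — it is
a hidden layer, and every hidden layer is ReLU-activated; the
nonlinearity sits between the update equation and the MLP and can be
disabled via `graph_relu` — then by a four-layer MLP (default widths
256/128/64, biases, ReLU) with a linear 3-unit output so the
coordinate domain is unrestricted.  All parameters are shared across
nodes; nothing in the network depends on N, which is what makes stored
models transferable.  Isolated nodes (zero off-diagonal weight)
consolidate to the zero vector.

**Training.**  Full-batch Adam (lr 0.001) on the MSE between structure
distances and wish distances over masked pairs, until the loss falls
below the convergence threshold (default 1e-5, from the explored grid
{1e-2, 1e-4, 1e-5, 1e-12}) or an epoch cap fires (default 10 000; cap
hits are flagged on the result).  Full batch is appropriate: maps at
the resolutions this targets have at most a few thousand loci.
Weights use seeded Glorot-uniform initialization, biases zero.  The
parameters achieving the lowest recorded loss are the ones returned,
so the reported loss is the best seen, not the last.  Gradients are
exact analytic backprop written in numpy; all parameters live in one
flat vector so the Adam update is a handful of vectorized operations.

## Generalization machinery

A trained model is a pure function of its stored parameters; inference
on a new map never mutates the checkpoint.  Two devices connect a
stored model to a map it was not trained on:

* **Row expansion.**  Across resolutions the maps of one chromosome
  have row counts in exact integer ratio k, *provided zero-contact
  bins are retained at read time* (the readers do this by default;
  `drop_empty` exists for single-map work).  The lower-resolution
  embedding matrix is expanded by repeating each row k consecutive
  times — output row r equals source row floor(r/k) — so equivalent
  rows describe the same genomic interval.
* **Procrustes alignment.**  Embeddings of two maps of the same
  chromosome are assumed approximately equivalent up to rotation,
  translation and scaling.  Both matrices are mean-centered, the E×E
  orthogonal transform minimizing ‖A·T − B‖_F is obtained from the SVD
  of AᵀB, and a single closed-form scale factor is applied; the target
  map's embeddings are transformed into the space the model was
  trained in.  Solving in the E-dimensional feature space keeps the
  transform well-defined when node counts differ before expansion; a
  literal N-side transform (SVD of B·Aᵀ) is available via
  `side="node"` for equal-shape inputs.  Alignment can only lower the
  Frobenius residual relative to leaving the embeddings untouched.
  Centering and scaling are included because translation and scale are
  part of the isometry assumption; disabling both recovers the bare
  orthogonal-Procrustes solution.

Generalization dSCC is evaluated at γ = 1 regardless of the training
γ: Spearman correlation is invariant under the monotone transform that
changing γ applies to the wish distances, so the choice is free and 1
is the convention used throughout.

## Evaluation

* **dSCC** — Spearman rank correlation (average ranks over ties)
  between structure distances and wish distances on masked pairs.
  Invariant to rigid motion and uniform scaling of the structure,
  which is the right property given that absolute scale is
  unidentifiable from contacts.  Undefined (error) when either
  distance vector is constant or fewer than 3 pairs exist.
* **dRMSD** — root-mean-square deviation of the same two vectors;
  optionally after applying the closed-form scalar
  `s* = Σ d·dist / Σ dist²` that minimizes the squared deviation, so
  structures of arbitrary scale can be compared.
* **Interpolation baseline** — a coarse structure resampled by placing
  k−1 equally spaced points on each segment, giving k(N−1)+1 points;
  when a target count differs (edge bins), the final coordinate is
  repeated or the tail truncated, logged.  This carries the coarse
  spatial configuration to the fine point count and is the null
  against which genuine generalization is judged.
* **Compartments** — A/B labels from the sign of the principal
  eigenvector of the Pearson correlation matrix of the KR-balanced map
  (raw counts optional via `normalization="raw"`; which normalization
  feeds the correlation is a genuinely open choice and is exposed).
  Constant rows are dropped and reported.  Absent external annotation
  (gene density, GC content) the sign of an eigenvector is arbitrary,
  so the convention "larger compartment = A" is applied; exact zeros
  go to B.
* **Region distance comparison** — mean structure distance of two pair
  sets plus a two-sided Mann–Whitney rank-sum p-value, for checks of
  the form "looped regions should sit closer than non-looped regions".

## Synthetic data

`hicstruct.synthetic` generates planted ground truth: a known curve
(regular helix; smoothed unit-step random walk; two Gaussian domains
joined for compartment tests) sampled at N loci, with contacts
`CF_ij = d(i,j)^(−1/γ)` so that the wish-distance conversion at the
generating γ recovers the true distances *exactly* at zero noise —
the identity every parameter-recovery experiment rests on.  Noise is
multiplicative log-normal with spread `noise_alpha` (contacts are
positive and heavy-tailed, so multiplicative noise is the natural
family).  Lower resolution is emulated by summing k×k bin blocks;
reduced sequencing coverage by symmetric binomial thinning of
integerized counts, which preserves expected totals.

What the synthetic experiments do **not** show: real maps carry
distance-dependent coverage decay, unmappable regions, translocations,
population heterogeneity (a map is an ensemble average over cells),
and enzyme-specific digestion bias.  Passing the planted-structure
tests demonstrates that the estimator inverts its own generative
assumption and that the generalization machinery behaves as designed;
it does not certify accuracy on real chromosomes, which in the
original setting is assessed against orthogonal experimental data.

## Validation experiment sizes and numerical choices

The validation runs (`scripts/acceptance.py`, `tests/test_acceptance.py`)
use reduced widths E = 64 and MLP 32/16/8 with N ∈ {30, 60, 100} for
the γ-grid recovery experiments, and an N=50→N=100 pair for the
cross-resolution ordering check.  The recovery runs cap training at
6000 epochs — chosen so that the γ = 1 runs actually reach the 1e-5
convergence threshold while the six 20-γ fits stay within a
ten-minute single-CPU budget; with much smaller caps training is
truncated far above the threshold and the selection among neighboring
γ values (whose wish distances differ only by a monotone transform on
noise-free data) is decided by optimization noise rather than by
goodness of fit.  The cross-resolution model is trained at γ = 1 only,
since the aligned-versus-unaligned comparison is evaluated at γ = 1
and does not involve the grid.

Other numerical choices: pair distances in the loss gradient are
floored at 1e-12 to avoid the singularity at coincident points;
KR tolerance 1e-6 on the squared-residual scale; Procrustes refuses
rank-0 input; dSCC refuses constant vectors rather than returning NaN;
the regular helix has exactly tied pairwise distances (distance
depends only on |i−j|), so rank correlations on helix fixtures sit a
hair below 1 even for perfect structures — tie-sensitive exactness
tests use tie-free point clouds instead.

## Known limitations

Single chromosome, cis contacts only; no `.hic`/`.cool` binary
parsing; one graph-convolution layer (no stacking, attention, or
neighborhood sampling); CPU-only full-batch training, practical to a
few thousand loci; the γ grid selection on noise-free synthetic data
is weakly identified near the optimum (see above), so recovered γ
should be read as "the grid neighborhood of the truth".
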