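# Methods

## Problem setting

A spatial transcriptomics section is a set of n spots, each with a 2-D
coordinate, a vector of gene counts, and optionally a precomputed histology
feature vector (the package never touches raw H&E images). The goals are
(i) an embedding whose clusters are contiguous, biologically coherent
spatial domains, and (ii) a denoised expression matrix in which marker-gene
patterns align with those domains.

## Preprocessing

Counts are scaled per spot to `target_sum` (default 1e4, the droplet-era
convention), log(1+x)-transformed, and reduced to the `n_hvg` (default 3000)
most variable genes. Gene variability is ranked by unbinned dispersion —
variance over mean of the log-normalized values — with ties broken by gene
name so the selection is deterministic. The mean-binned scanpy flavors
(`seurat`, `cell_ranger`) are available through the `flavor` argument; the
unbinned criterion is the default because binned z-scores degenerate on very
small inputs (singleton mean-bins), while the two agree on realistically
sized data where per-bin statistics are populated. Genes with zero total
count are dropped before ranking (their dispersion is undefined). Spots with
zero total count are an error, reported by id.

## Graph construction

* **Spatial graph.** The alpha-complex rule on the Euclidean plane: edge
  (i, j) exists iff it is a Delaunay edge and ‖x_i − x_j‖ ≤ 2σ. The radius σ
  is the mean k-NN distance over spots (k = 6, hexagonal packing). All
  geometry is Euclidean; a cosine metric on 2-D stage coordinates is
  degenerate under translation and is not offered. Degenerate co-circular
  configurations (square lattices) are broken by a deterministic jitter of
  1e-9 × the bounding-box diagonal before triangulation. Duplicate
  coordinates collapse to one Voronoi site; the duplicates are connected to
  each other and inherit the site's edges. With fewer than three distinct
  sites the graph falls back to the plain distance threshold at 2σ.
* **Histology graph.** Euclidean KNN (k = 6) on the per-spot feature
  vectors, symmetrized by union (edge iff either endpoint lists the other);
  union rather than mutual intersection keeps the graph connected at small k.
* **Fusion.** `G_w = w_s·A_s + w_h·A_h + I` with defaults w_s = w_h = 0.5;
  without histology `G_w = A_s + I`. The identity term guarantees a strictly
  positive diagonal, so degree normalization never divides by zero.

## Communities and their strength

Leiden (RB-configuration objective, resolution 1.0, fixed seed) runs on a
15-NN graph over the top 50 principal components of the preprocessed
expression — the conventional KNN recipe, since community detection needs a
graph rather than a raw matrix. Communities are detected once, before
training, and held fixed.

Community strength is the per-community summand of Newman–Girvan modularity
on a binary graph,

    S_c = |ε_c|/|ε| − [Σ_{v∈c} d(v)]² / (4|ε|²),

with |ε| the undirected edge count, |ε_c| the within-community edges and
d(v) the degree. Summing S_c over communities reproduces modularity Q
exactly; the test suite verifies this identity against networkx at 1e-10 on
random graphs, and the two-triangle bridge fixture gives the closed form
S = 5/28. Strengths are recomputed per graph (the ε terms are
graph-specific), sharing the one expression-derived partition. An edgeless
graph is an error (the formula divides by |ε|).

## Community-aware corruption

Both corruption operators map importance scores through the normalization
n̄(x) = (x_max − x)/(x_max − x_mean): the most important item gets 0
(never preferentially corrupted), items below the mean exceed 1, and final
keep-probabilities are clipped to [0, 1]. A constant score vector maps to
all zeros (no preferential corruption).

* **Attribute voting (gene masking).** Each spot votes for each gene with
  weight equal to its community's strength: votes_g = Σ_i |X_ig|·S_{c(i)}.
  Negative totals (communities weaker than random) are floored at zero, the
  totals are log(1+·)-compressed, and n̄-normalized into the penalty p_a.
  One Bernoulli draw per gene with keep-probability clip(1 − p_a·λ_a)
  masks the whole column — voting is about genes, so corruption is
  column-wise.
* **Edge dropping.** Intra-community edges score their community's
  strength, n̄-normalized among intra-community edges: edges inside strong
  communities are kept. Inter-community edges get −(1 + n̄(S_i + S_j)),
  normalized among themselves: the deliberate −1 offset makes the penalty
  strictly negative even at the normalization's argmax (where n̄ = 0), so
  after clipping inter-community edges always survive. Only the sign matters
  downstream; the magnitude is immaterial once clipped. Each undirected edge
  is drawn once and applied symmetrically.

Per-view corruption levels default to λ_a = (0.1, 0.2) and λ_e = (0.2, 0.3):
mild, and asymmetric so the two views differ in distribution as well as in
draws. Views are resampled every epoch (the loss is an expectation over view
pairs) from seeds spawned deterministically from the run seed.

## Model and objective

* **Encoder.** Two-layer GCN, Z = Â·relu(Â·X·W0)·W1 with
  Â = D̃^{-1/2}(A+I)D̃^{-1/2}; hidden 256, latent 64, Glorot-uniform init.
  The spatial and histology branches use separate encoders.
* **Contrastive loss.** Symmetrized InfoNCE over the two views with cosine
  logits at temperature τ (default 0.5): positives are the same spot across
  views; negatives are all other spots in both the same and the other view,
  all exponentiated in the denominator. Same-community pairs receive an
  additive logit bonus γ(k)·S_c/τ, with the ramp
  γ(k; k0, γ_max) = min{max{0, k − k0}, γ_max} (defaults k0 = 20,
  γ_max = 1.0) switching the community term on only after the embedding has
  taken shape. γ = 0 recovers plain InfoNCE exactly, which is the surface
  the brute-force oracle tests check. The loss is evaluated as one fused
  computation node with the closed softmax-form gradient and a log-sum-exp
  shift, rather than op-by-op, to keep n×n intermediates off the autodiff
  tape.
* **Attention fusion.** Per spot, each view's embedding is scored by
  W2·tanh(W1·z + b1) + b2 with shared weights; a two-way softmax yields
  α ∈ (0,1)², rows summing to 1, and Z = α_s·Z_s + α_h·Z_h. Without
  histology, fusion is bypassed (Z = Z_s) and λ_HE is forced to 0.
* **Decoder and reconstruction.** One GCN layer on degree-normalized G_w
  (no extra self-loops — G_w already contains +I) maps latent to gene space;
  the reconstruction loss is mean squared error against the preprocessed
  matrix. MSE is used as the norm: differentiable and scale-stable in the
  entry count.
* **Optimization.** Adam (lr 1e-3), 300 epochs by default. All randomness —
  init, per-epoch view seeds — derives from the single config seed, so runs
  are bitwise reproducible. The training loop runs on a minimal reverse-mode
  autodiff engine over numpy arrays written for exactly the ops this
  computation graph needs; its gradients are tested against finite
  differences. A non-finite loss aborts with the offending term named.

## Downstream

Domains come from a Gaussian mixture on the embedding (full covariances,
k-means init under seed) — an equivalent stand-in for the R model-based
clustering tradition, chosen to avoid a second language runtime — or from
Louvain/Leiden on a 15-NN graph of the embedding. Agreement uses the
permutation-model adjusted Rand index and NMI with arithmetic normalization
(the common default). Predicted labels are relabeled contiguous-from-0 in
order of first appearance, making label vectors reproducible bitwise.

## Synthetic tissue

The generator emulates a barcoded section: spots on an integer lattice,
domains as horizontal bands (near-equal contiguous row blocks, a stand-in
for laminar cortex) or Voronoi patches (irregular regions akin to tumor
sections); each domain owns `markers_per_domain` marker genes whose mean is
`marker_fold_change` × base inside the domain. Counts are negative binomial
parameterized by mean μ and dispersion φ (variance μ + φμ²; φ → 0 is the
Poisson limit), with independent dropout zeroing entries at the configured
rate — the standard surrogate for spatial count noise. Pseudo-histology
features are a (noisy) embedding of the one-hot domain identity.

What the simulation does *not* emulate: platform-specific spot geometry
(hex vs. square barcoding), spatial gradients within a domain, cell-type
mixtures per spot, segment-specific library-size trends, or realistic image
texture. Passing tests therefore demonstrate that the method recovers
planted, cleanly separable domain structure under overdispersed sparse
noise — not performance on any real platform's artifacts.

## Problem sizes and numerical choices

The end-to-end checks run on a 30×30 lattice (900 spots, 200 genes, four
bands, fold-change 5, dropout 0.3) with 300 training epochs — large enough
that domain recovery is a real test (raw marker-domain correlation is ~0.33
before denoising), small enough for a laptop-class single-CPU run. On that
fixture the embedding's GMM(k=4) clustering reaches ARI ≥ 0.9 across seeds
and the denoised marker-domain correlation roughly doubles; the acceptance
script recomputes both.

Tolerances: the modularity identity is checked at 1e-10 (pure arithmetic);
loss oracles at 1e-6 (float64 summation order); Bernoulli calibrations at
3 binomial standard errors over 10,000 draws. Degenerate inputs are
resolved as: constant score vectors → no preferential corruption; all-equal
coordinates → error; single-spot contrastive loss → 0 (no negatives);
epochs = 0 → the untrained encoder's embedding is returned unchanged.

## Known limitations

* Full-batch training with dense n×n similarity matrices: memory grows
  quadratically in spots, so sections beyond a few tens of thousands of
  spots need neighbor sampling, which is out of scope.
* Communities are fixed after initialization; a drifting embedding could in
  principle justify re-detection, but one detection pass matches the
  "initial communities" design and keeps the objective stationary.
* The exact enhancement of the InfoNCE logits by community strength admits
  several readings; the additive same-community bonus used here degrades
  gracefully to plain InfoNCE at γ = 0 and is the only surface asserted by
  oracles.
* The GMM stand-in for model-based clustering fixes one covariance family
  (full) rather than selecting among parameterizations by BIC.
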