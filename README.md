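# csgae — community-strength graph autoencoder for spatial transcriptomics

Spatially resolved transcriptomics measures per-spot gene expression together
with the spots' positions in a tissue section, but the counts are sparse and
noisy, and the central analysis task — partitioning the section into spatial
domains such as cortical layers or tumor regions — is easily derailed by that
noise. `csgae` is a library and command-line tool that learns a denoised,
spatially aware embedding of the spots with a graph contrastive autoencoder
whose augmentations are guided by *community strength*, and clusters that
embedding into spatial domains.

The pipeline:

1. **Graphs.** A spatial graph `G_s` connects spots by the alpha-complex
   rule: an edge is kept iff it is a Delaunay edge (the two Voronoi cells are
   adjacent) and its length is at most `2σ`, with `σ` the mean k-nearest-
   neighbor distance (k = 6 by default, matching hexagonal spot packing).
   When per-spot histology feature vectors are available, a Euclidean KNN
   graph `G_h` is built on them, and the two are fused as
   `G_w = w_s·A_s + w_h·A_h + I` (defaults `w_s = w_h = 0.5`).
2. **Community strength.** Leiden communities (resolution 1.0) are detected
   on the expression profile; each community `c` is scored by its summand of
   Newman–Girvan modularity,
   `S_c = |ε_c|/|ε| − [Σ_{v∈c} d(v)]² / (4|ε|²)`,
   so that `Σ_c S_c = Q`, the modularity of the partition.
3. **Community-aware augmentation.** Two corrupted views of each graph are
   drawn per epoch. Communal attribute voting masks whole gene columns with
   probability `clip(1 − p_a·λ_a)`, where `p_a` down-weights genes that
   receive strong community-weighted votes; community edge dropping removes
   edges with probability `clip(1 − p_e·λ_e)`, preferentially keeping edges
   inside strong communities and never preferentially dropping
   inter-community edges.
4. **Contrastive autoencoder.** A two-layer GCN encoder embeds both views;
   a symmetrized InfoNCE loss with cosine logits at temperature `τ` (plus a
   ramped same-community bonus `γ(k)·S_c`) aligns them. An attention layer
   fuses the spatial and histology embeddings per spot, and a GCN decoder on
   `G_w` reconstructs the normalized expression. The total objective is
   `L = λ_topo·L_topo + λ_HE·L_HE + λ_recon·L_recon`
   with defaults 0.1 / 0.1 / 1.0 (`λ_HE = 0` without histology).
5. **Domains.** The final embedding is clustered by a Gaussian mixture
   (or Louvain/Leiden on a KNN graph); ARI and NMI are reported when
   ground-truth annotations exist.

A first-class synthetic-tissue generator (negative-binomial counts with
dropout on a lattice of banded or Voronoi-patch domains, with optional
pseudo-histology features) makes the whole pipeline testable end to end.

## Worked example

```python
import numpy as np
from csgae import (TissueSimSpec, simulate_tissue, preprocess, estimate_radius,
                   build_spatial_graph, fuse_graphs, detect_communities,
                   community_strength, ModelConfig, train, cluster_embedding,
                   evaluate_domains)

spec = TissueSimSpec(grid_shape=(20, 20), n_domains=3, n_genes=120,
                     markers_per_domain=8, marker_fold_change=5.0,
                     dropout_rate=0.3, seed=0)
ds = preprocess(simulate_tissue(spec), target_sum=1e4, n_hvg=3000)
sigma = estimate_radius(ds.coords, k=6)
gs = build_spatial_graph(ds.coords, sigma)
gw = fuse_graphs(gs, None)
part = detect_communities(ds, resolution=1.0, seed=0)
S = community_strength(gs, part)
print(f"sigma = {sigma:.3f}; spatial edges = {gs.n_edges}")
print(f"{part.n_communities} communities; modularity = {S.sum():.3f}")
model = train(ds, gs, None, gw, part, ModelConfig(epochs=150, seed=0))
print(f"final loss = {model.loss_history[-1]['total']:.3f}")
res = cluster_embedding(model.final_embedding, "gmm", 3, seed=0)
ari, nmi = evaluate_domains(res.labels, ds.labels)
print(f"ARI = {ari:.3f}, NMI = {nmi:.3f}")
```

Output:

```
sigma = 1.173; spatial edges = 1151
5 communities; modularity = 0.134
final loss = 6.510
ARI = 0.918, NMI = 0.881
```

The simulated 20×20 section carries three horizontal bands of 400 spots;
`σ ≈ 1.17` is the mean 6-NN lattice distance, the Leiden partition of the
expression splits the bands into five communities with total modularity
0.134 on the spatial graph, and after 150 training epochs the Gaussian
mixture on the 64-dimensional embedding recovers the three bands almost
perfectly (ARI 0.92 against the planted labels).

The same run from the shell:

```bash
csgae run --simulate --seed 0 --outdir out/demo
```

writes the graphs, community table, embedding, `domains.csv`, `metrics.json`
and a reproducibility manifest under `out/demo/`.

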