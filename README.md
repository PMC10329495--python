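# schoml

Joint clustering of parallel multi-omics single-cell data by multi-modal
high-order neighborhood Laplacian matrix optimization (scHoML).

Assays such as CITE-seq (RNA + surface-protein ADT counts) and scM&T-seq
(methylome + transcriptome) profile several omics layers in the *same*
cells. Each layer views cellular state differently, and each is noisy and
sparse in its own way, so clustering cells from any single layer — or from a
naive concatenation — misses structure. `schoml` integrates the layers at
the level of their neighborhood graphs and returns a single embedding and
cell clustering.

## Model

For each modality p = 1..V (after per-feature z-scoring and PCA), a
k-nearest-neighbor Gaussian affinity graph W_p^(1) is built, plus a
second-order graph W_p^(2) whose similarities compare whole neighborhood
profiles (rows of W_p^(1)) between cells that share at least one neighbor —
capturing shared-neighborhood structure that is robust to noise in
individual edges. Each graph gives a symmetric normalized Laplacian
L_p^(i) = I − D^{−1/2} W_p^(i) D^{−1/2}.

The fused Laplacian is approximated by a low-rank factorization
I − WΛWᵀ and fitted jointly with the embedding H by

    min  tr(Hᵀ(I − WΛWᵀ)H) + ‖ I − WΛWᵀ − (λ L_μ^(1) + (1−λ) L_μ^(2)) ‖_F²

    s.t. WᵀW = HᵀH = I_c,  0 ≤ Λ_kk ≤ 1,  0 ≤ λ ≤ 1,
         L_μ^(i) = Σ_p μ_p L_p^(i),  μ ≥ 0, Σ μ_p = 1,

where μ weights the modalities, λ mixes the two graph orders, and the rows
of H ∈ R^{n×c} are the cells' joint coordinates. The problem is solved by
alternating exact block updates (closed forms for λ and Λ, eigenvector
problems for W and H, a simplex-constrained QP for μ), so the objective is
non-increasing and bounded below by zero. Cells are then grouped by
agglomerative hierarchical clustering on a correlation (or L1) distance
between rows of H, with the cluster number chosen by the mean silhouette
width (small n) or the variance-ratio criterion (large n).

The package also ships the two synthetic benchmark generators (block factor
models with per-type dropout, additive Gaussian noise, and a binarized
chromatin-like modality) so the headline results are reproducible offline.

## Worked example

```python
import numpy as np
from schoml import SCHoML, Sim2Config, generate_sim2, ari, nmi

ds = generate_sim2(Sim2Config(seed=7))          # 500 cells, 4 cell types
model = SCHoML(n_components=4, k_neighbors=10).fit(ds.modalities)
print("estimated clusters:", model.n_clusters_)
print("criterion:", model.criterion_used_)
print("modality weights mu:", np.round(model.mu_, 3))
print("order weight lambda:", round(model.lambda_weight_, 3))
print("ARI:", ari(ds.labels, model.labels_), " NMI:", nmi(ds.labels, model.labels_))
```

prints

```
estimated clusters: 4
criterion: silhouette
modality weights mu: [0.544 0.456]
order weight lambda: 0.005
ARI: 1.0  NMI: 1.0
```

The silhouette criterion picks 4 clusters without being told the truth; both
modalities contribute (μ ≈ 0.54/0.46 — necessary here, since the
transcriptome modality alone carries only 3 distinct block signatures);
λ near 0 means the second-order graphs dominate the fused Laplacian for this
dataset; and the recovered labels match the generating cell types exactly
(ARI = NMI = 1).

The same pipeline is available from the shell:

```bash
schoml simulate --dataset 2 --k2 4 --seed 7 --out sim2/
schoml fit --modality sim2/X1.csv --modality sim2/X2.csv \
    --c 4 --k 10 --out embedding.csv --trace trace.csv --labels-out pred.csv
schoml evaluate --truth sim2/labels.csv --pred pred.csv
```

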