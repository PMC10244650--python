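# umint

Unsupervised integration of paired single-cell multi-omics data with a
modular autoencoder.

## The problem

Assays such as CITE-seq measure two (or more) omics layers — thousands of
RNA transcripts alongside tens of surface proteins (ADTs), or RNA alongside
chromatin accessibility — in the *same* cells. Joint analysis wants one
low-dimensional embedding per cell that fuses all layers, but the layers
differ wildly in dimensionality, sparsity and noise, and dense neural
integration models pay a heavy parameter cost for the wide input.

`umint` implements a light-weight modular autoencoder for this task. Each
modality X_i (n cells × d_i features) gets its own encoder module

    h_2i = ReLU(W_1i x_i + b_1i),                    W_1i : d_i × n_i

and the modules are fused at a shared bottleneck of width k

    h_3 = ReLU( Σ_i W_2i h_2i + b_2 ),               h_3 : the embedding

with a mirrored decoder (per-modality ReLU module, then a linear
reconstruction head). Because the input layer is block-structured rather
than dense, its weight count is Σ_i d_i·n_i instead of (Σ d_i)(Σ n_i) — a
saving of Σ_i d_i Σ_{j≠i} n_j, incurred again at the reconstruction layer.
Training minimizes

    L = (1/n) Σ_i λ_i ‖X_i − X̃_i‖²_F  +  α Σ_j ‖h_j‖₁  +  β Σ_j ‖W_j‖²_F

with per-modality balancing weights λ_i (default 1/d_i), an L1 activity
penalty and an L2 weight penalty, via mini-batch Adam. The package also
provides:

- matched stacked-input baselines (plain, denoising and sparse autoencoders)
  sharing the same trainer and hyperparameters;
- the evaluation stack: ARI and FMI computed from the contingency table,
  silhouette / Davies–Bouldin, and the Overall Reconstruction Score
  (ORS = mean over modalities of the Pearson correlation between original
  and reconstructed pairwise cell distances);
- per-modality preprocessing (library-size normalization to 10,000 + log1p,
  highly-variable-feature selection, z-scaling with clipping for RNA;
  centered log-ratio for ADT panels);
- a synthetic paired-data generator with known cell types, dropout and batch
  effects, so the full pipeline is testable without downloads.

Everything, including backpropagation and Adam, is implemented in NumPy.

## Worked example

```python
import numpy as np
from umint import (SimulationConfig, UMINTConfig, simulate, preprocess_dataset,
                   train, encode, decode, cluster_embedding, ari, fmi, ors,
                   parameter_reduction)

# 1. a CITE-seq-like dataset: 2,000 cells, 5 cell types, RNA (500) + ADT (20)
ds = simulate(SimulationConfig(seed=1))

# 2. standard per-modality preprocessing
labels = dict(zip(ds.data.cell_ids, ds.true_labels))
data, _ = preprocess_dataset(ds.data.modalities, ["rna", "adt"], labels=labels,
                             n_top=None)

# 3. train and embed
config = UMINTConfig(seed=1)          # bottleneck 64, 25 epochs, batch 16, Adam
params, history = train(data, config)
embedding, _ = encode(params, data)

# 4. evaluate the embedding and the reconstruction
pred = cluster_embedding(embedding, k=5, method="kmeans", seed=1)
recons, _ = decode(params, embedding)
score = ors(data, recons, seed=1)
pc = parameter_reduction(data.dims, config.resolve(data.dims).hidden_widths)

print(f"training loss: {history[0].total:.3f} -> {history[-1].total:.3f}")
print(f"ARI  (k-means, k=5): {ari(data.labels, pred):.3f}")
print(f"FMI  (k-means, k=5): {fmi(data.labels, pred):.3f}")
print(f"ORS: {score.ors:.3f}  (per-modality rho: "
      + ", ".join(f"{r:.3f}" for r in score.rho) + ")")
print(f"first-layer weights: {pc.tp_umint} (modular) vs {pc.tp_ae} (dense AE); "
      f"total saving {pc.tp_total_reduction}")
```

Output:

```
training loss: 1.566 -> 1.028
ARI  (k-means, k=5): 0.995
FMI  (k-means, k=5): 0.996
ORS: 0.810  (per-modality rho: 0.703, 0.917)
first-layer weights: 31820 (modular) vs 41080 (dense AE); total saving 18520
```

Reading this: training reduced the objective by a third; k-means on the
64-dimensional embedding recovers the five simulated cell types almost
perfectly (ARI/FMI ≈ 1 means near-exact agreement with the true labels); the
trained decoder preserves ~81% of the pairwise-distance geometry of the
inputs on average (ADT better than the heavily dropped-out RNA layer); and
the modular first layer trains 9,260 fewer weights than a dense autoencoder
of matched capacity — 18,520 fewer counting the mirrored reconstruction
layer.

## Command line

```sh
umint simulate --n-cells 2000 --clusters 5 --dims 500,20 --seed 1 --out fixtures/
umint train --modality rna:fixtures/rna/matrix.mtx \
            --modality adt:fixtures/adt/matrix.mtx \
            --labels fixtures/labels.tsv --seed 1 --out run1/
umint evaluate --embedding run1/embedding.csv --labels fixtures/labels.tsv \
               --out run1/metrics.json
umint compare --fixtures fixtures/ --n-seeds 3 --out cmp/
```

Each command writes its artifacts plus a `manifest.json` recording resolved
parameters, input digests and output paths.

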