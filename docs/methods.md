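# Methods

## Model

`umint` learns a joint embedding of m paired omics matrices X_1…X_m
(n cells, d_i features each, identical cell order). The network is a
feed-forward autoencoder whose first layer is block-structured: modality i
connects only to its own encoding module of width n_i,

    h_2i = ReLU(W_1i x_i + b_1i)            W_1i : d_i × n_i
    h_3  = ReLU(Σ_i W_2i h_2i + b_2)        W_2i : n_i × k

and h_3 (width k, the bottleneck) is the embedding used downstream. The
decoder mirrors the encoder — per-modality ReLU modules h_4i =
ReLU(W_3i h_3 + b_3i) followed by *linear* reconstruction heads
x̃_i = W_4i h_4i + b_4i; reconstructions are unbounded because inputs are
z-scaled or CLR-transformed and so carry both signs. One encoding and one
decoding module per modality is used throughout; deeper module stacks are
out of scope for this version.

The objective is

    L = (1/n) Σ_i λ_i ‖X_i − X̃_i‖²_F
        + α Σ_{j=2..4} ‖h_j‖₁  +  β Σ_{j=2..4} ‖W_j‖²_F

Reading the layer summation literally, the L2 term covers W_2i, W_3i, W_4i
but not the input-layer weights W_1i; a config switch
(`include_input_l2=True`) extends it to the first layer for users who regard
that exclusion as a notational accident. The L1 activity term is computed as
the *mean over cells* of the per-cell L1 norm of every hidden activation
(h_2i, h_3, h_4i), so α keeps its meaning when the batch size changes; the
reconstruction term likewise divides by the number of cells in the batch.

Optimization is mini-batch Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8) with
hand-derived gradients in NumPy. The ReLU subgradient at zero is taken as
zero; since hidden activations are non-negative, the L1 term's subgradient
is α/n on active units and zero on dead ones, which backpropagation applies
through the same activation masks as the reconstruction signal.

## Parameter accounting

The modular input layer trains Σ_i d_i n_i weights where a dense autoencoder
of matched total width trains (Σ d_i)(Σ n_i). The saving,
Σ_i d_i Σ_{j≠i} n_j, recurs at the mirrored reconstruction layer, so the
total saving is twice that. `count_parameters_umint`,
`count_parameters_dense` and `parameter_reduction` expose these closed
forms (weight entries only, biases excluded, matching the formulas; an
`include_biases` flag adds them for full-model audits), and the builders are
tested to allocate exactly these counts. With m = 1 the block structure *is*
a dense layer, so the modular network degenerates to a plain autoencoder and
the saving is zero — the baselines exploit this by training through the same
code path.

## Defaults and what they mean

| Parameter | Default | Meaning / rationale |
|---|---|---|
| k (bottleneck) | 64 | embedding width; standard for single-cell latent spaces |
| n_i (module width) | min(128, max(16, ⌈d_i/8⌉)) | scales with modality width, floored so narrow ADT panels keep capacity |
| λ_i | 1/d_i | makes each reconstruction term a per-feature MSE, so a 500-feature layer cannot drown a 20-feature one |
| α | 1e-4 | L1 activity coefficient |
| β | 1e-3 | L2 weight coefficient |
| epochs / batch | 25 / 16 | fixed training recipe; no early stopping |
| learning rate | 1e-3 | Adam default |
| init | Glorot-uniform, seeded | biases start at zero |

Baselines: the denoising variant corrupts *inputs* with additive Gaussian
noise of sd = `noise_level` × per-feature sd (targets stay clean); the
sparse variant adds its own L1 coefficient on hidden activations (default
1e-4). Both degenerate exactly to the plain autoencoder when their extra
knob is zero, which the tests assert trace-for-trace.

## Preprocessing

RNA-like counts: each cell scaled to a total of 10,000, log1p, selection of
the top-variance features (plain variance of the log-normalized values —
deterministic and dependency-free, rather than a fitted mean–variance
trend), then per-feature z-scoring with population variance and clipping at
±10; zero-variance features map to zero. ADT-like counts: centered log-ratio
per cell, log(x + 1) minus the cell's mean log, treating the panel as a
per-cell composition; pseudocount 1 avoids log 0 (pseudocount 0 gives the
classical CLR whose rows sum to exactly zero). Natural log throughout.
Cells are aligned across modalities by sorted barcode intersection — a
canonical order independent of file order. Cells with zero total count must
be removed by the caller; the error lists the offending barcodes.

## Evaluation

ARI and FMI are computed from the contingency table between two labelings
(pair counts via Σ C(c_ij, 2) and the marginals). When both partitions are
trivial (all singletons or a single cluster) the ARI denominator vanishes;
the conventional value is 1 when the partitions are identical (compared by
first-appearance codes, hence rename-invariant) and 0 otherwise. Both
implementations are tested to 1e-12 against a brute-force enumeration of all
N(N−1)/2 pairs and against scikit-learn.

Clustering of embeddings uses k-means (k-means++, 10 restarts, seeded) or
agglomerative clustering with Ward linkage on Euclidean distances —
configurable, with Ward as the conventional choice for recovering k compact
clusters. Silhouette and Davies–Bouldin come from scikit-learn; the
Davies–Bouldin index diverges when two cluster centroids coincide.

The Overall Reconstruction Score is the unweighted mean over modalities of
the Pearson correlation between the condensed Euclidean distance matrices of
the original and reconstructed data, on a seeded subsample of at most 1,000
cells (pairwise distances are quadratic in cells). Euclidean distance
matches the scaled-data context; constant reconstructions are rejected
rather than scored. In the matched comparison workflow, ORS is computed on
held-out cells of a seeded 80:20 split while clustering metrics use all
cells, and the report carries per-seed rows plus per-method medians.

## Synthetic data generator

The generator emulates what the integration model assumes: a shared
low-dimensional cell state observed through heterogeneous noisy views. Per
dataset: k cluster centers are drawn at random directions and rescaled until
all pairwise distances reach `cluster_separation` (rejection, seeded);
each cell's latent state is its center plus unit Gaussian scatter; modality
i observes softplus(z A_i) through a seeded Gaussian loading matrix plus
additive Gaussian noise; count-like modalities draw Poisson counts with the
(clipped) softplus value as rate — the additive noise supplies mild
overdispersion without a second dispersion parameter; independent Bernoulli
dropout zero-masks entries; with ≥ 2 batches, a per-batch Gaussian feature
shift of sd `batch_shift_sd` is added (counts are re-rounded and clipped at
zero).

Defaults describe a small CITE-seq-like study and are the conditions under
which the package's end-to-end claims are tested: 2,000 cells, 5 equally
likely cell types, a 500-feature count modality with 50% dropout paired
with a dense 20-feature panel, latent dimension 10, separation 6 (clearly
distinct populations, as major immune lineages are after standard
preprocessing), noise sd 0.5 (moderate relative to softplus signal of order
1–3).

What it does **not** emulate: realistic library-size variation, gene–gene
correlation beyond the shared latent factors, negative-binomial
overdispersion, fragment-level chromatin structure, or nonlinear batch
effects. Passing the synthetic benchmarks therefore demonstrates that the
implementation is correct and that the architecture recovers a shared
latent geometry under dropout and noise — not that any particular score
will be attained on real data.

## Numerical choices

- Finite-difference gradient audits use central differences with ε = 1e-6
  and reject samples whose perturbation flips any ReLU activation pattern:
  the objective is piecewise-smooth and has no derivative on those kinks.
- Training shuffles cells each epoch from a generator seeded by the run
  seed; identical seeds reproduce loss traces to 1e-6 on one platform
  (bitwise identity across platforms is not claimed).
- Divergence (non-finite loss) raises an error reporting the last finite
  epoch loss rather than continuing.
- Zero-variance features z-score to zero; ties in variance-based feature
  selection keep original feature order (stable sort).
- The benchmark workflow (`synthetic_benchmark`) runs the full study at
  2,000 cells; unit tests use 300–400-cell versions of the same generator
  so the suite stays fast.

## Limitations

- One encoding/decoding layer per modality; no unpaired-sample integration,
  missing-modality imputation or feature-importance extraction.
- Batch effects are not explicitly corrected; the generator can produce
  them so their effect on the embedding can be measured.
- The Poisson count model understates the overdispersion of deeply
  sequenced real data.
- Model archives are NumPy `.npz` files and are not interchangeable with
  other frameworks.
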