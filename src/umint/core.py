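"""The UMINT network: modality-wise encoders fused at a shared bottleneck.

UMINT integrates m paired omics modalities X_1..X_m (n cells, d_i features)
into one k-dimensional embedding. Each modality gets its own narrow encoder
module (d_i -> n_i, ReLU); the module outputs are summed into a shared
bottleneck (ReLU) whose activations are the embedding. The decoder mirrors
this: per-modality decoding modules (k -> n_i, ReLU) followed by linear
reconstruction heads (n_i -> d_i). Because the input layer connects only
within its own modality, the first-layer weight count is sum_i d_i*n_i
instead of the (sum d_i)(sum n_i) of a dense autoencoder — the parameter
saving that makes the architecture light-weight.

The training objective is

    L = (1/n) sum_i lambda_i ||X_i - Xhat_i||_F^2
        + alpha * sum_{layers j=2..4} ||h_j||_1   (mean per-cell L1)
        + beta  * sum_{layers j=2..4} ||W_j||_F^2

i.e. lambda-weighted squared reconstruction error per modality, an L1
activity penalty on hidden activations, and an L2 weight penalty that (read
literally from the layer summation) excludes the input-layer weights W_1i.
Optimization is mini-batch Adam; everything is implemented in NumPy with
hand-derived gradients.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_preprocess import PairedDataset, ValidationError

__all__ = [
    "UMINTConfig",
    "UMINTParameters",
    "LayerActivations",
    "Embedding",
    "LossBreakdown",
    "ParameterCount",
    "default_hidden_widths",
    "build_model",
    "encode",
    "decode",
    "compute_loss",
    "train",
    "count_parameters_umint",
    "count_parameters_dense",
    "parameter_reduction",
    "save_model",
    "load_model",
    "write_embedding_csv",
    "read_embedding_csv",
]

FORMAT_VERSION = 1


def default_hidden_widths(dims: Sequence[int]) -> list[int]:
    """Per-modality encoder widths: n_i = min(128, max(16, ceil(d_i/8)))."""
    return [int(min(128, max(16, -(-d // 8)))) for d in dims]


@dataclass
class UMINTConfig:
    """Hyperparameters of a UMINT run.

    ``lambdas="auto"`` resolves to 1/d_i per modality so each reconstruction
    term is a per-feature mean squared error, balancing modalities of very
    different width. ``alpha``/``beta`` are the L1-activity and L2-weight
    coefficients; defaults follow the published training recipe
    (25 epochs, batch 16, Adam, alpha=1e-4, beta=1e-3, bottleneck 64).
    """

    hidden_widths: list[int] | None = None
    bottleneck_width: int = 64
    lambdas: list[float] | str = "auto"
    alpha: float = 0.0001
    beta: float = 0.001
    epochs: int = 25
    batch_size: int = 16
    learning_rate: float = 0.001
    seed: int = 0
    include_input_l2: bool = False

    def resolve(self, dims: Sequence[int]) -> "UMINTConfig":
        """Return a copy with widths and lambdas made concrete for ``dims``."""
        hw = self.hidden_widths or default_hidden_widths(dims)
        if len(hw) != len(dims):
            raise ValidationError(
                f"hidden_widths has {len(hw)} entries for {len(dims)} modalities"
            )
        if isinstance(self.lambdas, str):
            if self.lambdas != "auto":
                raise ValidationError(f"unknown lambdas spec {self.lambdas!r}")
            lam = [1.0 / d for d in dims]
        else:
            lam = list(self.lambdas)
        if len(lam) != len(dims):
            raise ValidationError(
                f"lambdas has {len(lam)} entries for {len(dims)} modalities"
            )
        if any(l < 0 for l in lam) or self.alpha < 0 or self.beta < 0:
            raise ValidationError("lambda, alpha and beta must be non-negative")
        if any(h < 1 for h in hw) or self.bottleneck_width < 1:
            raise ValidationError("layer widths must be positive")
        if self.bottleneck_width >= sum(dims):
            raise ValidationError(
                f"bottleneck width {self.bottleneck_width} must be smaller than "
                f"total input width {sum(dims)}"
            )
        return UMINTConfig(
            hidden_widths=list(hw), bottleneck_width=self.bottleneck_width,
            lambdas=lam, alpha=self.alpha, beta=self.beta, epochs=self.epochs,
            batch_size=self.batch_size, learning_rate=self.learning_rate,
            seed=self.seed, include_input_l2=self.include_input_l2,
        )


@dataclass
class UMINTParameters:
    """Learned weights/biases. Per modality i: W1[i] (d_i x n_i), b1[i] (n_i),
    W2[i] (n_i x k), W3[i] (k x n_i), b3[i] (n_i), W4[i] (n_i x d_i),
    b4[i] (d_i); one shared bottleneck bias b2 (k)."""

    W1: list[np.ndarray]
    b1: list[np.ndarray]
    W2: list[np.ndarray]
    b2: np.ndarray
    W3: list[np.ndarray]
    b3: list[np.ndarray]
    W4: list[np.ndarray]
    b4: list[np.ndarray]

    @property
    def m(self) -> int:
        return len(self.W1)

    @property
    def dims(self) -> list[int]:
        return [w.shape[0] for w in self.W1]

    @property
    def hidden_widths(self) -> list[int]:
        return [w.shape[1] for w in self.W1]

    @property
    def bottleneck_width(self) -> int:
        return self.b2.shape[0]

    def arrays(self) -> list[np.ndarray]:
        """All parameter arrays in a fixed flat order (for the optimizer)."""
        out: list[np.ndarray] = []
        for i in range(self.m):
            out += [self.W1[i], self.b1[i], self.W2[i]]
        out.append(self.b2)
        for i in range(self.m):
            out += [self.W3[i], self.b3[i], self.W4[i], self.b4[i]]
        return out

    def encoder_weight_entries(self) -> int:
        """Input->modality-encoding weight entries (the TP_UMINT quantity)."""
        return int(sum(w.size for w in self.W1))

    def decoder_weight_entries(self) -> int:
        return int(sum(w.size for w in self.W4))

    def total_weight_entries(self, include_biases: bool = False) -> int:
        ws = self.W1 + self.W2 + self.W3 + self.W4
        total = sum(w.size for w in ws)
        if include_biases:
            total += sum(b.size for b in self.b1 + self.b3 + self.b4) + self.b2.size
        return int(total)


@dataclass
class LayerActivations:
    """Post-ReLU activations from one encode/decode pass (all entries >= 0)."""

    h2: list[np.ndarray]
    h3: np.ndarray
    h4: list[np.ndarray] | None = None


@dataclass
class Embedding:
    """The n x k bottleneck activations used for all downstream clustering."""

    values: np.ndarray
    cell_ids: list[str]

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass
class LossBreakdown:
    reconstruction_terms: list[float]
    activity_penalty: float
    weight_penalty: float

    @property
    def total(self) -> float:
        return float(sum(self.reconstruction_terms)
                     + self.activity_penalty + self.weight_penalty)


@dataclass
class ParameterCount:
    """First-layer trainable-parameter accounting, modular vs dense."""

    tp_umint: int
    tp_ae: int
    tp_reduction: int

    @property
    def tp_total_reduction(self) -> int:
        return 2 * self.tp_reduction


# ---------------------------------------------------------------------------
# Parameter accounting (closed form)
# ---------------------------------------------------------------------------

def _check_dims(dims: Sequence[int], hidden: Sequence[int]) -> None:
    if len(dims) != len(hidden):
        raise ValidationError(f"{len(dims)} dims vs {len(hidden)} hidden widths")
    if any(d < 1 for d in dims) or any(n < 1 for n in hidden):
        raise ValidationError("dims and hidden widths must be positive integers")


def count_parameters_umint(
    dims: Sequence[int], hidden: Sequence[int], include_biases: bool = False
) -> int:
    """Weight entries between input and modality-encoding layers: sum d_i n_i."""
    _check_dims(dims, hidden)
    total = sum(d * n for d, n in zip(dims, hidden))
    if include_biases:
        total += sum(hidden)
    return int(total)


def count_parameters_dense(
    dims: Sequence[int], hidden: Sequence[int], include_biases: bool = False
) -> int:
    """First-layer weight entries of the dense comparator: (sum d_i)(sum n_i)."""
    _check_dims(dims, hidden)
    total = sum(dims) * sum(hidden)
    if include_biases:
        total += sum(hidden)
    return int(total)


def parameter_reduction(dims: Sequence[int], hidden: Sequence[int]) -> ParameterCount:
    """Saving of the modular first layer over the dense one, and its double
    (the same saving recurs at the reconstruction layer)."""
    _check_dims(dims, hidden)
    tot_n = sum(hidden)
    red = sum(d * (tot_n - n) for d, n in zip(dims, hidden))
    pc = ParameterCount(
        tp_umint=count_parameters_umint(dims, hidden),
        tp_ae=count_parameters_dense(dims, hidden),
        tp_reduction=int(red),
    )
    assert pc.tp_reduction == pc.tp_ae - pc.tp_umint
    return pc


# ---------------------------------------------------------------------------
# Model construction & forward pass
# ---------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def build_model(dims: Sequence[int], config: UMINTConfig) -> UMINTParameters:
    """Allocate and seed all weights (Glorot-uniform) and biases (zero)."""
    cfg = config.resolve(dims)
    rng = np.random.default_rng(cfg.seed)
    k = cfg.bottleneck_width
    W1, b1, W2, W3, b3, W4, b4 = [], [], [], [], [], [], []
    for d, n in zip(dims, cfg.hidden_widths):
        W1.append(_glorot(rng, d, n))
        b1.append(np.zeros(n))
        W2.append(_glorot(rng, n, k))
    b2 = np.zeros(k)
    for d, n in zip(dims, cfg.hidden_widths):
        W3.append(_glorot(rng, k, n))
        b3.append(np.zeros(n))
        W4.append(_glorot(rng, n, d))
        b4.append(np.zeros(d))
    return UMINTParameters(W1, b1, W2, b2, W3, b3, W4, b4)


def _as_matrices(data: PairedDataset | Sequence[np.ndarray]) -> list[np.ndarray]:
    if isinstance(data, PairedDataset):
        return data.matrices()
    return [np.asarray(x, dtype=np.float64) for x in data]


def _check_modality_dims(params: UMINTParameters, mats: list[np.ndarray]) -> None:
    if len(mats) != params.m:
        raise ValidationError(f"model has {params.m} modalities, data has {len(mats)}")
    for i, (x, d) in enumerate(zip(mats, params.dims)):
        if x.shape[1] != d:
            raise ValidationError(
                f"modality {i}: data has {x.shape[1]} features, model expects {d}"
            )


def encode(
    params: UMINTParameters, data: PairedDataset | Sequence[np.ndarray]
) -> tuple[Embedding, LayerActivations]:
    """Forward pass through the encoder.

    h2_i = ReLU(x_i W1_i + b1_i);  h3 = ReLU(sum_i h2_i W2_i + b2).
    """
    mats = _as_matrices(data)
    _check_modality_dims(params, mats)
    h2 = [np.maximum(x @ W + b, 0.0)
          for x, W, b in zip(mats, params.W1, params.b1)]
    a3 = sum(h @ W for h, W in zip(h2, params.W2)) + params.b2
    h3 = np.maximum(a3, 0.0)
    cell_ids = (data.cell_ids if isinstance(data, PairedDataset)
                else [str(i) for i in range(h3.shape[0])])
    return Embedding(h3, list(cell_ids)), LayerActivations(h2=h2, h3=h3)


def decode(
    params: UMINTParameters, embedding: Embedding | np.ndarray
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Decoder pass: returns (reconstructions, h4 activations).

    h4_i = ReLU(h3 W3_i + b3_i);  xhat_i = h4_i W4_i + b4_i (linear head).
    """
    h3 = embedding.values if isinstance(embedding, Embedding) else np.asarray(embedding)
    if h3.shape[1] != params.bottleneck_width:
        raise ValidationError(
            f"embedding width {h3.shape[1]} != bottleneck {params.bottleneck_width}"
        )
    h4 = [np.maximum(h3 @ W + b, 0.0)
          for W, b in zip(params.W3, params.b3)]
    recons = [h @ W + b for h, W, b in zip(h4, params.W4, params.b4)]
    return recons, h4


def compute_loss(
    params: UMINTParameters,
    data: PairedDataset | Sequence[np.ndarray],
    acts: LayerActivations,
    recons: Sequence[np.ndarray],
    config: UMINTConfig,
) -> LossBreakdown:
    """Evaluate the objective on a given forward pass.

    The activity penalty is the mean over cells of the per-cell L1 norm of
    every hidden activation (h2_i, h3, h4_i), times alpha — mean rather than
    sum over the batch so the coefficient keeps its meaning across batch
    sizes. The weight penalty covers W2, W3, W4 (and W1 only when
    ``include_input_l2`` is set).
    """
    mats = _as_matrices(data)
    cfg = config.resolve([x.shape[1] for x in mats])
    n = mats[0].shape[0]
    rec = [
        float(lam * np.sum((x - r) ** 2) / n)
        for lam, x, r in zip(cfg.lambdas, mats, recons)
    ]
    if acts.h4 is None:
        raise ValidationError("LayerActivations.h4 required for the loss")
    l1 = sum(float(np.abs(h).sum()) for h in acts.h2)
    l1 += float(np.abs(acts.h3).sum())
    l1 += sum(float(np.abs(h).sum()) for h in acts.h4)
    activity = cfg.alpha * l1 / n
    ws = list(params.W2) + list(params.W3) + list(params.W4)
    if cfg.include_input_l2:
        ws += list(params.W1)
    weight = cfg.beta * sum(float(np.sum(w ** 2)) for w in ws)
    return LossBreakdown(rec, activity, weight)


# ---------------------------------------------------------------------------
# Gradients and training
# ---------------------------------------------------------------------------

def loss_and_gradients(
    params: UMINTParameters,
    mats: list[np.ndarray],
    cfg: UMINTConfig,
) -> tuple[LossBreakdown, UMINTParameters]:
    """Full forward + hand-derived backward pass.

    Returns the loss breakdown and a parameter-shaped gradient container.
    ReLU subgradient at 0 is taken as 0; since the L1 activity term acts on
    post-ReLU values (all >= 0), its subgradient is alpha/n on active units.
    """
    return _denoising_loss_and_gradients(params, mats, mats, cfg)


class _Adam:
    """Plain Adam over a flat list of ndarrays, updated in place."""

    def __init__(self, arrays: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.arrays = arrays
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(a) for a in arrays]
        self.v = [np.zeros_like(a) for a in arrays]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for a, g, m, v in zip(self.arrays, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            a -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class DivergenceError(RuntimeError):
    def __init__(self, epoch: int, last_finite: float):
        super().__init__(
            f"non-finite loss at epoch {epoch}; last finite epoch loss {last_finite:.6g}"
        )
        self.epoch = epoch
        self.last_finite = last_finite


def train(
    data: PairedDataset | Sequence[np.ndarray],
    config: UMINTConfig,
    params: UMINTParameters | None = None,
    input_noise_sd: Sequence[np.ndarray | float] | None = None,
    callback=None,
) -> tuple[UMINTParameters, list[LossBreakdown]]:
    """Mini-batch Adam on the UMINT objective for ``config.epochs`` epochs.

    Shuffling is reseeded deterministically from ``config.seed`` each epoch.
    ``input_noise_sd`` (per modality, scalar or per-feature) corrupts the
    *inputs* with additive Gaussian noise while the loss is still computed
    against the clean targets — this is what the denoising baseline uses.
    Returns the trained parameters and one mean-over-batches loss breakdown
    per epoch.
    """
    mats = _as_matrices(data)
    dims = [x.shape[1] for x in mats]
    cfg = config.resolve(dims)
    if params is None:
        params = build_model(dims, cfg)
    _check_modality_dims(params, mats)
    n = mats[0].shape[0]
    arrays = params.arrays()
    opt = _Adam(arrays, cfg.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed) % (2**31), 0x7EA1]))
    noise_rng = np.random.default_rng(
        np.random.SeedSequence([int(cfg.seed) % (2**31), 0x4015E]))

    history: list[LossBreakdown] = []
    last_finite = np.nan
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        ep_rec = np.zeros(params.m)
        ep_act = ep_wt = 0.0
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            batch = [x[idx] for x in mats]
            if input_noise_sd is not None:
                noisy = []
                for x, sd in zip(batch, input_noise_sd):
                    sd_arr = np.asarray(sd, dtype=np.float64)
                    if np.all(sd_arr == 0):
                        noisy.append(x)
                    else:
                        noisy.append(x + noise_rng.normal(size=x.shape) * sd_arr)
                loss, grads = _denoising_loss_and_gradients(params, noisy, batch, cfg)
            else:
                loss, grads = loss_and_gradients(params, batch, cfg)
            total = loss.total
            if not np.isfinite(total):
                raise DivergenceError(epoch, last_finite)
            last_finite = total
            opt.step(grads.arrays())
            ep_rec += np.asarray(loss.reconstruction_terms)
            ep_act += loss.activity_penalty
            ep_wt += loss.weight_penalty
            n_batches += 1
        epoch_loss = LossBreakdown(
            list(ep_rec / n_batches), ep_act / n_batches, ep_wt / n_batches
        )
        history.append(epoch_loss)
        if callback is not None:
            callback(epoch, epoch_loss)
    return params, history


def _denoising_loss_and_gradients(params, noisy, clean, cfg):
    """Backward pass with corrupted inputs and clean reconstruction targets."""
    n = clean[0].shape[0]
    a2 = [x @ W + b for x, W, b in zip(noisy, params.W1, params.b1)]
    h2 = [np.maximum(a, 0.0) for a in a2]
    a3 = sum(h @ W for h, W in zip(h2, params.W2)) + params.b2
    h3 = np.maximum(a3, 0.0)
    a4 = [h3 @ W + b for W, b in zip(params.W3, params.b3)]
    h4 = [np.maximum(a, 0.0) for a in a4]
    recons = [h @ W + b for h, W, b in zip(h4, params.W4, params.b4)]
    loss = compute_loss(params, clean, LayerActivations(h2, h3, h4), recons, cfg)

    alpha_n = cfg.alpha / n
    beta2 = 2.0 * cfg.beta
    gW1 = [None] * params.m
    gb1 = [None] * params.m
    gW2 = [None] * params.m
    gW3 = [None] * params.m
    gb3 = [None] * params.m
    gW4 = [None] * params.m
    gb4 = [None] * params.m
    dH3 = np.full_like(h3, alpha_n)
    for i in range(params.m):
        dR = (2.0 * cfg.lambdas[i] / n) * (recons[i] - clean[i])
        gW4[i] = h4[i].T @ dR + beta2 * params.W4[i]
        gb4[i] = dR.sum(axis=0)
        dA4 = (dR @ params.W4[i].T + alpha_n) * (a4[i] > 0)
        gW3[i] = h3.T @ dA4 + beta2 * params.W3[i]
        gb3[i] = dA4.sum(axis=0)
        dH3 += dA4 @ params.W3[i].T
    dA3 = dH3 * (a3 > 0)
    gb2 = dA3.sum(axis=0)
    for i in range(params.m):
        gW2[i] = h2[i].T @ dA3 + beta2 * params.W2[i]
        dA2 = (dA3 @ params.W2[i].T + alpha_n) * (a2[i] > 0)
        gW1[i] = noisy[i].T @ dA2
        if cfg.include_input_l2:
            gW1[i] = gW1[i] + beta2 * params.W1[i]
        gb1[i] = dA2.sum(axis=0)
    return loss, UMINTParameters(gW1, gb1, gW2, gb2, gW3, gb3, gW4, gb4)


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_model(params: UMINTParameters, config: UMINTConfig, path: str | Path) -> None:
    """Save all W/b arrays plus a JSON config block into one .npz archive."""
    path = Path(path)
    arrays: dict[str, np.ndarray] = {"b2": params.b2}
    for i in range(params.m):
        for name, group in (("W1", params.W1), ("b1", params.b1), ("W2", params.W2),
                            ("W3", params.W3), ("b3", params.b3),
                            ("W4", params.W4), ("b4", params.b4)):
            arrays[f"{name}_{i}"] = group[i]
    cfg = config.resolve(params.dims)
    meta = {
        "format_version": FORMAT_VERSION,
        "m": params.m,
        "dims": params.dims,
        "hidden_widths": cfg.hidden_widths,
        "bottleneck_width": cfg.bottleneck_width,
        "lambdas": cfg.lambdas,
        "alpha": cfg.alpha, "beta": cfg.beta,
        "epochs": cfg.epochs, "batch_size": cfg.batch_size,
        "learning_rate": cfg.learning_rate, "seed": cfg.seed,
        "include_input_l2": cfg.include_input_l2,
    }
    np.savez(path, **arrays)
    # np.savez writes a zip; append the config block as a member
    with zipfile.ZipFile(path, "a") as zf:
        zf.writestr("config.json", json.dumps(meta, indent=2))


def load_model(path: str | Path) -> tuple[UMINTParameters, UMINTConfig]:
    path = Path(path)
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("config.json"))
    with np.load(path) as npz:
        m = meta["m"]
        params = UMINTParameters(
            W1=[npz[f"W1_{i}"] for i in range(m)],
            b1=[npz[f"b1_{i}"] for i in range(m)],
            W2=[npz[f"W2_{i}"] for i in range(m)],
            b2=npz["b2"],
            W3=[npz[f"W3_{i}"] for i in range(m)],
            b3=[npz[f"b3_{i}"] for i in range(m)],
            W4=[npz[f"W4_{i}"] for i in range(m)],
            b4=[npz[f"b4_{i}"] for i in range(m)],
        )
    cfg = UMINTConfig(
        hidden_widths=meta["hidden_widths"],
        bottleneck_width=meta["bottleneck_width"],
        lambdas=meta["lambdas"], alpha=meta["alpha"], beta=meta["beta"],
        epochs=meta["epochs"], batch_size=meta["batch_size"],
        learning_rate=meta["learning_rate"], seed=meta["seed"],
        include_input_l2=meta["include_input_l2"],
    )
    return params, cfg


def write_embedding_csv(embedding: Embedding, path: str | Path,
                        prefix: str = "UMINT") -> None:
    cols = [f"{prefix}_{j + 1}" for j in range(embedding.k)]
    df = pd.DataFrame(embedding.values, columns=cols)
    df.insert(0, "cell_id", embedding.cell_ids)
    df.to_csv(path, index=False)


def read_embedding_csv(path: str | Path) -> Embedding:
    df = pd.read_csv(path)
    return Embedding(
        df.iloc[:, 1:].to_numpy(dtype=np.float64),
        [str(c) for c in df.iloc[:, 0]],
    )
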