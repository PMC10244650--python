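"""Stacked-input autoencoder baselines: AE, denoising AE, sparse AE.

Each baseline sees the horizontally stacked modalities as one wide input and
uses a dense first layer — exactly the comparator whose first-layer weight
count is (sum d_i)(sum n_i), versus UMINT's sum d_i n_i. A dense autoencoder
is the single-modality degeneration of the modular network, so the baselines
are built and trained through the same code path (m=1), which enforces
"identical hyperparameters" by construction:

* AE  — plain per-feature mean-squared reconstruction error + L2 weights.
* DAE — additive Gaussian input corruption during training (sd =
  ``noise_level`` x per-feature sd), loss against clean targets.
* SAE — adds an L1 penalty on hidden activations with its own coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    Embedding,
    LossBreakdown,
    UMINTConfig,
    UMINTParameters,
    build_model,
    encode,
    train,
)
from .io_preprocess import OmicsMatrix, PairedDataset, ValidationError

__all__ = ["BaselineConfig", "stack_modalities", "build_baseline", "train_baseline"]

VARIANTS = ("AE", "DAE", "SAE")


@dataclass
class BaselineConfig:
    """Dense autoencoder matched to a UMINT run.

    ``hidden_width`` is the total first-layer width (defaults to the matched
    UMINT's sum of per-modality widths when built via
    :func:`matched_baseline_config`). ``noise_level`` only applies to DAE,
    ``sparsity_alpha`` only to SAE.
    """

    variant: str = "AE"
    hidden_width: int = 64
    bottleneck_width: int = 64
    noise_level: float = 0.0
    sparsity_alpha: float = 0.0001
    beta: float = 0.001
    epochs: int = 25
    batch_size: int = 16
    learning_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValidationError(f"variant must be one of {VARIANTS}")
        if self.noise_level < 0 or self.sparsity_alpha < 0:
            raise ValidationError("noise_level and sparsity_alpha must be >= 0")

    def to_core_config(self, d_total: int) -> UMINTConfig:
        """The m=1 modular config this baseline trains under.

        lambda = 1/d_total (per-feature MSE); alpha = 0 except for SAE.
        """
        alpha = self.sparsity_alpha if self.variant == "SAE" else 0.0
        return UMINTConfig(
            hidden_widths=[self.hidden_width],
            bottleneck_width=self.bottleneck_width,
            lambdas=[1.0 / d_total],
            alpha=alpha,
            beta=self.beta,
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            seed=self.seed,
        )


def matched_baseline_config(
    variant: str, dims: list[int], core_cfg: UMINTConfig, **overrides
) -> BaselineConfig:
    """Baseline sharing every training knob with a resolved UMINT config,
    with hidden_width = sum of the UMINT per-modality widths."""
    cfg = core_cfg.resolve(dims)
    kw = dict(
        variant=variant,
        hidden_width=sum(cfg.hidden_widths),
        bottleneck_width=cfg.bottleneck_width,
        beta=cfg.beta,
        sparsity_alpha=cfg.alpha,
        epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        learning_rate=cfg.learning_rate,
        seed=cfg.seed,
    )
    kw.update(overrides)
    return BaselineConfig(**kw)


def stack_modalities(data: PairedDataset) -> OmicsMatrix:
    """Concatenate modalities horizontally; feature ids get a modality prefix."""
    mats = data.matrices()
    feature_ids = [
        f"{m.modality_tag}:{f}" for m in data.modalities for f in m.feature_ids
    ]
    return OmicsMatrix(
        np.hstack(mats),
        list(data.cell_ids),
        feature_ids,
        modality_tag="stacked",
        is_count=False,
    )


def build_baseline(d_total: int, config: BaselineConfig) -> UMINTParameters:
    """Dense encoder d_total -> hidden_width -> k with mirrored decoder."""
    if config.bottleneck_width >= d_total:
        raise ValidationError(
            f"bottleneck {config.bottleneck_width} must be < input width {d_total}"
        )
    return build_model([d_total], config.to_core_config(d_total))


def train_baseline(
    data: OmicsMatrix | np.ndarray, config: BaselineConfig
) -> tuple[UMINTParameters, list[LossBreakdown]]:
    """Train one baseline on a stacked matrix with the shared trainer."""
    x = data.dense() if isinstance(data, OmicsMatrix) else np.asarray(data, float)
    cfg = config.to_core_config(x.shape[1])
    noise = None
    if config.variant == "DAE" and config.noise_level > 0:
        noise = [config.noise_level * x.std(axis=0)]
    return train([x], cfg, input_noise_sd=noise)


def embed_baseline(
    params: UMINTParameters, data: OmicsMatrix | np.ndarray,
    cell_ids: list[str] | None = None,
) -> Embedding:
    x = data.dense() if isinstance(data, OmicsMatrix) else np.asarray(data, float)
    emb, _ = encode(params, [x])
    if cell_ids is None and isinstance(data, OmicsMatrix):
        cell_ids = list(data.cell_ids)
    if cell_ids is not None:
        emb = Embedding(emb.values, list(cell_ids))
    return emb
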