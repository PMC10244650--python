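"""End-to-end workflows: preprocess -> train -> embed -> cluster -> report.

These functions are the substance behind the command-line interface; they
accept in-memory objects so tests and notebooks can drive them directly.
Every workflow writes a run manifest (resolved parameters, input digests,
package version, timestamps, output paths) so a run can be reproduced from
its output directory alone.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .baselines import (
    embed_baseline,
    matched_baseline_config,
    stack_modalities,
    train_baseline,
)
from .core import (
    Embedding,
    UMINTConfig,
    build_model,
    decode,
    encode,
    parameter_reduction,
    save_model,
    train,
    write_embedding_csv,
)
from .evaluation import ari, cluster_embedding, fmi, internal_indices, ors
from .io_preprocess import (
    OmicsMatrix,
    PairedDataset,
    ValidationError,
    align_cells,
    preprocess_modality,
)

__all__ = ["write_manifest", "preprocess_dataset", "run_train", "run_evaluate",
           "compare_methods", "train_test_split_cells", "synthetic_benchmark"]


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir: Path, config: dict, inputs: list[Path],
                   outputs: list[Path]) -> Path:
    manifest = {
        "software": {"name": "umint", "version": __version__},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        "config": config,
        "inputs": {str(p): _digest(Path(p)) for p in inputs if Path(p).exists()},
        "outputs": [str(p) for p in outputs],
    }
    path = Path(out_dir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path


def preprocess_dataset(
    modalities: list[OmicsMatrix],
    recipes: list[str],
    labels=None,
    batches=None,
    n_top: int | None = 2000,
) -> tuple[PairedDataset, list[dict]]:
    """Align cells across modalities, then apply one named recipe per modality."""
    if len(recipes) != len(modalities):
        raise ValidationError("one recipe per modality required")
    data = align_cells(modalities, labels=labels, batches=batches)
    processed, reports = [], []
    for mod, recipe in zip(data.modalities, recipes):
        y, rep = preprocess_modality(mod, recipe, n_top=n_top)
        processed.append(y)
        reports.append(rep)
    out = PairedDataset(processed, labels=data.labels, batches=data.batches,
                        dropped_per_modality=data.dropped_per_modality)
    return out, reports


def run_train(
    data: PairedDataset,
    config: UMINTConfig,
    out_dir: str | Path | None = None,
    input_paths: list[Path] | None = None,
) -> dict:
    """Train UMINT on a preprocessed dataset; optionally persist artifacts.

    Returns a dict with the trained ``params``, ``embedding``, ``history``
    and (when ``out_dir`` is given) the written paths.
    """
    params, history = train(data, config)
    embedding, _ = encode(params, data)
    result = {"params": params, "embedding": embedding, "history": history,
              "config": config.resolve(data.dims)}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        model_path = out / "model.npz"
        emb_path = out / "embedding.csv"
        loss_path = out / "loss_trace.csv"
        save_model(params, config, model_path)
        write_embedding_csv(embedding, emb_path)
        rows = []
        for e, lb in enumerate(history):
            row = {"epoch": e + 1, "total": lb.total,
                   "activity_penalty": lb.activity_penalty,
                   "weight_penalty": lb.weight_penalty}
            for i, r in enumerate(lb.reconstruction_terms):
                row[f"reconstruction_{i + 1}"] = r
            rows.append(row)
        pd.DataFrame(rows).to_csv(loss_path, index=False)
        cfg = config.resolve(data.dims)
        write_manifest(out, asdict(cfg), input_paths or [],
                       [model_path, emb_path, loss_path])
        result["paths"] = {"model": model_path, "embedding": emb_path,
                           "loss_trace": loss_path}
    return result


def run_evaluate(
    embedding: Embedding,
    labels=None,
    k: int | None = None,
    methods: tuple[str, ...] = ("kmeans", "hierarchical"),
    seed: int = 0,
    out_path: str | Path | None = None,
) -> dict:
    """Cluster an embedding and score it.

    With labels given, k defaults to the number of distinct labels and the
    external indices (ARI, FMI) are reported; internal indices (silhouette,
    Davies-Bouldin) are reported whenever the clustering has >= 2 clusters.
    """
    if labels is None and k is None:
        raise ValidationError("need ground-truth labels or an explicit k")
    if labels is not None and len(labels) != embedding.values.shape[0]:
        raise ValidationError("labels length does not match embedding")
    k_use = k if k is not None else len(set(labels))
    report: dict = {"k": k_use, "seed": seed, "methods": {}}
    for method in methods:
        pred = cluster_embedding(embedding, k_use, method=method, seed=seed)
        entry: dict = {}
        if labels is not None:
            entry["ari"] = ari(labels, pred)
            entry["fmi"] = fmi(labels, pred)
        if len(np.unique(pred)) >= 2:
            sil, db = internal_indices(embedding, pred)
            entry["silhouette"] = sil
            entry["davies_bouldin"] = db
        else:
            entry["internal_indices_error"] = "single cluster; indices undefined"
        report["methods"][method] = entry
    if out_path is not None:
        Path(out_path).write_text(json.dumps(report, indent=2) + "\n")
    return report


def train_test_split_cells(n: int, test_fraction: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Seeded cell-index split (train, test), test_fraction of cells held out."""
    rng = np.random.default_rng(int(seed) % (2**31))
    order = rng.permutation(n)
    n_test = int(round(n * test_fraction))
    return np.sort(order[n_test:]), np.sort(order[:n_test])


def compare_methods(
    data: PairedDataset,
    config: UMINTConfig,
    n_seeds: int = 3,
    base_seed: int = 0,
    test_fraction: float = 0.2,
    noise_level: float = 0.5,
    max_cells_rho: int = 1000,
    out_dir: str | Path | None = None,
) -> dict:
    """Matched comparison of UMINT against dense AE / DAE / SAE baselines.

    For each seed the cells are split 80:20; all four models train on the
    same training cells with identical shared hyperparameters, ORS is scored
    on the held-out cells, and clustering metrics (k-means and hierarchical,
    k = number of ground-truth label values) are scored on all cells.
    Parameter counts and per-epoch wall-clock are recorded per method.
    Returns per-seed rows plus per-method medians.
    """
    if data.labels is None:
        raise ValidationError("compare_methods needs ground-truth labels")
    dims = data.dims
    cfg0 = config.resolve(dims)
    k_clusters = len(set(data.labels))
    pc = parameter_reduction(dims, cfg0.hidden_widths)

    rows: list[dict] = []
    for s in range(n_seeds):
        seed = base_seed + s
        tr_idx, te_idx = train_test_split_cells(data.n_cells, test_fraction, seed)
        train_ds = data.subset_cells(tr_idx)
        test_ds = data.subset_cells(te_idx)

        def _score(name, embedding_all, recons_test, elapsed, n_epochs,
                   first_layer_weights):
            row = {"method": name, "seed": seed,
                   "first_layer_weights": first_layer_weights,
                   "seconds_per_epoch": elapsed / max(n_epochs, 1)}
            score = ors(test_ds, recons_test, max_cells=max_cells_rho, seed=seed)
            row["ors"] = score.ors
            for i, r in enumerate(score.rho):
                row[f"rho_{i + 1}"] = r
            for method in ("kmeans", "hierarchical"):
                pred = cluster_embedding(embedding_all, k_clusters,
                                         method=method, seed=seed)
                row[f"ari_{method}"] = ari(data.labels, pred)
                row[f"fmi_{method}"] = fmi(data.labels, pred)
            rows.append(row)

        cfg = UMINTConfig(**{**asdict(cfg0), "seed": seed})
        t0 = time.perf_counter()
        params, history = train(train_ds, cfg)
        elapsed = time.perf_counter() - t0
        emb_all, _ = encode(params, data)
        emb_test, _ = encode(params, test_ds)
        recons_test, _ = decode(params, emb_test)
        _score("UMINT", emb_all, recons_test, elapsed, cfg.epochs,
               params.encoder_weight_entries())

        stacked_all = stack_modalities(data)
        stacked_train = stacked_all.dense()[tr_idx]
        stacked_test = stacked_all.dense()[te_idx]
        d_splits = np.cumsum(dims)[:-1]
        for variant in ("AE", "DAE", "SAE"):
            bcfg = matched_baseline_config(
                variant, dims, cfg,
                noise_level=noise_level if variant == "DAE" else 0.0,
            )
            t0 = time.perf_counter()
            bparams, _ = train_baseline(stacked_train, bcfg)
            elapsed = time.perf_counter() - t0
            bemb_all = embed_baseline(bparams, stacked_all.dense(),
                                      cell_ids=data.cell_ids)
            bemb_test = embed_baseline(bparams, stacked_test)
            brecon_stacked, _ = decode(bparams, bemb_test)
            brecons = np.split(brecon_stacked[0], d_splits, axis=1)
            _score(variant, bemb_all, brecons, elapsed, bcfg.epochs,
                   bparams.encoder_weight_entries())

    df = pd.DataFrame(rows)
    numeric = [c for c in df.columns if c not in ("method", "seed")]
    medians = df.groupby("method")[numeric].median().reset_index()
    summary = {
        "n_seeds": n_seeds,
        "k_clusters": k_clusters,
        "parameter_counts": {
            "tp_umint": pc.tp_umint,
            "tp_ae": pc.tp_ae,
            "tp_reduction": pc.tp_reduction,
            "tp_total_reduction": pc.tp_total_reduction,
        },
        "per_seed": rows,
        "median": medians.to_dict(orient="records"),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "per_seed.csv", index=False)
        medians.to_csv(out / "median.csv", index=False)
        (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
        write_manifest(out, {"n_seeds": n_seeds, "base_seed": base_seed,
                             "test_fraction": test_fraction,
                             "config": asdict(cfg0)}, [],
                       [out / "per_seed.csv", out / "median.csv",
                        out / "summary.json"])
    return summary


def synthetic_benchmark(
    seed: int,
    sim_config=None,
    model_config: UMINTConfig | None = None,
    include_untrained: bool = True,
) -> dict:
    """One full run of the reference synthetic study.

    Simulates a CITE-seq-like dataset (2,000 cells, 5 cell types, a 500-feature
    count modality with 50% dropout paired with a 20-feature panel), applies
    the rna/adt preprocessing recipes, trains the model with the standard
    recipe (bottleneck 64, 25 epochs, batch 16, Adam, alpha=1e-4, beta=1e-3),
    and scores k-means cluster recovery (k = 5) plus reconstruction fidelity.
    The untrained (freshly initialized) model's ORS serves as the null
    reference for how much geometry training actually recovers.
    """
    from .synthetic import SimulationConfig, simulate  # local: avoid cycle

    sim_config = sim_config or SimulationConfig(seed=seed)
    ds = simulate(sim_config)
    labels = dict(zip(ds.data.cell_ids, ds.true_labels))
    data, _ = preprocess_dataset(
        ds.data.modalities, ["rna", "adt"], labels=labels, n_top=None)
    cfg = model_config or UMINTConfig(seed=seed)
    cfg = UMINTConfig(**{**asdict(cfg.resolve(data.dims)), "seed": seed})
    params, history = train(data, cfg)
    emb, _ = encode(params, data)
    k = len(set(ds.true_labels))
    pred = cluster_embedding(emb, k, method="kmeans", seed=seed)
    recons, _ = decode(params, emb)
    out = {
        "seed": seed,
        "n_cells": data.n_cells,
        "ari_kmeans": ari(data.labels, pred),
        "fmi_kmeans": fmi(data.labels, pred),
        "ors_trained": ors(data, recons, seed=seed).ors,
        "loss_first_epoch": history[0].total,
        "loss_final_epoch": history[-1].total,
    }
    if include_untrained:
        p0 = build_model(data.dims, cfg)
        r0, _ = decode(p0, encode(p0, data)[0])
        out["ors_untrained"] = ors(data, r0, seed=seed).ors
    return out
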