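"""Reading, aligning and preprocessing paired single-cell omics matrices.

The containers here are deliberately minimal: an :class:`OmicsMatrix` is one
modality's cells x features matrix with its barcode and feature names, and a
:class:`PairedDataset` is an ordered collection of modalities sharing one
canonical cell order, plus optional cell-type and batch labels.

Preprocessing follows the standard single-cell recipes: library-size
normalization to a fixed target followed by log1p for RNA counts, the centered
log-ratio (CLR) transform for antibody-derived-tag (ADT) panels, variance-based
selection of highly variable features, and per-feature z-scoring with clipping.
All internal matrices are cells x features; file orientation is resolved at the
reader boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = [
    "OmicsMatrix",
    "PairedDataset",
    "read_matrix",
    "read_labels",
    "align_cells",
    "normalize_rna",
    "clr_transform",
    "select_hvg",
    "scale_features",
    "write_matrix",
    "preprocess_modality",
]


class FormatError(ValueError):
    """Malformed on-disk matrix (bad header, unreadable triplets)."""


class ValidationError(ValueError):
    """Structurally readable input violating a contract (duplicates, shape)."""


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    seen: set[str] = set()
    dups = []
    for i in ids:
        if i in seen:
            dups.append(i)
        seen.add(i)
    if dups:
        raise ValidationError(f"duplicate {what}: {sorted(set(dups))[:10]}")
    return ids


@dataclass
class OmicsMatrix:
    """One modality's cells x features matrix.

    Parameters
    ----------
    values
        Dense ndarray or scipy sparse matrix, cells in rows.
    cell_ids, feature_ids
        Unique ordered identifiers for rows and columns.
    modality_tag
        Free-form label such as ``"RNA"``, ``"ADT"`` or ``"ATAC"``.
    is_count
        True while the matrix still holds raw (non-negative) counts.
    """

    values: np.ndarray | sp.spmatrix
    cell_ids: list[str]
    feature_ids: list[str]
    modality_tag: str = "X"
    is_count: bool = True

    def __post_init__(self) -> None:
        self.cell_ids = _check_unique(self.cell_ids, "cell ids")
        self.feature_ids = _check_unique(self.feature_ids, "feature ids")
        n, d = self.values.shape
        if n != len(self.cell_ids):
            raise ValidationError(
                f"{self.modality_tag}: {n} rows but {len(self.cell_ids)} cell ids"
            )
        if d != len(self.feature_ids):
            raise ValidationError(
                f"{self.modality_tag}: {d} columns but {len(self.feature_ids)} feature ids"
            )
        if self.is_count and self.dense().size and self.dense().min() < 0:
            raise ValidationError(f"{self.modality_tag}: negative entries in count matrix")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        """Return values as a dense float64 ndarray (no copy if already dense)."""
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=np.float64)
        return np.asarray(self.values, dtype=np.float64)

    def subset_cells(self, index: Sequence[int]) -> "OmicsMatrix":
        idx = np.asarray(index, dtype=int)
        vals = self.values[idx] if not sp.issparse(self.values) else self.values.tocsr()[idx]
        return replace(
            self, values=vals, cell_ids=[self.cell_ids[i] for i in idx],
            feature_ids=list(self.feature_ids),
        )


@dataclass
class PairedDataset:
    """Modalities aligned to a single canonical cell order."""

    modalities: list[OmicsMatrix]
    labels: list[str] | None = None
    batches: list[str] | None = None
    dropped_per_modality: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.modalities:
            raise ValidationError("PairedDataset needs at least one modality")
        ref = self.modalities[0].cell_ids
        for m in self.modalities[1:]:
            if m.cell_ids != ref:
                raise ValidationError(
                    f"modality {m.modality_tag} cell ids differ from {self.modalities[0].modality_tag}"
                )
        n = len(ref)
        for name, vec in (("labels", self.labels), ("batches", self.batches)):
            if vec is not None and len(vec) != n:
                raise ValidationError(f"{name} has length {len(vec)}, expected {n}")

    @property
    def n_cells(self) -> int:
        return self.modalities[0].n_cells

    @property
    def cell_ids(self) -> list[str]:
        return self.modalities[0].cell_ids

    @property
    def dims(self) -> list[int]:
        return [m.n_features for m in self.modalities]

    def matrices(self) -> list[np.ndarray]:
        return [m.dense() for m in self.modalities]

    def subset_cells(self, index: Sequence[int]) -> "PairedDataset":
        idx = list(map(int, index))
        return PairedDataset(
            modalities=[m.subset_cells(idx) for m in self.modalities],
            labels=[self.labels[i] for i in idx] if self.labels is not None else None,
            batches=[self.batches[i] for i in idx] if self.batches is not None else None,
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _read_sidecar(path: Path) -> list[str]:
    # barcodes.tsv / features.tsv style: first column is the id
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                out.append(line.split("\t")[0])
    return out


def read_matrix(
    path: str | Path,
    fmt: str | None = None,
    orientation: str = "cells_by_features",
    modality_tag: str = "X",
    is_count: bool = True,
    barcodes: str | Path | None = None,
    features: str | Path | None = None,
) -> OmicsMatrix:
    """Read a matrix from MTX or delimited text into cells x features form.

    For ``mtx``, barcode/feature sidecars default to ``barcodes.tsv`` and
    ``features.tsv`` next to the matrix file.  For ``csv``/``tsv`` the first
    row is a header and the first column holds row ids.  ``orientation``
    declares the on-disk layout; the returned matrix is always
    cells x features.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = {".mtx": "mtx", ".csv": "csv", ".tsv": "tsv", ".txt": "tsv"}.get(
            path.suffix.lower(), "csv"
        )
    if orientation not in ("cells_by_features", "features_by_cells"):
        raise ValidationError(f"unknown orientation {orientation!r}")

    if fmt == "mtx":
        try:
            mat = mmread(path)
        except Exception as exc:  # noqa: BLE001 - surface as format error
            raise FormatError(f"cannot parse Matrix Market file {path}: {exc}") from exc
        mat = sp.csr_matrix(mat)
        bpath = Path(barcodes) if barcodes else path.with_name("barcodes.tsv")
        fpath = Path(features) if features else path.with_name("features.tsv")
        cells = _read_sidecar(bpath)
        feats = _read_sidecar(fpath)
        if orientation == "features_by_cells":
            mat = mat.T.tocsr()
        if mat.shape[0] != len(cells) or mat.shape[1] != len(feats):
            raise ValidationError(
                f"matrix shape {mat.shape} does not match sidecars "
                f"({len(cells)} barcodes, {len(feats)} features)"
            )
        return OmicsMatrix(mat, cells, feats, modality_tag, is_count)

    sep = "," if fmt == "csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot parse {fmt} file {path}: {exc}") from exc
    if orientation == "features_by_cells":
        df = df.T
    return OmicsMatrix(
        df.to_numpy(dtype=np.float64),
        [str(i) for i in df.index],
        [str(c) for c in df.columns],
        modality_tag,
        is_count,
    )


def write_matrix(x: OmicsMatrix, path: str | Path, fmt: str | None = None) -> None:
    """Write cells x features to CSV/TSV (ids in header/index) or MTX + sidecars."""
    path = Path(path)
    if fmt is None:
        fmt = {".mtx": "mtx", ".tsv": "tsv"}.get(path.suffix.lower(), "csv")
    if fmt == "mtx":
        mat = sp.coo_matrix(x.values)
        if x.is_count and np.allclose(mat.data, np.round(mat.data)):
            mat = mat.astype(np.int64)
        mmwrite(str(path), mat)
        path.with_name("barcodes.tsv").write_text("\n".join(x.cell_ids) + "\n")
        path.with_name("features.tsv").write_text("\n".join(x.feature_ids) + "\n")
    else:
        sep = "\t" if fmt == "tsv" else ","
        pd.DataFrame(x.dense(), index=x.cell_ids, columns=x.feature_ids).to_csv(
            path, sep=sep
        )


def read_labels(path: str | Path, cell_ids: Sequence[str] | None = None) -> list[str]:
    """Read per-cell labels: single-column (aligned to barcodes) or two-column
    ``barcode<TAB>value`` files.  With ``cell_ids`` given, two-column files are
    reordered to that canonical order."""
    path = Path(path)
    rows = [ln.rstrip("\n") for ln in path.read_text().splitlines() if ln.strip()]
    parts = [r.split("\t") for r in rows]
    if all(len(p) >= 2 for p in parts) and len(parts) > 0 and cell_ids is not None:
        mapping = {p[0]: p[1] for p in parts}
        missing = [c for c in cell_ids if c not in mapping]
        if missing:
            raise ValidationError(f"labels missing for cells: {missing[:5]}")
        return [mapping[c] for c in cell_ids]
    labels = [p[-1] if len(p) > 1 else p[0] for p in parts]
    if cell_ids is not None and len(labels) != len(cell_ids):
        raise ValidationError(
            f"label file has {len(labels)} rows, expected {len(cell_ids)}"
        )
    return labels


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def align_cells(
    modalities: list[OmicsMatrix],
    labels: dict[str, str] | Sequence[str] | None = None,
    batches: dict[str, str] | Sequence[str] | None = None,
) -> PairedDataset:
    """Restrict all modalities to their common cells, in sorted-barcode order.

    Sequence-typed labels/batches are taken as aligned to the *first*
    modality's original order; dict-typed ones are keyed by barcode.
    """
    if not modalities:
        raise ValidationError("need at least one modality")
    common = set(modalities[0].cell_ids)
    for m in modalities[1:]:
        common &= set(m.cell_ids)
    if not common:
        raise ValidationError("empty cell-id intersection across modalities")
    order = sorted(common)

    aligned = []
    dropped = []
    for m in modalities:
        pos = {c: i for i, c in enumerate(m.cell_ids)}
        aligned.append(m.subset_cells([pos[c] for c in order]))
        dropped.append(m.n_cells - len(order))

    def _resolve(vec, first: OmicsMatrix):
        if vec is None:
            return None
        if isinstance(vec, dict):
            return [vec[c] for c in order]
        pos = {c: i for i, c in enumerate(first.cell_ids)}
        return [vec[pos[c]] for c in order]

    return PairedDataset(
        modalities=aligned,
        labels=_resolve(labels, modalities[0]),
        batches=_resolve(batches, modalities[0]),
        dropped_per_modality=dropped,
    )


# ---------------------------------------------------------------------------
# Per-modality transforms
# ---------------------------------------------------------------------------

def normalize_rna(x: OmicsMatrix, target_sum: float = 10_000.0) -> OmicsMatrix:
    """Library-size normalize each cell to ``target_sum`` total, then log1p."""
    if target_sum <= 0:
        raise ValidationError("target_sum must be positive")
    vals = x.values
    if sp.issparse(vals):
        totals = np.asarray(vals.sum(axis=1)).ravel()
    else:
        totals = np.asarray(vals, dtype=np.float64).sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        bad = [x.cell_ids[i] for i in zero[:10]]
        raise ValidationError(f"cells with zero total count: {bad}")
    scale = target_sum / totals
    if sp.issparse(vals):
        out = sp.diags(scale) @ vals.tocsr()
        out.data = np.log1p(out.data)
    else:
        out = np.log1p(np.asarray(vals, dtype=np.float64) * scale[:, None])
    return replace(x, values=out, is_count=False)


def clr_transform(x: OmicsMatrix, pseudocount: float = 1.0) -> OmicsMatrix:
    """Centered log-ratio per cell: log(x+c) minus the cell's mean log(x+c).

    With ``pseudocount=0`` this is the classical CLR and every transformed
    cell sums to zero exactly.
    """
    if pseudocount < 0:
        raise ValidationError("pseudocount must be non-negative")
    vals = x.dense()
    if (vals + pseudocount <= 0).any():
        raise ValidationError(
            "log undefined: entries with value + pseudocount <= 0 "
            f"(pseudocount={pseudocount})"
        )
    logged = np.log(vals + pseudocount)
    out = logged - logged.mean(axis=1, keepdims=True)
    return replace(x, values=out, is_count=False)


def select_hvg(x: OmicsMatrix, n_top: int = 2000) -> OmicsMatrix:
    """Keep the ``n_top`` features with highest (population) variance.

    Features are returned in descending-variance order; ties keep original
    feature order (stable sort).
    """
    if n_top > x.n_features:
        raise ValidationError(f"n_top={n_top} exceeds {x.n_features} features")
    vals = x.dense()
    var = vals.var(axis=0)
    order = np.argsort(-var, kind="stable")[:n_top]
    return replace(
        x,
        values=vals[:, order],
        feature_ids=[x.feature_ids[i] for i in order],
    )


def scale_features(x: OmicsMatrix, clip: float = 10.0) -> OmicsMatrix:
    """Z-score each feature (population sd; constant features -> 0), clip to ±clip."""
    if clip <= 0:
        raise ValidationError("clip must be positive")
    vals = x.dense()
    mu = vals.mean(axis=0)
    sd = vals.std(axis=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    out = (vals - mu) / sd_safe
    out[:, sd == 0] = 0.0
    np.clip(out, -clip, clip, out=out)
    return replace(x, values=out, is_count=False)


_RECIPES = ("rna", "adt", "none")


def preprocess_modality(
    x: OmicsMatrix,
    recipe: str = "rna",
    target_sum: float = 10_000.0,
    n_top: int | None = 2000,
    clip: float = 10.0,
    pseudocount: float = 1.0,
) -> tuple[OmicsMatrix, dict]:
    """Apply a named per-modality recipe and return (matrix, report).

    ``rna``: normalize to target_sum, log1p, HVG (n_top, capped at d), scale.
    ``adt``: CLR.  ``none``: passthrough.
    """
    if recipe not in _RECIPES:
        raise ValidationError(f"unknown recipe {recipe!r}; choose from {_RECIPES}")
    report: dict = {"modality": x.modality_tag, "recipe": recipe,
                    "n_cells": x.n_cells, "n_features_in": x.n_features}
    if recipe == "rna":
        y = normalize_rna(x, target_sum)
        keep = min(n_top, x.n_features) if n_top else x.n_features
        y = select_hvg(y, keep)
        y = scale_features(y, clip)
        report.update(target_sum=target_sum, n_hvg=keep, clip=clip)
    elif recipe == "adt":
        y = clr_transform(x, pseudocount)
        report.update(pseudocount=pseudocount)
    else:
        y = x
    report["n_features_out"] = y.n_features
    return y, report


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
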