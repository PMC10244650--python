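"""Embedding evaluation: external/internal clustering indices and the
Overall Reconstruction Score (ORS).

The external indices — Adjusted Rand Index and Fowlkes–Mallows Index — are
computed from the contingency table between two labelings. Writing c_ij for
the number of cells in cluster i of partition A and cluster j of partition B,
with marginals p_i, q_j and total N:

    ARI = [sum C(c_ij,2) - sum C(p_i,2) sum C(q_j,2) / C(N,2)]
          / [0.5 (sum C(p_i,2) + sum C(q_j,2)) - sum C(p_i,2) sum C(q_j,2) / C(N,2)]

    FMI = TP / sqrt((TP+FP)(TP+FN)),  TP = sum C(c_ij,2),
          TP+FP = sum C(p_i,2),  TP+FN = sum C(q_j,2)

over unordered cell pairs. ORS is the mean over modalities of the Pearson
correlation between pairwise cell distances in the original matrix and in
its reconstruction — a scale-insensitive measure of how well the geometry
of each modality survives the autoencoding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.metrics import davies_bouldin_score, silhouette_score

from .core import Embedding
from .io_preprocess import OmicsMatrix, PairedDataset, ValidationError

__all__ = [
    "ContingencyTable",
    "PairCounts",
    "ReconstructionScore",
    "contingency",
    "ari",
    "fmi",
    "pair_counts",
    "cluster_embedding",
    "reconstruction_rho",
    "ors",
    "internal_indices",
]


@dataclass
class ContingencyTable:
    counts: np.ndarray        # clusters-of-A x clusters-of-B, ints
    row_labels: list
    col_labels: list

    @property
    def p(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def q(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass
class PairCounts:
    """Unordered-pair confusion counts between two partitions."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class ReconstructionScore:
    rho: list[float]

    @property
    def ors(self) -> float:
        return float(np.mean(self.rho))


def _as_labels(x: Sequence) -> np.ndarray:
    arr = np.asarray(list(x))
    if arr.ndim != 1:
        raise ValidationError("labels must be one-dimensional")
    return arr


def contingency(labels_a: Sequence, labels_b: Sequence) -> ContingencyTable:
    """Cross-tabulate two labelings of the same cells."""
    a = _as_labels(labels_a)
    b = _as_labels(labels_b)
    if len(a) != len(b):
        raise ValidationError(f"label lengths differ: {len(a)} vs {len(b)}")
    if len(a) < 2:
        raise ValidationError("need at least 2 cells")
    ra, ia = np.unique(a, return_inverse=True)
    rb, ib = np.unique(b, return_inverse=True)
    counts = np.zeros((len(ra), len(rb)), dtype=np.int64)
    np.add.at(counts, (ia, ib), 1)
    return ContingencyTable(counts, list(ra), list(rb))


def _comb2(x: np.ndarray) -> np.ndarray:
    x = x.astype(np.float64)
    return x * (x - 1.0) / 2.0


def pair_counts(labels_a: Sequence, labels_b: Sequence) -> PairCounts:
    """TP/FP/FN/TN over the N(N-1)/2 unordered cell pairs."""
    tab = contingency(labels_a, labels_b)
    tp = _comb2(tab.counts).sum()
    pa = _comb2(tab.p).sum()          # pairs together in A  (= TP + FP)
    pb = _comb2(tab.q).sum()          # pairs together in B  (= TP + FN)
    total = _comb2(np.asarray([tab.n])).sum()
    fp = pa - tp
    fn = pb - tp
    tn = total - tp - fp - fn
    return PairCounts(int(tp), int(fp), int(fn), int(tn))


def ari(labels_a: Sequence, labels_b: Sequence) -> float:
    """Adjusted Rand Index; 1 for identical partitions, ~0 at chance.

    When both partitions are trivial (all singletons or one cluster) the
    denominator vanishes; the conventional value is 1.0 iff the partitions
    are identical, else 0.0.
    """
    tab = contingency(labels_a, labels_b)
    sum_c = _comb2(tab.counts).sum()
    sum_p = _comb2(tab.p).sum()
    sum_q = _comb2(tab.q).sum()
    n2 = _comb2(np.asarray([tab.n]))[0]
    expected = sum_p * sum_q / n2
    maximum = 0.5 * (sum_p + sum_q)
    denom = maximum - expected
    if denom == 0:
        # first-appearance codes are invariant to cluster renaming
        def canon(labels):
            seen: dict = {}
            return [seen.setdefault(l, len(seen)) for l in labels]

        return 1.0 if canon(labels_a) == canon(labels_b) else 0.0
    return float((sum_c - expected) / denom)


def fmi(labels_a: Sequence, labels_b: Sequence) -> float:
    """Fowlkes–Mallows Index: TP / sqrt((TP+FP)(TP+FN)), in [0, 1]."""
    tab = contingency(labels_a, labels_b)
    tp = _comb2(tab.counts).sum()
    pa = _comb2(tab.p).sum()
    pb = _comb2(tab.q).sum()
    if pa == 0 or pb == 0:
        return 0.0
    return float(tp / np.sqrt(pa * pb))


def cluster_embedding(
    embedding: Embedding | np.ndarray,
    k: int,
    method: str = "kmeans",
    seed: int = 0,
    linkage: str = "ward",
) -> np.ndarray:
    """Cluster an embedding into k groups.

    ``kmeans`` uses k-means++ with 10 restarts (best inertia), seeded;
    ``hierarchical`` is agglomerative with Ward linkage on Euclidean
    distances, cut at k clusters (deterministic).
    """
    x = embedding.values if isinstance(embedding, Embedding) else np.asarray(embedding)
    n = x.shape[0]
    if k > n:
        raise ValidationError(f"k={k} exceeds number of cells {n}")
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k == 1:
        return np.zeros(n, dtype=int)
    if method == "kmeans":
        km = KMeans(n_clusters=k, init="k-means++", n_init=10,
                    random_state=int(seed) % (2**31))
        return km.fit_predict(x)
    if method == "hierarchical":
        hc = AgglomerativeClustering(n_clusters=k, linkage=linkage)
        return hc.fit_predict(x)
    raise ValidationError(f"unknown clustering method {method!r}")


def reconstruction_rho(
    original: OmicsMatrix | np.ndarray,
    reconstructed: np.ndarray,
    max_cells: int = 1000,
    seed: int = 0,
) -> float:
    """Pearson correlation between original and reconstructed pairwise
    Euclidean cell distances, on a seeded subsample of up to ``max_cells``."""
    x = original.dense() if isinstance(original, OmicsMatrix) else np.asarray(original, float)
    y = np.asarray(reconstructed, dtype=np.float64)
    if x.shape != y.shape:
        raise ValidationError(f"shape mismatch: {x.shape} vs {y.shape}")
    n = x.shape[0]
    if n < 3:
        raise ValidationError("need at least 3 cells for distance correlation")
    if n > max_cells:
        rng = np.random.default_rng(int(seed) % (2**31))
        idx = np.sort(rng.choice(n, size=max_cells, replace=False))
        x, y = x[idx], y[idx]
    dx = pdist(x)
    dy = pdist(y)
    if dx.std() == 0 or dy.std() == 0:
        raise ValidationError(
            "degenerate (constant) pairwise distances; cannot correlate"
        )
    return float(np.corrcoef(dx, dy)[0, 1])


def ors(
    originals: PairedDataset | Sequence[np.ndarray],
    reconstructions: Sequence[np.ndarray],
    max_cells: int = 1000,
    seed: int = 0,
) -> ReconstructionScore:
    """Overall Reconstruction Score: unweighted mean of per-modality rho."""
    mats = (originals.matrices() if isinstance(originals, PairedDataset)
            else [np.asarray(x, float) for x in originals])
    if len(mats) != len(reconstructions):
        raise ValidationError(
            f"{len(mats)} originals vs {len(reconstructions)} reconstructions"
        )
    rho = [reconstruction_rho(x, r, max_cells=max_cells, seed=seed)
           for x, r in zip(mats, reconstructions)]
    return ReconstructionScore(rho)


def internal_indices(
    embedding: Embedding | np.ndarray, labels: Sequence
) -> tuple[float, float]:
    """(silhouette, Davies–Bouldin) of a labeling on an embedding.

    Both need >= 2 clusters; DB diverges when two cluster centroids
    coincide (surfaced as inf by the underlying computation).
    """
    x = embedding.values if isinstance(embedding, Embedding) else np.asarray(embedding)
    lab = _as_labels(labels)
    if len(lab) != x.shape[0]:
        raise ValidationError("labels length does not match embedding rows")
    if len(np.unique(lab)) < 2:
        raise ValidationError("internal indices undefined for a single cluster")
    sil = float(silhouette_score(x, lab, metric="euclidean"))
    with np.errstate(divide="ignore", invalid="ignore"):
        db = float(davies_bouldin_score(x, lab))
    return sil, db
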