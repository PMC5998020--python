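"""Unsupervised blob-class discovery and cross-population group matching.

Groups are discovered per population with X-means (BIC-driven recursive
2-means splitting on standardized descriptors).  Groups from two
populations are matched on the Euclidean distance between their raw
centroid descriptors with threshold beta (default 30); a group whose
nearest counterpart lies at distance >= beta stays unmatched — the
signature of a class present in only one population.  Test-phase blobs
are labeled by their nearest centroid in the standardized space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .blobs import BlobDescriptor
from .registry import BLOB_FEATURES, BLOB_REGISTRY_VERSION

__all__ = [
    "GroupModel",
    "MatchResult",
    "discover_groups",
    "match_groups",
    "assign_blobs",
    "xmeans",
]

DEFAULT_BETA = 30.0


@dataclass
class GroupModel:
    """Learned blob groups of one population."""

    centroids: np.ndarray          # (K, d) in raw descriptor units
    scale_mean: np.ndarray         # (d,) standardization fitted on training
    scale_std: np.ndarray          # (d,)
    sizes: np.ndarray              # (K,) member counts, descending
    population_tag: str = ""
    feature_names: tuple[str, ...] = BLOB_FEATURES
    registry_version: str = BLOB_REGISTRY_VERSION

    @property
    def n_groups(self) -> int:
        return len(self.centroids)

    @property
    def centroids_scaled(self) -> np.ndarray:
        return (self.centroids - self.scale_mean) / self.scale_std

    def to_json(self, path=None) -> str:
        payload = json.dumps({
            "population_tag": self.population_tag,
            "registry_version": self.registry_version,
            "feature_names": list(self.feature_names),
            "centroids": self.centroids.tolist(),
            "scale_mean": self.scale_mean.tolist(),
            "scale_std": self.scale_std.tolist(),
            "sizes": self.sizes.tolist(),
        }, indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source) -> "GroupModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(
            source)
        d = json.loads(text)
        return cls(centroids=np.asarray(d["centroids"], dtype=np.float64),
                   scale_mean=np.asarray(d["scale_mean"], dtype=np.float64),
                   scale_std=np.asarray(d["scale_std"], dtype=np.float64),
                   sizes=np.asarray(d["sizes"], dtype=np.int64),
                   population_tag=d.get("population_tag", ""),
                   feature_names=tuple(d.get("feature_names", BLOB_FEATURES)),
                   registry_version=d.get("registry_version",
                                          BLOB_REGISTRY_VERSION))


@dataclass
class MatchResult:
    """Pairs (i in A, j* in B) within beta, with distances and e^-d report."""

    pairs: list[tuple[int, int]]
    distances: np.ndarray          # (N, M) full centroid distance matrix
    similarities: np.ndarray       # e^{-distances}, report-only
    unmatched_a: list[int]
    beta: float


def _spherical_bic(X: np.ndarray, labels: np.ndarray,
                   centers: np.ndarray) -> float:
    """BIC of a spherical-Gaussian K-means model (Pelleg-Moore form).

    Returns -inf when the within-cluster variance degenerates to 0 with
    more free parameters than a single point supports.
    """
    n, d = X.shape
    k = len(centers)
    if n <= k:
        return -np.inf
    resid = X - centers[labels]
    ssq = float(np.sum(resid ** 2))
    var = ssq / (d * (n - k))
    if var <= 1e-30:
        # all points coincide with their centers; likelihood unbounded,
        # treat extra clusters as unjustified
        var = 1e-30
    ll = 0.0
    for j in range(k):
        nj = int(np.sum(labels == j))
        if nj == 0:
            continue
        ll += (nj * np.log(nj) - nj * np.log(n)
               - nj * d / 2.0 * np.log(2.0 * np.pi * var)
               - (nj - 1) * d / 2.0)
    p = (k - 1) + k * d + 1
    return ll - p / 2.0 * np.log(n)


def xmeans(X: np.ndarray, k_max: int = 10, seed: int = 0,
           n_restarts: int = 10) -> np.ndarray:
    """Cluster-count selection by the X-means BIC criterion.

    Scores a seeded k-means model for every K in 1..k_max with the
    spherical-Gaussian BIC and keeps the best.  (A purely recursive
    2-way splitting search can stall at configurations where the first
    bisection is BIC-indifferent — e.g. four equal clusters on a square —
    so the search is over K globally; the selection criterion is the
    same.)  Returns integer labels.
    """
    X = np.asarray(X, dtype=np.float64)
    n = len(X)
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    best_labels = np.zeros(n, dtype=np.int64)
    best_bic = _spherical_bic(X, best_labels, X.mean(axis=0, keepdims=True))
    if np.allclose(X, X[0]):
        return best_labels
    for k in range(2, min(k_max, n - 1) + 1):
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        labels = km.fit_predict(X)
        if len(np.unique(labels)) < k:
            continue
        bic = _spherical_bic(X, labels, km.cluster_centers_)
        if bic > best_bic:
            best_bic = bic
            best_labels = labels.astype(np.int64)
    _, best_labels = np.unique(best_labels, return_inverse=True)
    return best_labels


def _descriptor_matrix(descriptors) -> np.ndarray:
    if isinstance(descriptors, np.ndarray):
        return np.asarray(descriptors, dtype=np.float64)
    rows = [d.values if isinstance(d, BlobDescriptor) else np.asarray(d)
            for d in descriptors]
    return np.asarray(rows, dtype=np.float64)


def discover_groups(descriptors, k_max: int = 10, seed: int = 0,
                    population_tag: str = "") -> GroupModel:
    """Discover blob groups by X-means on standardized descriptors.

    Descriptor features are strongly correlated, which breaks the
    spherical-Gaussian BIC; clustering therefore runs on the principal
    components holding 99 % of the standardized variance.  Groups are
    relabeled in descending size order; centroids are reported in raw
    descriptor units (the matching space).
    """
    X = _descriptor_matrix(descriptors)
    if len(X) < 2 * 2:
        raise ValueError("too few blobs to discover groups")
    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=0)
    std = np.where(std > 0, std, 1.0)
    Xs = (X - mean) / std
    if not np.allclose(Xs, Xs[0]):
        n_comp = min(len(Xs) - 1, Xs.shape[1])
        pca = PCA(n_components=n_comp, random_state=seed).fit(Xs)
        keep = int(np.searchsorted(
            np.cumsum(pca.explained_variance_ratio_), 0.99) + 1)
        Xs = pca.transform(Xs)[:, :max(keep, 2)]
    labels = xmeans(Xs, k_max=k_max, seed=seed)
    uniq, counts = np.unique(labels, return_counts=True)
    order = np.argsort(-counts, kind="stable")
    centroids = np.array([X[labels == uniq[o]].mean(axis=0) for o in order])
    return GroupModel(centroids=centroids, scale_mean=mean, scale_std=std,
                      sizes=counts[order], population_tag=population_tag)


def match_groups(model_a: GroupModel, model_b: GroupModel,
                 beta: float = DEFAULT_BETA, use_scaled: bool = False,
                 feature_subset: Optional[Sequence[str]] = None
                 ) -> MatchResult:
    """Match each group of A to its nearest group of B within ``beta``.

    Distances are Euclidean between centroids — raw feature units by
    default (the scale on which beta = 30 is quoted), standardized when
    ``use_scaled``.  ``feature_subset`` restricts the distance to named
    features (e.g. the molecule-count sensitivity re-run).
    """
    if model_a.feature_names != model_b.feature_names or (
            model_a.registry_version != model_b.registry_version):
        raise ValueError("group models use different descriptor registries")
    ca = model_a.centroids_scaled if use_scaled else model_a.centroids
    cb = model_b.centroids_scaled if use_scaled else model_b.centroids
    if feature_subset is not None:
        cols = [model_a.feature_names.index(f) for f in feature_subset]
        ca, cb = ca[:, cols], cb[:, cols]
    dist = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=2)
    pairs: list[tuple[int, int]] = []
    unmatched: list[int] = []
    for i in range(len(ca)):
        j = int(np.argmin(dist[i]))
        if dist[i, j] < beta:
            pairs.append((i, j))
        else:
            unmatched.append(i)
    return MatchResult(pairs=pairs, distances=dist,
                       similarities=np.exp(-dist), unmatched_a=unmatched,
                       beta=beta)


def assign_blobs(model: GroupModel, descriptors
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-centroid group label for each blob (standardized space).

    Returns ``(labels, distances)``; exact ties resolve to the lowest
    group index.
    """
    X = _descriptor_matrix(descriptors)
    Xs = (X - model.scale_mean) / model.scale_std
    cs = model.centroids_scaled
    dist = np.linalg.norm(Xs[:, None, :] - cs[None, :, :], axis=2)
    labels = np.argmin(dist, axis=1)  # argmin takes the first (lowest) index
    return labels, dist[np.arange(len(X)), labels]
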