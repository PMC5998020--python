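"""Blob segmentation (mean shift) and the 28-feature blob descriptor.

Retained localizations are segmented into blobs by flat-kernel mean
shift; each blob is then summarised by a fixed 28-entry descriptor
covering size (convex-hull volume and coordinate ranges), shape
(covariance-eigenvalue statistics), hollowness (member distances to the
centroid) and network structure at the 80 nm analysis threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from sklearn.cluster import MeanShift

from . import netgraph
from .io_events import LocalizationSet
from .registry import BLOB_FEATURES, BLOB_REGISTRY_VERSION

__all__ = [
    "Blob",
    "BlobDescriptor",
    "segment_blobs",
    "blob_descriptor",
    "multi_threshold_modularity",
    "descriptor_frame",
]

DEFAULT_BANDWIDTH_NM = 80.0
DEFAULT_MIN_BLOB_SIZE = 3
NETWORK_T_NM = 80.0


@dataclass
class Blob:
    members: LocalizationSet
    blob_id: int = 0
    roi_ref: str = ""
    member_indices: Optional[np.ndarray] = None  # into the segmented set
    mode: Optional[np.ndarray] = None            # mean-shift mode (3,)

    def __len__(self) -> int:
        return len(self.members)

    @property
    def points(self) -> np.ndarray:
        return self.members.points


@dataclass
class BlobDescriptor:
    """28 named features of one blob (see :mod:`netlyze.registry`)."""

    values: np.ndarray
    names: tuple[str, ...] = BLOB_FEATURES
    degenerate: bool = False       # hull/shape terms unavailable or flat
    registry_version: str = BLOB_REGISTRY_VERSION
    blob_id: int = 0

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.values)))


def segment_blobs(points, bandwidth: float = DEFAULT_BANDWIDTH_NM,
                  min_size: int = DEFAULT_MIN_BLOB_SIZE,
                  roi_ref: str = "") -> tuple[list[Blob], np.ndarray]:
    """Mean-shift segmentation of a localization set into blobs.

    Every point is assigned to the basin of the mode it converges to
    (flat kernel of radius ``bandwidth``).  Basins with fewer than
    ``min_size`` members are diverted to the unassigned pool.  Returns
    ``(blobs, unassigned_indices)``; blob ids are ordered by descending
    member count.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    locs = points if isinstance(points, LocalizationSet) else LocalizationSet(
        points=np.asarray(points, dtype=np.float64).reshape(-1, 3))
    n = len(locs)
    if n == 0:
        return [], np.zeros(0, dtype=np.int64)
    if n == 1:
        labels = np.zeros(1, dtype=int)
        modes = locs.points.copy()
    else:
        ms = MeanShift(bandwidth=bandwidth, bin_seeding=False,
                       cluster_all=True)
        ms.fit(locs.points)
        labels = ms.labels_
        modes = ms.cluster_centers_

    blobs: list[Blob] = []
    unassigned: list[np.ndarray] = []
    order = np.argsort([-(labels == lab).sum() for lab in np.unique(labels)])
    uniq = np.unique(labels)[order]
    next_id = 0
    for lab in uniq:
        idx = np.flatnonzero(labels == lab)
        if len(idx) < min_size:
            unassigned.append(idx)
            continue
        blobs.append(Blob(members=locs.subset(labels == lab),
                          blob_id=next_id, roi_ref=roi_ref,
                          member_indices=idx,
                          mode=modes[lab] if lab < len(modes) else None))
        next_id += 1
    pool = (np.concatenate(unassigned) if unassigned
            else np.zeros(0, dtype=np.int64))
    return blobs, np.sort(pool)


def _shape_stats(pts: np.ndarray) -> tuple[np.ndarray, bool]:
    """Covariance eigenvalues (descending, clipped >= 0) + degeneracy flag."""
    if len(pts) < 3:
        return np.zeros(3), True
    cov = np.cov(pts.T)
    lam = np.sort(np.linalg.eigvalsh(cov))[::-1]
    lam = np.clip(lam, 0.0, None)
    return lam, bool(lam[0] <= 0)


def _hull_volume(pts: np.ndarray) -> tuple[float, bool]:
    if len(pts) < 4:
        return 0.0, True
    try:
        return float(ConvexHull(pts).volume), False
    except QhullError:
        return 0.0, True  # coplanar / collinear members


def blob_descriptor(b, network_T: float = NETWORK_T_NM) -> BlobDescriptor:
    """Compute the 28-feature signature of a blob.

    Shape terms derive from the covariance eigenvalues lam1 >= lam2 >=
    lam3: fractional anisotropy (normalized eigenvalue dispersion),
    linearity (lam1-lam2)/lam1, planarity (lam2-lam3)/lam1 and sphericity
    lam3/lam1.  Network terms are evaluated at ``network_T``; modularity
    is taken on the largest connected component when the blob is
    disconnected at that threshold.  Degenerate blobs (fewer than 3
    members, or flat hulls) get zeroed shape/volume terms and the
    ``degenerate`` flag.
    """
    pts = b.points if isinstance(b, Blob) else np.asarray(b).reshape(-1, 3)
    blob_id = b.blob_id if isinstance(b, Blob) else 0
    n = len(pts)
    if n == 0:
        raise ValueError("cannot describe an empty blob")
    centroid = pts.mean(axis=0)
    d = np.linalg.norm(pts - centroid, axis=1)
    ranges = pts.max(axis=0) - pts.min(axis=0) if n > 1 else np.zeros(3)

    volume, hull_degen = _hull_volume(pts)
    lam, shape_degen = _shape_stats(pts)
    l1, l2, l3 = lam
    if l1 > 0:
        lam_bar = lam.mean()
        fa = float(np.sqrt(1.5 * np.sum((lam - lam_bar) ** 2)
                           / np.sum(lam ** 2)))
        linearity = float((l1 - l2) / l1)
        planarity = float((l2 - l3) / l1)
        sphericity = float(l3 / l1)
        r21, r31 = float(l2 / l1), float(l3 / l1)
        r32 = float(l3 / l2) if l2 > 0 else 0.0
    else:
        fa = linearity = planarity = sphericity = r21 = r31 = r32 = 0.0

    g = netgraph.build_graph(pts, network_T)
    node = netgraph.node_measures(g)
    from scipy.sparse.csgraph import connected_components
    n_comp, comp = connected_components(g.adjacency(weighted=False),
                                        directed=False)
    # modularity on the largest component when disconnected
    if n_comp > 1:
        sizes = np.bincount(comp)
        keep = comp == np.argmax(sizes)
        sub = netgraph.build_graph(pts[keep], network_T)
        part = netgraph.newman_partition(sub)
    else:
        part = netgraph.newman_partition(g)
    cpl, _ = netgraph._char_path_and_efficiency(g, weighted=False)

    values = {
        "volume": volume,
        "x_range": float(ranges[0]),
        "y_range": float(ranges[1]),
        "z_range": float(ranges[2]),
        "sphericity": sphericity,
        "fractional_anisotropy": fa,
        "linearity": linearity,
        "planarity": planarity,
        "pca_lambda1": float(l1),
        "pca_lambda2": float(l2),
        "pca_lambda3": float(l3),
        "pca_ratio21": r21,
        "pca_ratio31": r31,
        "pca_ratio32": r32,
        "pca_total_var": float(lam.sum()),
        "dist_centroid_min": float(d.min()),
        "dist_centroid_mean": float(d.mean()),
        "dist_centroid_max": float(d.max()),
        "dist_centroid_sd": float(d.std(ddof=0)),
        "n_nodes": float(n),
        "uw_avg_degree": float(node["uw_degree"].mean()),
        "w_avg_degree": float(node["w_degree"].mean()),
        "uw_avg_cc": float(node["uw_cc"].mean()),
        "w_avg_cc": float(node["w_cc"].mean()),
        "char_path": cpl,
        "modularity": part.Q,
        "n_modules": float(part.n_modules),
        "n_components": float(n_comp),
    }
    vec = np.array([values[name] for name in BLOB_FEATURES])
    return BlobDescriptor(values=vec, degenerate=hull_degen or shape_degen,
                          blob_id=blob_id)


def multi_threshold_modularity(b, grid: Sequence[float]) -> pd.DataFrame:
    """Component and module structure of a blob across thresholds.

    For each T: number of connected components, Newman module count
    within the largest component, and the mean module size.
    """
    grid = np.asarray(grid, dtype=np.float64)
    if grid.size == 0:
        raise ValueError("threshold grid must be non-empty")
    pts = b.points if isinstance(b, Blob) else np.asarray(b).reshape(-1, 3)
    from scipy.sparse.csgraph import connected_components
    records = []
    for T in grid:
        g = netgraph.build_graph(pts, T)
        n_comp, comp = connected_components(g.adjacency(weighted=False),
                                            directed=False)
        sizes = np.bincount(comp)
        keep = comp == np.argmax(sizes)
        sub = netgraph.build_graph(pts[keep], T)
        part = netgraph.newman_partition(sub)
        records.append({
            "threshold_nm": float(T),
            "n_components": int(n_comp),
            "n_modules": int(part.n_modules),
            "mean_module_size": float(keep.sum() / part.n_modules),
        })
    return pd.DataFrame.from_records(records).set_index("threshold_nm")


def descriptor_frame(descriptors: Sequence[BlobDescriptor]) -> pd.DataFrame:
    """Blob table: one row per blob, 28 descriptor columns + flags."""
    rows = []
    for d in descriptors:
        row = {"blob_id": d.blob_id, "degenerate": d.degenerate}
        row.update(d.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)
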