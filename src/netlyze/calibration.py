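"""Single-antibody calibration: gating, single-vs-cluster split, spreads.

Blobs segmented from a single-antibody acquisition are gated by the
conjunction (#blinks < 6 AND XY area <= 100 nm^2), then split into
single- and multi-antibody classes with K-means (K = 2); the per-axis
standard deviation of the raw blink coordinates in the single class
estimates the effective localization precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from sklearn.cluster import KMeans

from .blobs import Blob

__all__ = [
    "CalibrationReport",
    "blob_area_xy",
    "calibration_features",
    "gate_blobs",
    "split_single_vs_cluster",
]

DEFAULT_MIN_BLINKS = 6
DEFAULT_MAX_AREA_NM2 = 100.0


def blob_area_xy(b) -> float:
    """2D convex-hull area of the blob's XY projection (0 if degenerate)."""
    pts = b.points if isinstance(b, Blob) else np.asarray(b).reshape(-1, 3)
    xy = np.unique(pts[:, :2], axis=0)
    if len(xy) < 3:
        return 0.0
    try:
        return float(ConvexHull(xy).volume)  # 2D hull: volume == area
    except QhullError:
        return 0.0  # collinear projection


def calibration_features(blobs: Sequence[Blob]) -> pd.DataFrame:
    """Per-blob calibration table: blink count, XY area, per-axis SDs."""
    rows = []
    for b in blobs:
        pts = b.points
        sd = pts.std(axis=0, ddof=1) if len(pts) > 1 else np.zeros(3)
        rows.append({
            "blob_id": b.blob_id,
            "n_blinks": len(pts),
            "area_nm2": blob_area_xy(b),
            "sd_x": float(sd[0]),
            "sd_y": float(sd[1]),
            "sd_z": float(sd[2]),
        })
    return pd.DataFrame(rows)


def gate_blobs(blobs: Sequence[Blob],
               min_blinks: int = DEFAULT_MIN_BLINKS,
               max_area: float = DEFAULT_MAX_AREA_NM2) -> list[Blob]:
    """Drop blobs satisfying BOTH gate clauses (few blinks AND small area).

    A blob survives if it has at least ``min_blinks`` blinks or its XY
    area exceeds ``max_area`` nm^2.
    """
    return [b for b in blobs
            if not (len(b) < min_blinks and blob_area_xy(b) <= max_area)]


@dataclass
class CalibrationReport:
    """Outcome of the single-vs-cluster split."""

    table: pd.DataFrame            # calibration features + class column
    single_mean_sd: np.ndarray     # (3,) mean per-axis SD, single class
    cluster_mean_sd: np.ndarray    # (3,) mean per-axis SD, cluster class
    gate: tuple[int, float]
    degenerate: bool = False       # all blobs identical: split meaningless


def split_single_vs_cluster(blobs: Sequence[Blob], seed: int = 0,
                            gate: tuple[int, float] = (
                                DEFAULT_MIN_BLINKS, DEFAULT_MAX_AREA_NM2)
                            ) -> CalibrationReport:
    """K-means (K = 2) split of gated blobs into single vs cluster class.

    Clustering runs on standardized calibration features (blink count,
    area, per-axis spreads); the class with the smaller mean area is
    labeled ``single``.  Reports the mean per-axis blink SD per class.
    """
    if len(blobs) < 2:
        raise ValueError("need at least 2 blobs to split")
    feats = calibration_features(blobs)
    X = feats[["n_blinks", "area_nm2", "sd_x", "sd_y", "sd_z"]].to_numpy(
        dtype=np.float64)
    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=0)
    degenerate = bool(np.all(std == 0))
    if degenerate:
        labels = np.zeros(len(X), dtype=int)
    else:
        Xs = (X - mean) / np.where(std > 0, std, 1.0)
        labels = KMeans(n_clusters=2, n_init=10,
                        random_state=seed).fit_predict(Xs)
    areas = feats["area_nm2"].to_numpy()
    if degenerate or len(np.unique(labels)) < 2:
        single_label = 0
        degenerate = True
    else:
        single_label = int(np.argmin(
            [areas[labels == k].mean() for k in (0, 1)]))
    feats["cls"] = np.where(labels == single_label, "single", "cluster")
    sd_cols = ["sd_x", "sd_y", "sd_z"]

    def _mean_sd(cls: str) -> np.ndarray:
        sel = feats["cls"] == cls
        if not sel.any():
            return np.full(3, np.nan)
        return feats.loc[sel, sd_cols].mean().to_numpy()

    return CalibrationReport(table=feats,
                             single_mean_sd=_mean_sd("single"),
                             cluster_mean_sd=_mean_sd("cluster"),
                             gate=gate, degenerate=degenerate)
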