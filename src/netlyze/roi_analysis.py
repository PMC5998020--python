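"""Multi-threshold ROI feature extraction and population statistics.

Each ROI is summarised by the 32-measure registry evaluated on proximity
graphs at 24 thresholds (20..250 nm, step 10), a 768-entry vector.  The
two populations are compared per feature-threshold cell with a two-sided
Mann-Whitney test; per-experiment p-value matrices are combined by the
L2-norm (so any non-significant experiment dominates) and thresholded
with Bonferroni correction over the 768 comparisons.  A seeded random
forest with leave-one-cell-out cross-validation scores how well the
features separate the populations at each threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from . import netgraph
from .registry import _GRAPH_LEVEL, _NODE_LEVEL, ROI_MEASURES

__all__ = [
    "threshold_grid",
    "RoiFeatureVector",
    "SignificanceMap",
    "roi_features",
    "features_frame",
    "mw_test",
    "aggregate_pvalues",
    "rf_validate",
]

BONFERRONI_ALPHA = 0.05


def threshold_grid() -> np.ndarray:
    """The analysis grid of proximity thresholds: 20..250 nm, step 10."""
    return np.arange(20.0, 251.0, 10.0)


@dataclass
class RoiFeatureVector:
    """32 measures x 24 thresholds for one ROI (flattened length 768)."""

    values: np.ndarray            # (32, 24)
    measure_names: tuple[str, ...]
    thresholds_nm: np.ndarray     # (24,)
    missing: bool = False         # degenerate ROI (fewer than 2 points)
    cell_id: str = ""
    roi_index: int = 0

    @property
    def flat(self) -> np.ndarray:
        return self.values.ravel()

    def __len__(self) -> int:
        return self.values.size


@dataclass
class SignificanceMap:
    """L2-combined p-values and the Bonferroni-corrected significance mask."""

    p_combined: np.ndarray
    significant_mask: np.ndarray
    measure_names: tuple[str, ...]
    thresholds_nm: np.ndarray
    alpha: float
    n_comparisons: int


def _measures_at_threshold(points: np.ndarray, T: float) -> np.ndarray:
    g = netgraph.build_graph(points, T)
    node = netgraph.node_measures(g)
    gm = {False: netgraph.graph_measures(g, weighted=False),
          True: netgraph.graph_measures(g, weighted=True)}
    out = np.empty(len(ROI_MEASURES))
    i = 0
    for _, key, stat in _NODE_LEVEL:
        vals = node[key]
        out[i] = float(np.mean(vals)) if stat == "mean" else float(
            np.median(vals))
        i += 1
    for _, key, weighted in _GRAPH_LEVEL:
        out[i] = gm[weighted][key]
        i += 1
    return out


def roi_features(roi, thresholds: Optional[Sequence[float]] = None
                 ) -> RoiFeatureVector:
    """Evaluate the full measure registry over the threshold grid.

    ROIs with fewer than 2 points return an all-zero vector flagged
    ``missing`` rather than propagating NaNs.
    """
    grid = np.asarray(thresholds if thresholds is not None else
                      threshold_grid(), dtype=np.float64)
    pts = roi
    while hasattr(pts, "points"):  # Roi -> LocalizationSet -> ndarray
        pts = pts.points
    pts = np.asarray(pts, dtype=np.float64).reshape(-1, 3)
    cell_id = getattr(roi, "cell_id", "")
    roi_index = int(getattr(roi, "roi_index", 0))
    if len(pts) < 2:
        return RoiFeatureVector(
            values=np.zeros((len(ROI_MEASURES), len(grid))),
            measure_names=ROI_MEASURES, thresholds_nm=grid, missing=True,
            cell_id=cell_id, roi_index=roi_index)
    vals = np.column_stack([_measures_at_threshold(pts, T) for T in grid])
    return RoiFeatureVector(values=vals, measure_names=ROI_MEASURES,
                            thresholds_nm=grid, missing=False,
                            cell_id=cell_id, roi_index=roi_index)


def features_frame(fvs: Iterable[RoiFeatureVector]) -> pd.DataFrame:
    """Tabulate feature vectors: one row per ROI, columns ``measure@T``."""
    fvs = list(fvs)
    if not fvs:
        return pd.DataFrame()
    cols = [f"{m}@{int(t)}" for m in fvs[0].measure_names
            for t in fvs[0].thresholds_nm]
    data = np.vstack([fv.flat for fv in fvs])
    df = pd.DataFrame(data, columns=cols)
    df.insert(0, "cell_id", [fv.cell_id for fv in fvs])
    df.insert(1, "roi_index", [fv.roi_index for fv in fvs])
    df.insert(2, "missing", [fv.missing for fv in fvs])
    return df


def mw_test(a, b) -> float:
    """Two-sided Mann-Whitney U p-value (exact for small tie-free samples).

    Pooled all-identical samples carry no evidence and score p = 1.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method="auto").pvalue)


def aggregate_pvalues(p_per_experiment: Sequence[np.ndarray],
                      alpha: float = BONFERRONI_ALPHA,
                      measure_names: tuple[str, ...] = ROI_MEASURES,
                      thresholds: Optional[np.ndarray] = None
                      ) -> SignificanceMap:
    """Combine per-experiment p matrices by the entrywise L2-norm.

    A single large p dominates the norm, so a feature is only called
    significant when it is significant in every experiment; the mask then
    applies Bonferroni over all feature-threshold comparisons.
    """
    mats = [np.asarray(p, dtype=np.float64) for p in p_per_experiment]
    if not mats:
        raise ValueError("need at least one p matrix")
    shape = mats[0].shape
    for m in mats:
        if m.shape != shape:
            raise ValueError("p matrices must share one shape")
    combined = np.sqrt(np.sum([m ** 2 for m in mats], axis=0))
    n_comp = int(np.prod(shape))
    mask = combined < (alpha / n_comp)
    if thresholds is None:
        thresholds = threshold_grid()
    return SignificanceMap(p_combined=combined, significant_mask=mask,
                           measure_names=measure_names,
                           thresholds_nm=np.asarray(thresholds),
                           alpha=alpha, n_comparisons=n_comp)


def mw_map(features_a: pd.DataFrame, features_b: pd.DataFrame) -> np.ndarray:
    """Per feature-threshold Mann-Whitney p matrix (32 x 24) between two
    populations of ROI feature rows (as from :func:`features_frame`)."""
    cols = [c for c in features_a.columns if "@" in c]
    grid = threshold_grid()
    out = np.ones((len(ROI_MEASURES), len(grid)))
    a_ok = ~features_a["missing"].to_numpy(dtype=bool)
    b_ok = ~features_b["missing"].to_numpy(dtype=bool)
    for i, m in enumerate(ROI_MEASURES):
        for j, t in enumerate(grid):
            col = f"{m}@{int(t)}"
            if col not in cols:
                continue
            out[i, j] = mw_test(features_a.loc[a_ok, col],
                                features_b.loc[b_ok, col])
    return out


def rf_validate(features: pd.DataFrame, labels: Sequence[str],
                thresholds: Optional[Sequence[float]] = None,
                feature_subset: Optional[Sequence[str]] = None,
                n_estimators: int = 500, seed: int = 0
                ) -> pd.DataFrame:
    """Leave-one-cell-out random-forest validation, per threshold.

    ``features`` is a :func:`features_frame` table with a ``cell_id``
    column; ``labels`` gives the population label per row (constant
    within a cell).  For each threshold a forest is trained on the
    32-measure slice (optionally restricted to ``feature_subset`` measure
    names), every cell held out in turn.  Returns a frame indexed by
    threshold with ``roi_accuracy`` and ``cell_accuracy`` (majority vote
    over the cell's ROIs).
    """
    labels = np.asarray(labels)
    usable = ~features["missing"].to_numpy(dtype=bool)
    df = features.loc[usable].reset_index(drop=True)
    labels = labels[usable]
    cells = df["cell_id"].to_numpy()
    if thresholds is None:
        thresholds = threshold_grid()
    measures = list(feature_subset) if feature_subset else list(ROI_MEASURES)

    records = []
    for t in thresholds:
        cols = [f"{m}@{int(t)}" for m in measures]
        X = df[cols].to_numpy()
        roi_hits = cell_hits = n_roi = n_cell = 0
        for cell in np.unique(cells):
            test = cells == cell
            if test.all() or not test.any():
                continue
            clf = RandomForestClassifier(n_estimators=n_estimators,
                                         random_state=seed)
            clf.fit(X[~test], labels[~test])
            pred = clf.predict(X[test])
            truth = labels[test]
            roi_hits += int(np.sum(pred == truth))
            n_roi += int(test.sum())
            vals, counts = np.unique(pred, return_counts=True)
            majority = vals[np.argmax(counts)]
            cell_hits += int(majority == truth[0])
            n_cell += 1
        records.append({
            "threshold_nm": float(t),
            "roi_accuracy": roi_hits / n_roi if n_roi else np.nan,
            "cell_accuracy": cell_hits / n_cell if n_cell else np.nan,
        })
    return pd.DataFrame.from_records(records).set_index("threshold_nm")
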