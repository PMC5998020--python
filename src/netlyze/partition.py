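"""Tiling of a cell-scale point cloud into fixed-size ROIs.

ROIs are axis-aligned boxes forming a disjoint cover of the cell extent,
using half-open intervals (x0, x1] closed at the upper edge: a point
exactly on an interior boundary plane belongs to the lower tile.  The
global minimum face is closed so no point is lost.  Empty ROIs are
retained (flagged) so the ROI count depends only on the extent, not the
data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .io_events import LocalizationSet

__all__ = ["Roi", "TilingError", "tile", "default_extent"]

_AXES = "xyz"


class TilingError(ValueError):
    """ROI size does not divide the cell extent along some axis."""


@dataclass
class Roi:
    """One tile of a cell: bounds (2, 3) nm array [[lo], [hi]] + contents."""

    bounds: np.ndarray
    points: LocalizationSet
    cell_id: str = ""
    roi_index: int = 0
    grid_index: tuple[int, int, int] = (0, 0, 0)
    source_indices: Optional[np.ndarray] = None  # into the tiled set

    @property
    def empty(self) -> bool:
        return len(self.points) == 0

    def __len__(self) -> int:
        return len(self.points)


def default_extent(points: np.ndarray, roi_size: Sequence[float]) -> np.ndarray:
    """Tight bounding box rounded outward to a multiple of ``roi_size``.

    Anchored at the data minimum corner; degenerate axes get one tile.
    """
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    if len(pts) == 0:
        raise ValueError("cannot infer an extent from an empty point set")
    size = np.asarray(roi_size, dtype=np.float64)
    lo = pts.min(axis=0)
    span = pts.max(axis=0) - lo
    ntiles = np.maximum(1, np.ceil(span / size - 1e-12)).astype(int)
    return np.array([lo, lo + ntiles * size])


def tile(points, roi_size: Sequence[float],
         cell_extent: Optional[np.ndarray] = None,
         cell_id: str = "") -> list[Roi]:
    """Partition ``points`` into ROIs of size ``roi_size`` (dx, dy, dz) nm.

    ``cell_extent`` is a (2, 3) array [[x0,y0,z0],[x1,y1,z1]]; when None
    it defaults to :func:`default_extent`.  Raises :class:`TilingError`
    naming the axis if the extent is not an exact multiple of the ROI
    size.  Every in-extent point lands in exactly one ROI.
    """
    locs = points if isinstance(points, LocalizationSet) else LocalizationSet(
        points=np.asarray(points, dtype=np.float64).reshape(-1, 3))
    size = np.asarray(roi_size, dtype=np.float64)
    if np.any(size <= 0):
        raise TilingError("roi_size components must be positive")
    if cell_extent is None:
        extent = default_extent(locs.points, size)
    else:
        extent = np.asarray(cell_extent, dtype=np.float64).reshape(2, 3)
    span = extent[1] - extent[0]
    counts = span / size
    ntiles = np.rint(counts).astype(int)
    for ax in range(3):
        if ntiles[ax] < 1 or abs(counts[ax] - ntiles[ax]) > 1e-9 * max(1.0, counts[ax]):
            raise TilingError(
                f"extent {span[ax]} nm along {_AXES[ax]} is not an exact "
                f"multiple of roi size {size[ax]} nm")

    pts = locs.points
    inside = np.all((pts >= extent[0]) & (pts <= extent[1]), axis=1)
    # (lo, hi] intervals: boundary points go to the lower tile; the global
    # minimum face is closed (clip to tile 0)
    idx3 = np.ceil((pts - extent[0]) / size).astype(int) - 1
    idx3 = np.clip(idx3, 0, ntiles - 1)

    rois: list[Roi] = []
    flat = 0
    for ix in range(ntiles[0]):
        for iy in range(ntiles[1]):
            for iz in range(ntiles[2]):
                sel = inside & np.all(idx3 == (ix, iy, iz), axis=1)
                lo = extent[0] + size * (ix, iy, iz)
                rois.append(Roi(
                    bounds=np.array([lo, lo + size]),
                    points=locs.subset(sel),
                    cell_id=cell_id,
                    roi_index=flat,
                    grid_index=(ix, iy, iz),
                    source_indices=np.flatnonzero(sel),
                ))
                flat += 1
    return rois
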