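"""Iterative blink merging: overcounting correction for multi-blinking.

Blinks within the resolution limit T (default 20 nm) are iteratively
collapsed onto their centroid, starting from the blink with the most
neighbors, until no pair of points is within T of each other.  The
surviving points are the predicted molecule localizations.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .io_events import EventList, LocalizationSet

__all__ = ["MergeParams", "neighbor_counts", "merge_blinks", "MergeError"]


class MergeError(RuntimeError):
    """Raised if the merge fails to converge (should be unreachable)."""


@dataclass(frozen=True)
class MergeParams:
    threshold_T: float = 20.0
    max_iterations: int | None = None  # default: input size (safe bound)

    def __post_init__(self) -> None:
        if self.threshold_T <= 0:
            raise ValueError("threshold_T must be positive")


def neighbor_counts(points, T: float) -> np.ndarray:
    """Number of *other* points within Euclidean distance <= T of each point.

    Uses a k-d tree fixed-radius query; coincident duplicates each count
    all their twins.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    pts = points.points if hasattr(points, "points") else np.asarray(points)
    pts = pts.reshape(-1, 3).astype(np.float64)
    if len(pts) == 0:
        return np.zeros(0, dtype=np.int64)
    tree = cKDTree(pts)
    counts = tree.query_ball_point(pts, r=T, return_length=True)
    return np.asarray(counts, dtype=np.int64) - 1


class _Grid:
    """Uniform spatial hash over a dynamic point set (cell size = T)."""

    def __init__(self, cell: float):
        self.cell = cell
        self.cells: dict[tuple[int, int, int], set[int]] = {}

    def key(self, p) -> tuple[int, int, int]:
        return (int(np.floor(p[0] / self.cell)),
                int(np.floor(p[1] / self.cell)),
                int(np.floor(p[2] / self.cell)))

    def add(self, idx: int, p) -> None:
        self.cells.setdefault(self.key(p), set()).add(idx)

    def remove(self, idx: int, p) -> None:
        k = self.key(p)
        bucket = self.cells.get(k)
        if bucket is not None:
            bucket.discard(idx)
            if not bucket:
                del self.cells[k]

    def query(self, p, r: float) -> list[int]:
        reach = int(np.ceil(r / self.cell))
        kx, ky, kz = self.key(p)
        out: list[int] = []
        for dx in range(-reach, reach + 1):
            for dy in range(-reach, reach + 1):
                for dz in range(-reach, reach + 1):
                    bucket = self.cells.get((kx + dx, ky + dy, kz + dz))
                    if bucket:
                        out.extend(bucket)
        return out


def merge_blinks(ev, params: MergeParams | None = None,
                 T: float | None = None) -> LocalizationSet:
    """Iteratively merge blinks within ``T`` nm into centroid localizations.

    At each step the point with the largest current neighbor count is
    replaced, together with all points within T of it, by the unweighted
    centroid of the original blinks they absorbed (tracked through
    repeated merges via coordinate sums).  Neighbor counts of points near
    the new centroid are refreshed before the next maximum is selected;
    ties break on lowest index (insertion order) for determinism.

    Postconditions: output minimum pairwise distance > T; the
    ``merged_from`` counts sum to the input blink count; the operation is
    idempotent.
    """
    if params is None:
        params = MergeParams() if T is None else MergeParams(threshold_T=T)
    T = params.threshold_T
    pts_in = ev.points if hasattr(ev, "points") else np.asarray(ev)
    pts_in = np.asarray(pts_in, dtype=np.float64).reshape(-1, 3)
    n = len(pts_in)
    label = getattr(ev, "source_label", "")
    if n == 0:
        return LocalizationSet(points=np.zeros((0, 3)),
                               merged_from=np.zeros(0, dtype=np.int64),
                               source_label=label)

    # Growable state: merged points append at fresh indices.
    coord_sum = [pts_in[i].copy() for i in range(n)]
    weight = [1] * n          # original blinks absorbed
    pos = [pts_in[i].copy() for i in range(n)]
    alive = [True] * n
    counts = list(neighbor_counts(pts_in, T))

    grid = _Grid(cell=T)
    for i in range(n):
        grid.add(i, pos[i])

    heap: list[tuple[int, int]] = [(-c, i) for i, c in enumerate(counts) if c > 0]
    heapq.heapify(heap)

    def live_neighbors(p, r):
        return [j for j in grid.query(p, r)
                if alive[j] and np.linalg.norm(pos[j] - p) <= r]

    max_iter = params.max_iterations or (n + 1)
    merges = 0
    while heap:
        negc, i = heapq.heappop(heap)
        if not alive[i] or counts[i] != -negc or counts[i] == 0:
            continue
        if merges >= max_iter:
            raise MergeError("merge did not converge within max_iterations")
        merges += 1

        group = live_neighbors(pos[i], T)  # includes i itself
        new_sum = np.sum([coord_sum[j] for j in group], axis=0)
        new_w = sum(weight[j] for j in group)
        centroid = new_sum / new_w
        for j in group:
            alive[j] = False
            grid.remove(j, pos[j])
        k = len(pos)
        pos.append(centroid)
        coord_sum.append(new_sum)
        weight.append(new_w)
        alive.append(True)
        counts.append(0)
        grid.add(k, centroid)

        # Counts can change for points within T of any removed point; all
        # removed points lie within 2T of the centroid, so a 3T ball is a
        # safe superset to refresh (plus the new point itself).
        for j in live_neighbors(centroid, 3 * T):
            c = len(live_neighbors(pos[j], T)) - 1
            counts[j] = c
            if c > 0:
                heapq.heappush(heap, (-c, j))

    keep = [i for i in range(len(pos)) if alive[i]]
    out_pts = np.array([pos[i] for i in keep], dtype=np.float64).reshape(-1, 3)
    out_w = np.array([weight[i] for i in keep], dtype=np.int64)

    # convergence assertion: no surviving pair within T
    if len(out_pts) > 1:
        if cKDTree(out_pts).query_pairs(r=T, output_type="ndarray").size:
            raise MergeError("merge terminated with a pair within threshold")
    assert out_w.sum() == n
    return LocalizationSet(points=out_pts, merged_from=out_w,
                           source_label=label)
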