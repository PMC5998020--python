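"""Proximity graphs over 3D point sets and their network measures.

A proximity graph joins every pair of points at Euclidean distance
d_ij <= T.  The weighted variant carries edge weights w_ij = 1/d_ij so
stronger edges connect more proximate nodes.  On top of the graph the
module provides node-level measures (degree, average neighbor degree,
clustering coefficient — weighted and unweighted), graph-level summaries
(characteristic path length, components, density, efficiency,
assortativity) and Newman leading-eigenvector modularity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components, shortest_path
from scipy.spatial import cKDTree

__all__ = [
    "ProximityGraph",
    "ModulePartition",
    "build_graph",
    "node_measures",
    "graph_measures",
    "newman_partition",
    "modularity",
    "random_points_like",
]

#: Cap on 1/d weights for (defensively handled) coincident points.
MIN_DISTANCE_NM = 1.0


@dataclass
class ProximityGraph:
    """Undirected threshold graph: edge (i, j) iff d_ij <= T."""

    n: int
    edges: np.ndarray        # (m, 2) int, i < j
    dists: np.ndarray        # (m,) nm
    threshold_T: float
    mode: str = "unweighted"  # "weighted" | "unweighted"

    @property
    def m(self) -> int:
        return len(self.edges)

    @property
    def weights(self) -> np.ndarray:
        """Edge weights w_ij = 1/d_ij (capped at 1/1 nm for d -> 0)."""
        return 1.0 / np.maximum(self.dists, MIN_DISTANCE_NM)

    def adjacency(self, weighted: Optional[bool] = None) -> sparse.csr_matrix:
        if weighted is None:
            weighted = self.mode == "weighted"
        vals = self.weights if weighted else np.ones(self.m)
        if self.m == 0:
            return sparse.csr_matrix((self.n, self.n))
        i, j = self.edges[:, 0], self.edges[:, 1]
        a = sparse.coo_matrix(
            (np.concatenate([vals, vals]),
             (np.concatenate([i, j]), np.concatenate([j, i]))),
            shape=(self.n, self.n))
        return a.tocsr()

    def distance_adjacency(self) -> sparse.csr_matrix:
        """Adjacency carrying d_ij (for weighted shortest paths)."""
        if self.m == 0:
            return sparse.csr_matrix((self.n, self.n))
        i, j = self.edges[:, 0], self.edges[:, 1]
        d = np.maximum(self.dists, MIN_DISTANCE_NM)
        return sparse.coo_matrix(
            (np.concatenate([d, d]),
             (np.concatenate([i, j]), np.concatenate([j, i]))),
            shape=(self.n, self.n)).tocsr()


@dataclass
class ModulePartition:
    """Node -> module assignment with its modularity score."""

    assignment: np.ndarray
    Q: float
    n_modules: int


def build_graph(points, T: float, mode: str = "unweighted") -> ProximityGraph:
    """Exact threshold graph over ``points`` at proximity threshold T nm."""
    if T <= 0:
        raise ValueError("T must be positive")
    if mode not in ("weighted", "unweighted"):
        raise ValueError("mode must be 'weighted' or 'unweighted'")
    pts = points.points if hasattr(points, "points") else np.asarray(points)
    pts = pts.reshape(-1, 3).astype(np.float64)
    n = len(pts)
    if n < 2:
        return ProximityGraph(n=n, edges=np.zeros((0, 2), dtype=np.int64),
                              dists=np.zeros(0), threshold_T=T, mode=mode)
    pairs = cKDTree(pts).query_pairs(r=T, output_type="ndarray")
    if pairs.size == 0:
        pairs = np.zeros((0, 2), dtype=np.int64)
        dists = np.zeros(0)
    else:
        pairs = np.sort(pairs, axis=1)
        order = np.lexsort((pairs[:, 1], pairs[:, 0]))
        pairs = pairs[order]
        dists = np.linalg.norm(pts[pairs[:, 0]] - pts[pairs[:, 1]], axis=1)
    return ProximityGraph(n=n, edges=pairs, dists=dists,
                          threshold_T=T, mode=mode)


def node_measures(g: ProximityGraph) -> dict[str, np.ndarray]:
    """Per-node measures, both weighted and unweighted variants.

    Keys: ``uw_degree``, ``w_degree`` (strength, sum of 1/d), ``uw_ndeg``
    and ``w_ndeg`` (average neighbor degree; weighted = w-averaged
    neighbor strength), ``uw_cc`` (triangle fraction) and ``w_cc``
    (Barrat weighted clustering).  Isolated nodes score 0 throughout.
    """
    n = g.n
    A = g.adjacency(weighted=False)
    W = g.adjacency(weighted=True)
    k = np.asarray(A.sum(axis=1)).ravel()            # unweighted degree
    s = np.asarray(W.sum(axis=1)).ravel()            # strength

    with np.errstate(divide="ignore", invalid="ignore"):
        uw_ndeg = np.where(k > 0, A.dot(k) / np.maximum(k, 1), 0.0)
        w_ndeg = np.where(s > 0, W.dot(s) / np.maximum(s, 1e-300), 0.0)

    # unweighted clustering: closed triangles / possible at each node
    tri = np.zeros(n)
    w_tri = np.zeros(n)
    if g.m:
        A2 = A.dot(A)
        tri = np.asarray(A2.multiply(A).sum(axis=1)).ravel() / 2.0
        # Barrat numerator: sum over ordered neighbor pairs (j, h) closing
        # a triangle at i of (w_ij + w_ih)/2, which by j<->h symmetry
        # equals sum_{j,h} w_ij a_jh a_ih = row sums of (W A) o A.
        WA = W.dot(A)
        w_tri = np.asarray(WA.multiply(A).sum(axis=1)).ravel()
    denom = k * (k - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        uw_cc = np.where(denom > 0, tri / np.maximum(denom, 1), 0.0)
        barrat_denom = s * (k - 1)
        w_cc = np.where(barrat_denom > 0,
                        w_tri / np.maximum(barrat_denom, 1e-300), 0.0)
    return {
        "uw_degree": k, "w_degree": s,
        "uw_ndeg": uw_ndeg, "w_ndeg": w_ndeg,
        "uw_cc": uw_cc, "w_cc": w_cc,
    }


def _char_path_and_efficiency(g: ProximityGraph,
                              weighted: bool) -> tuple[float, float]:
    """Characteristic path length over connected pairs + global efficiency.

    Unweighted paths count hops; weighted paths use d_ij as edge length.
    Disconnected pairs are excluded from the path average but count as
    efficiency 0.  Degenerate (n < 2 or edgeless) graphs score (0, 0).
    """
    n = g.n
    if n < 2 or g.m == 0:
        return 0.0, 0.0
    if weighted:
        D = shortest_path(g.distance_adjacency(), method="D", directed=False)
    else:
        D = shortest_path(g.adjacency(weighted=False), method="D",
                          directed=False, unweighted=True)
    iu = np.triu_indices(n, k=1)
    d = D[iu]
    finite = np.isfinite(d)
    cpl = float(d[finite].mean()) if finite.any() else 0.0
    with np.errstate(divide="ignore"):
        inv = np.where(finite & (d > 0), 1.0 / np.maximum(d, 1e-300), 0.0)
    eff = float(inv.mean())
    return cpl, eff


def _assortativity(g: ProximityGraph, weighted: bool) -> float:
    """Degree (or strength) Pearson correlation across edges; 0 if degenerate."""
    if g.m < 2:
        return 0.0
    nm = node_measures(g)
    deg = nm["w_degree"] if weighted else nm["uw_degree"]
    x = np.concatenate([deg[g.edges[:, 0]], deg[g.edges[:, 1]]])
    y = np.concatenate([deg[g.edges[:, 1]], deg[g.edges[:, 0]]])
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def modularity(g: ProximityGraph, assignment: np.ndarray,
               weighted: bool = False) -> float:
    """Newman modularity Q of a node partition.

    Q = (1/2m) sum_ij (A_ij - k_i k_j / 2m) [c_i == c_j]; the weighted
    variant substitutes edge weights for A.  Edgeless graphs score 0.
    """
    A = g.adjacency(weighted=weighted)
    two_m = A.sum()
    if two_m == 0:
        return 0.0
    k = np.asarray(A.sum(axis=1)).ravel()
    q = 0.0
    for c in np.unique(assignment):
        idx = np.flatnonzero(assignment == c)
        sub = A[np.ix_(idx, idx)]
        q += sub.sum() / two_m - (k[idx].sum() / two_m) ** 2
    return float(q)


def _fine_tune(Bsub: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Kernighan-Lin style refinement of a bisection vector s in {-1, +1}.

    Repeated sweeps move each node once (greedily by modularity gain,
    gains allowed to be negative mid-sweep) and keep the best
    configuration seen; stops when a full sweep yields no improvement.
    """
    n = len(s)
    best_val = s @ Bsub @ s
    improved = True
    while improved:
        improved = False
        cur = s.copy()
        cur_val = cur @ Bsub @ cur
        moved = np.zeros(n, dtype=bool)
        sweep_best_val, sweep_best_s = best_val, s.copy()
        for _ in range(n):
            row = Bsub @ cur
            gains = -4.0 * cur * row + 4.0 * np.diag(Bsub)
            gains[moved] = -np.inf
            i = int(np.argmax(gains))
            cur_val += gains[i]
            cur[i] = -cur[i]
            moved[i] = True
            if cur_val > sweep_best_val + 1e-12:
                sweep_best_val, sweep_best_s = cur_val, cur.copy()
        if sweep_best_val > best_val + 1e-12:
            best_val, s = sweep_best_val, sweep_best_s
            improved = True
    return s


def _leading_split(Bsub: np.ndarray, two_m: float,
                   tol: float = 1e-10) -> Optional[np.ndarray]:
    """One leading-eigenvector bisection of a generalized modularity
    submatrix, with KL fine-tuning.  Returns a boolean side mask, or
    None when no split with positive modularity gain exists."""
    vals, vecs = np.linalg.eigh(Bsub)
    if vals[-1] <= tol:
        return None
    s = np.where(vecs[:, -1] >= 0, 1.0, -1.0)
    s = _fine_tune(Bsub, s)
    dq = s @ Bsub @ s / (2.0 * two_m)
    if dq <= tol:
        return None
    side = s > 0
    if side.all() or not side.any():
        return None
    return side


def newman_partition(g: ProximityGraph,
                     weighted: bool = False) -> ModulePartition:
    """Community structure by recursive leading-eigenvector bisection.

    Each connected component is bisected along the leading eigenvector of
    its (generalized) modularity matrix B = A - k k^T / 2m, recursing
    while the split contributes positive modularity; the returned Q is
    computed on the final partition of the whole graph.
    """
    if g.n == 0:
        raise ValueError("empty graph")
    assignment = np.zeros(g.n, dtype=np.int64)
    A = g.adjacency(weighted=weighted)
    two_m = float(A.sum())
    if two_m == 0:
        # edgeless: every node its own (degenerate) module, Q = 0
        assignment = np.arange(g.n, dtype=np.int64)
        return ModulePartition(assignment=assignment, Q=0.0, n_modules=g.n)

    k = np.asarray(A.sum(axis=1)).ravel()
    Ad = np.asarray(A.todense())
    B = Ad - np.outer(k, k) / two_m

    n_comp, comp = connected_components(A, directed=False)
    next_label = 0
    for c in range(n_comp):
        members = np.flatnonzero(comp == c)
        stack = [members]
        while stack:
            grp = stack.pop()
            if len(grp) < 2:
                assignment[grp] = next_label
                next_label += 1
                continue
            Bg = B[np.ix_(grp, grp)].copy()
            Bg[np.diag_indices_from(Bg)] -= Bg.sum(axis=1)
            side = _leading_split(Bg, two_m)
            if side is None:
                assignment[grp] = next_label
                next_label += 1
            else:
                stack.append(grp[side])
                stack.append(grp[~side])
    q = modularity(g, assignment, weighted=weighted)
    return ModulePartition(assignment=assignment, Q=q,
                           n_modules=len(np.unique(assignment)))


def graph_measures(g: ProximityGraph, weighted: bool = False) -> dict[str, float]:
    """Graph-level summary in one mode (weighted or unweighted).

    Structure-only entries (components, node count) coincide across modes
    by construction; they are reported in both for a fixed-width registry.
    """
    n = g.n
    out: dict[str, float] = {"node_count": float(n)}
    if n == 0:
        return {**out, "char_path": 0.0, "global_eff": 0.0, "n_components": 0.0,
                "largest_comp_frac": 0.0, "mean_comp_size": 0.0,
                "density": 0.0, "modularity": 0.0, "n_modules": 0.0,
                "assortativity": 0.0}
    n_comp, comp = connected_components(g.adjacency(weighted=False),
                                        directed=False)
    sizes = np.bincount(comp)
    cpl, eff = _char_path_and_efficiency(g, weighted=weighted)
    if weighted:
        density = float(2.0 * g.weights.sum() / (n * (n - 1))) if n > 1 else 0.0
    else:
        density = float(2.0 * g.m / (n * (n - 1))) if n > 1 else 0.0
    part = newman_partition(g, weighted=weighted)
    out.update({
        "char_path": cpl,
        "global_eff": eff,
        "n_components": float(n_comp),
        "largest_comp_frac": float(sizes.max() / n),
        "mean_comp_size": float(n / n_comp),
        "density": density,
        "modularity": part.Q,
        "n_modules": float(part.n_modules),
        "assortativity": _assortativity(g, weighted=weighted),
    })
    return out


def random_points_like(roi, seed=None) -> np.ndarray:
    """Matched random point set for the noise null model.

    Same count as the ROI; X and Y uniform over the ROI bounds, Z normal
    with mean/SD fitted to the ROI's Z sample.  ``seed`` may be an int or
    a Generator.
    """
    pts = roi.points.points if hasattr(roi.points, "points") else np.asarray(
        roi.points)
    n = len(pts)
    if n < 2:
        raise ValueError("ROI must contain at least 2 points to fit the null")
    rng = seed if isinstance(seed, np.random.Generator) else (
        np.random.default_rng(seed))
    lo, hi = np.asarray(roi.bounds)
    x = rng.uniform(lo[0], hi[0], size=n)
    y = rng.uniform(lo[1], hi[1], size=n)
    z_mu, z_sd = float(pts[:, 2].mean()), float(pts[:, 2].std(ddof=1))
    z = rng.normal(z_mu, z_sd, size=n) if z_sd > 0 else np.full(n, z_mu)
    return np.column_stack([x, y, z])
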