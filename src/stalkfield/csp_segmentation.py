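"""Bottom-up region growing by comparative shortest paths.

Every non-ground point is connected to its k nearest neighbors (within a
radius cap) to form a weighted graph approximating distances *along* plant
surfaces.  For each detected stem, the multi-source shortest-path distance
D_v from its seed points to every cloud point is computed; distances are
scaled by the stem diameter as

    DvN = D_v / d^(2/3)

so thicker stems reach further, and each point is assigned to the stem
minimizing DvN.  Points unreachable from every seed keep label 0 (an
optional nearest-seed Euclidean fallback can claim them instead).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from .fusion_mapping import StemSeed3D
from .pointcloud_io import PointCloud

__all__ = ["NeighborGraph", "SegmentationResult", "SegmentConfig",
           "build_graph", "transport_distances", "assign_labels", "segment"]

DEFAULT_K = 10
DEFAULT_RADIUS_CAP = 0.05   # m; below the 0.2 m plant spacing so plants do not
                            # short-circuit through air
DBH_EXPONENT = 2.0 / 3.0


@dataclass
class NeighborGraph:
    """Symmetric k-nearest-neighbor graph with Euclidean edge weights."""

    n_vertices: int
    matrix: csr_matrix          # symmetric, zero diagonal
    k: int
    radius_cap: float

    def edge_set(self):
        """Undirected edges as a set of (i, j, weight) with i < j (testing aid)."""
        coo = self.matrix.tocoo()
        return {(int(i), int(j), float(w)) for i, j, w
                in zip(coo.row, coo.col, coo.data) if i < j}


@dataclass
class SegmentationResult:
    """Per-point plant labels (0 = unassigned) with winning scaled distances."""

    label: np.ndarray           # (n,) int; label i+1 <=> seeds[i]
    dvn: np.ndarray             # (n,) float; +inf where unassigned
    seeds: List[StemSeed3D]

    def points_of(self, plant_label: int) -> np.ndarray:
        return np.flatnonzero(self.label == plant_label)

    def plant_ids(self) -> np.ndarray:
        ids = np.unique(self.label)
        return ids[ids > 0]


@dataclass
class SegmentConfig:
    """Graph and assignment parameters for :func:`segment`."""

    k: int = DEFAULT_K
    radius_cap: float = DEFAULT_RADIUS_CAP
    dbh_exponent: float = DBH_EXPONENT
    euclidean_fallback: bool = False  # assign unreachable points to the
                                      # nearest seed centroid instead of 0


def build_graph(cloud: PointCloud, k: int = DEFAULT_K,
                radius_cap: float = DEFAULT_RADIUS_CAP) -> NeighborGraph:
    """Symmetrized k-NN graph; edges longer than ``radius_cap`` are dropped."""
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(cloud)
    if n == 0:
        raise ValueError("cannot build a graph on an empty cloud")
    tree = cKDTree(cloud.xyz)
    k_eff = min(k + 1, n)
    dist, nbr = tree.query(cloud.xyz, k=k_eff)
    dist = np.atleast_2d(dist)
    nbr = np.atleast_2d(nbr)
    rows = np.repeat(np.arange(n), k_eff)
    cols = nbr.ravel()
    w = dist.ravel()
    keep = (cols != rows) & (w <= radius_cap) & np.isfinite(w)
    rows, cols, w = rows[keep], cols[keep], w[keep]
    # guard against exactly coincident points producing zero-weight edges
    w = np.maximum(w, 1e-12)
    mat = csr_matrix((w, (rows, cols)), shape=(n, n))
    mat = mat.maximum(mat.T)    # symmetrize
    return NeighborGraph(n, mat, k, radius_cap)


def transport_distances(graph: NeighborGraph,
                        seeds: Sequence[StemSeed3D]) -> np.ndarray:
    """Multi-source shortest-path distance D_v from each seed to every point.

    Returns an ``(n_seeds, n_points)`` array; unreachable entries are +inf.
    Each seed's distance is measured to the nearest member of its seed set.
    """
    seeds = list(seeds)
    if not seeds:
        raise ValueError("need at least one seed")
    out = np.empty((len(seeds), graph.n_vertices))
    for i, seed in enumerate(seeds):
        idx = seed.seed_point_indices
        if idx.min() < 0 or idx.max() >= graph.n_vertices:
            raise ValueError(f"seed {i} indexes points outside the graph")
        out[i] = dijkstra(graph.matrix, directed=False, indices=idx,
                          min_only=True)
    return out


def assign_labels(distances: np.ndarray, seeds: Sequence[StemSeed3D],
                  dbh_exponent: float = DBH_EXPONENT) -> SegmentationResult:
    """Label each point with the seed minimizing DvN = D_v / d^exponent.

    Ties break to the lowest seed id; points unreachable from every seed get
    label 0 and DvN = +inf.
    """
    seeds = list(seeds)
    distances = np.asarray(distances, dtype=np.float64)
    if distances.shape[0] != len(seeds):
        raise ValueError("distances row count must equal seed count")
    scale = np.array([s.diameter ** dbh_exponent for s in seeds])
    dvn = distances / scale[:, None]
    best = np.argmin(dvn, axis=0)               # first minimum = lowest seed id
    best_dvn = dvn[best, np.arange(dvn.shape[1])]
    label = best.astype(np.int64) + 1
    label[~np.isfinite(best_dvn)] = 0
    return SegmentationResult(label, best_dvn, seeds)


def segment(cloud: PointCloud, seeds: Sequence[StemSeed3D],
            cfg: Optional[SegmentConfig] = None) -> SegmentationResult:
    """Grow plants from stem seeds: build_graph → D_v → DvN assignment.

    Memory-lean: the per-seed distance rows are folded into running minima
    instead of materializing the full matrix when there are many points.
    """
    cfg = cfg or SegmentConfig()
    seeds = list(seeds)
    if not seeds:
        raise ValueError("segmentation needs at least one stem seed")
    graph = build_graph(cloud, cfg.k, cfg.radius_cap)
    n = graph.n_vertices
    best_dvn = np.full(n, np.inf)
    label = np.zeros(n, dtype=np.int64)
    for i, seed in enumerate(seeds):
        d = dijkstra(graph.matrix, directed=False,
                     indices=seed.seed_point_indices, min_only=True)
        dvn = d / (seed.diameter ** cfg.dbh_exponent)
        better = dvn < best_dvn      # strict: ties stay with the lower seed id
        best_dvn[better] = dvn[better]
        label[better] = i + 1
    if cfg.euclidean_fallback:
        orphan = np.flatnonzero(label == 0)
        if orphan.size:
            cent = np.array([s.centroid for s in seeds])
            scale = np.array([s.diameter ** cfg.dbh_exponent for s in seeds])
            d = np.linalg.norm(cloud.xyz[orphan, None, :] - cent[None, :, :],
                               axis=2) / scale[None, :]
            pick = np.argmin(d, axis=1)
            label[orphan] = pick + 1
            best_dvn[orphan] = d[np.arange(orphan.size), pick]
    return SegmentationResult(label, best_dvn, seeds)
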