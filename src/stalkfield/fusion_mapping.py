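"""Confidence filtering, 2D→3D mapping of detections, and direction fusion.

A detection's pixel box plus its slice window define a 3D box in the rotated
viewing frame (the box gives x and z, the window gives the y slab).  The
world points inside that box become the stem's *seed points*.  Because every
site is viewed from many directions, the same stalk is detected repeatedly;
seeds whose centroids fall within a merge radius in x-y are treated as the
same maize and only the best-confidence member is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .pointcloud_io import PointCloud
from .projection import SliceWindow, rotate_xy
from .stem_detection import StemDetection

__all__ = ["StemSeed3D", "EmptySeedError", "filter_confidence", "map_to_3d",
           "fuse_directions", "DEFAULT_MIN_CONF", "DEFAULT_MERGE_RADIUS",
           "MIN_SEED_DIAMETER"]

DEFAULT_MIN_CONF = 0.9       # keep detections with confidence strictly above
DEFAULT_MERGE_RADIUS = 0.1   # m; half the 0.2 m within-row plant spacing
MIN_SEED_DIAMETER = 0.005    # m floor on the estimated stem diameter


class EmptySeedError(ValueError):
    """A detection box contained no world points."""


@dataclass
class StemSeed3D:
    """Back-projection of one 2D stem detection into the world cloud."""

    seed_point_indices: np.ndarray     # indices into the world cloud
    centroid: Tuple[float, float, float]
    confidence: float
    diameter: float                    # m, estimated stem diameter
    source: Tuple[int, Tuple[float, float, float], Tuple[float, float, float, float]] \
        = (0, (0.0, 0.0, 0.0), (0.0, 0.0, 0.0, 0.0))  # (direction, window origin, box)

    def __post_init__(self) -> None:
        self.seed_point_indices = np.asarray(self.seed_point_indices,
                                             dtype=np.int64).ravel()
        if self.seed_point_indices.size < 1:
            raise EmptySeedError("a stem seed needs at least one point")
        if self.diameter <= 0:
            raise ValueError("seed diameter must be positive")

    @property
    def n_points(self) -> int:
        return int(self.seed_point_indices.size)


def filter_confidence(dets: Sequence[StemDetection],
                      min_conf: float = DEFAULT_MIN_CONF) -> List[StemDetection]:
    """Keep detections whose confidence is *strictly* greater than ``min_conf``."""
    if not (0.0 <= min_conf <= 1.0):
        raise ValueError("min_conf must lie in [0, 1]")
    return [d for d in dets if d.confidence > min_conf]


def map_to_3d(det: StemDetection, window: SliceWindow, world: PointCloud,
              pixel_size: Optional[float] = None,
              rotated_xyz: Optional[np.ndarray] = None,
              candidates: Optional[np.ndarray] = None) -> StemSeed3D:
    """Map a 2D detection back to 3D seed points in the world cloud.

    The pixel box becomes a meter box in the rotated frame (the window
    supplies the y slab); membership is evaluated on the rotated coordinates
    and reported as indices into the *unrotated* world cloud.  ``rotated_xyz``
    and ``candidates`` let callers reuse precomputed rotations of the world
    cloud / a candidate index subset (e.g. the window's own points).

    Raises :class:`EmptySeedError` when no world point falls in the box.
    """
    if pixel_size is None:
        pixel_size = getattr(det.image_ref, "pixel_size", None)
        if pixel_size is None:
            raise ValueError("pass pixel_size= when the detection has no image ref")
    x0, y0, z0 = window.origin
    box = det.box
    lo = np.array([x0 + box.x_min * pixel_size, y0, z0 + box.z_min * pixel_size])
    hi = np.array([x0 + box.x_max * pixel_size, y0 + window.depth_y,
                   z0 + box.z_max * pixel_size])
    if candidates is None:
        candidates = np.arange(len(world))
    if rotated_xyz is None:
        rotated_xyz = rotate_xy(world.xyz, window.direction.angle,
                                window.rotation_center)
    pts = rotated_xyz[candidates]
    eps = 1e-9
    inside = np.all((pts >= lo - eps) & (pts <= hi + eps), axis=1)
    seed_idx = np.asarray(candidates)[inside]
    if seed_idx.size == 0:
        raise EmptySeedError(f"no world point inside mapped box {lo}..{hi}")
    world_pts = world.xyz[seed_idx]
    centroid = tuple(world_pts.mean(axis=0))
    spread = world_pts[:, :2].max(axis=0) - world_pts[:, :2].min(axis=0)
    diameter = max(float(spread.max()), MIN_SEED_DIAMETER)
    return StemSeed3D(
        seed_point_indices=seed_idx,
        centroid=centroid,
        confidence=det.confidence,
        diameter=diameter,
        source=(window.direction.index, window.origin,
                (box.x_min, box.z_min, box.x_max, box.z_max)),
    )


def fuse_directions(seeds: Sequence[StemSeed3D],
                    merge_radius: float = DEFAULT_MERGE_RADIUS,
                    world: Optional[PointCloud] = None,
                    stalk_radius: float = 0.05) -> List[StemSeed3D]:
    """Keep one seed per maize across viewing directions.

    Seeds are grouped by single-linkage clustering of their centroids in x-y
    at ``merge_radius``; each group keeps its best-confidence member (ties:
    more seed points, then lower direction index, then lower x).  Two pieces
    of information are pooled across the group rather than taken from the
    single kept member, because one thin slice through a stem edge misreads
    them badly while the ensemble over many viewing directions is robust:

    * the stem diameter becomes the median of the members' estimates;
    * when ``world`` is given, the seed point set becomes the union of the
      members' points within ``stalk_radius`` (x-y) of the kept centroid —
      the stalk column seen from all directions, rather than one 16 mm
      sliver of it, which keeps path distances from the plant top short.

    The result is ordered by centroid (x, y) for determinism.
    """
    if merge_radius <= 0:
        raise ValueError("merge_radius must be positive")
    seeds = list(seeds)
    if not seeds:
        return []
    xy = np.array([[s.centroid[0], s.centroid[1]] for s in seeds])
    tree = cKDTree(xy)
    pairs = tree.query_pairs(r=merge_radius, output_type="ndarray")
    n = len(seeds)
    if len(pairs):
        adj = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
                         shape=(n, n))
        _, comp = connected_components(adj, directed=False)
    else:
        comp = np.arange(n)
    best: dict = {}
    diameters: dict = {}
    members: dict = {}
    for i, s in enumerate(seeds):
        key = int(comp[i])
        rank = (-s.confidence, -s.n_points, s.source[0], s.centroid[0], s.centroid[1])
        diameters.setdefault(key, []).append(s.diameter)
        members.setdefault(key, []).append(s)
        if key not in best or rank < best[key][0]:
            best[key] = (rank, s)
    kept = []
    for key, (_, s) in best.items():
        dia = max(float(np.median(diameters[key])), MIN_SEED_DIAMETER)
        idx = s.seed_point_indices
        if world is not None:
            pool = np.unique(np.concatenate(
                [m.seed_point_indices for m in members[key]]))
            dxy = world.xyz[pool, :2] - np.array(s.centroid[:2])
            near = np.hypot(dxy[:, 0], dxy[:, 1]) <= stalk_radius
            if near.any():
                idx = pool[near]
        kept.append(replace(s, diameter=dia, seed_point_indices=idx))
    kept.sort(key=lambda s: (s.centroid[0], s.centroid[1]))
    return kept
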