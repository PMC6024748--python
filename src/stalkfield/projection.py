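"""Rotation, slicing and depth-image compression of point clouds.

A cloud is viewed from ``n_views`` azimuthal directions (default 32, i.e.
360°/32 apart) by rotating it about the vertical axis around its x-y
centroid.  In each rotated frame the cloud is tiled into fixed 3D windows —
1.024 m x 1.024 m in x and z, a thin stride in viewing depth y (0.016 m for
testing, 0.256 m for training regions of interest) — and each window's
points are compressed into a depth image whose pixel intensity encodes the
nearest point's depth (nearest surface brightest).  With the default 0.004 m
pixel the 1.024 m field is an exact 256 x 256 grid.

Image convention: row 0 is the *bottom* of the window (lowest z), columns
run along +x of the rotated frame.  PNG export flips rows so that up is up.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .pointcloud_io import PointCloud
from .stem_detection import Box2D
from .synth_field import PlantTruth

__all__ = [
    "ViewDirection", "SliceWindow", "DepthImage", "TrainingSample",
    "rotate_cloud", "slice_windows", "rasterize", "make_training_samples",
    "DEFAULT_FIELD", "DEFAULT_TEST_DEPTH", "DEFAULT_TRAIN_DEPTH", "DEFAULT_PIXEL",
]

DEFAULT_FIELD = 1.024        # m, window size in x and z
DEFAULT_TEST_DEPTH = 0.016   # m, slice depth when detecting stems
DEFAULT_TRAIN_DEPTH = 0.256  # m, ROI depth when exporting training samples
DEFAULT_PIXEL = 0.004        # m per pixel -> 256 px across the 1.024 m field

_MIN_INTENSITY = 1.0 / 255.0  # occupied pixels never rasterize to exactly 0


@dataclass(frozen=True)
class ViewDirection:
    """One of ``n_views`` azimuthal viewing directions."""

    index: int
    n_views: int = 32

    def __post_init__(self) -> None:
        if not (0 <= self.index < self.n_views):
            raise ValueError(f"index {self.index} outside [0, {self.n_views})")

    @property
    def angle(self) -> float:
        """Rotation angle in radians: index * 2*pi / n_views."""
        return self.index * 2.0 * np.pi / self.n_views


@dataclass(frozen=True)
class SliceWindow:
    """An axis-aligned 3D box in a rotated viewing frame."""

    direction: ViewDirection
    origin: Tuple[float, float, float]          # (x0, y0, z0), rotated frame
    field_x: float = DEFAULT_FIELD
    field_z: float = DEFAULT_FIELD
    depth_y: float = DEFAULT_TEST_DEPTH
    rotation_center: Tuple[float, float] = (0.0, 0.0)  # x-y pivot in world frame

    def __post_init__(self) -> None:
        if min(self.field_x, self.field_z, self.depth_y) <= 0:
            raise ValueError("window dimensions must be positive")

    def contains(self, xyz: np.ndarray, atol: float = 1e-9) -> np.ndarray:
        x0, y0, z0 = self.origin
        xyz = np.asarray(xyz, dtype=np.float64).reshape(-1, 3)
        return ((xyz[:, 0] >= x0 - atol) & (xyz[:, 0] <= x0 + self.field_x + atol)
                & (xyz[:, 1] >= y0 - atol) & (xyz[:, 1] <= y0 + self.depth_y + atol)
                & (xyz[:, 2] >= z0 - atol) & (xyz[:, 2] <= z0 + self.field_z + atol))


@dataclass
class DepthImage:
    """Depth raster of one slice window (rows = z from the bottom, cols = x)."""

    pixels: np.ndarray          # (rows, cols) float in [0, 1]; 0 <=> empty
    pixel_size: float
    window: SliceWindow

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape

    def pixel_center_meters(self, col, row) -> Tuple[np.ndarray, np.ndarray]:
        """Rotated-frame (x, z) of pixel centers."""
        x0, _, z0 = self.window.origin
        return (x0 + (np.asarray(col) + 0.5) * self.pixel_size,
                z0 + (np.asarray(row) + 0.5) * self.pixel_size)

    def meters_to_pixel(self, x, z) -> Tuple[np.ndarray, np.ndarray]:
        """Rotated-frame coordinates -> (col, row) pixel indices."""
        x0, _, z0 = self.window.origin
        col = np.floor((np.asarray(x) - x0) / self.pixel_size).astype(np.int64)
        row = np.floor((np.asarray(z) - z0) / self.pixel_size).astype(np.int64)
        return col, row

    def to_uint8(self) -> np.ndarray:
        """8-bit grayscale with up pointing up (for PNG export)."""
        return np.flipud(np.round(self.pixels * 255).astype(np.uint8))


@dataclass
class TrainingSample:
    """One plant x view: depth image with plant and stem boxes in pixels."""

    image: DepthImage
    plant_box: Box2D
    stem_box: Box2D
    plant_id: int

    def __post_init__(self) -> None:
        p, s = self.plant_box, self.stem_box
        if not (s.x_min >= p.x_min and s.z_min >= p.z_min
                and s.x_max <= p.x_max and s.z_max <= p.z_max):
            raise ValueError("stem_box must lie inside plant_box")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _frame_name(direction: ViewDirection, center: Tuple[float, float]) -> str:
    return f"view:{direction.index}/{direction.n_views}@{center[0]!r},{center[1]!r}"


def rotation_center_of(cloud: PointCloud) -> Tuple[float, float]:
    """Default rotation pivot: the cloud's x-y centroid."""
    return (float(cloud.xyz[:, 0].mean()), float(cloud.xyz[:, 1].mean()))


def rotate_xy(xyz: np.ndarray, angle: float,
              center: Tuple[float, float]) -> np.ndarray:
    """Rotate points about the vertical axis through ``center``; z unchanged."""
    c, s = np.cos(angle), np.sin(angle)
    out = np.asarray(xyz, dtype=np.float64).reshape(-1, 3).copy()
    dx = out[:, 0] - center[0]
    dy = out[:, 1] - center[1]
    out[:, 0] = center[0] + c * dx - s * dy
    out[:, 1] = center[1] + s * dx + c * dy
    return out


def rotate_cloud(cloud: PointCloud, direction: ViewDirection,
                 center: Optional[Tuple[float, float]] = None) -> PointCloud:
    """View the cloud from ``direction``: azimuthal rotation about its centroid.

    z values are exactly preserved; ``source_frame`` records the direction and
    the pivot so detections can be mapped back to the world frame.
    """
    if center is None:
        center = rotation_center_of(cloud)
    xyz = rotate_xy(cloud.xyz, direction.angle, center)
    lab = None if cloud.plant_label is None else cloud.plant_label.copy()
    return PointCloud(xyz, lab, source_frame=_frame_name(direction, center))


def slice_windows(cloud: PointCloud, field: float = DEFAULT_FIELD,
                  depth: float = DEFAULT_TEST_DEPTH,
                  direction: ViewDirection = ViewDirection(0, 1),
                  rotation_center: Tuple[float, float] = (0.0, 0.0),
                  ) -> List[Tuple[SliceWindow, np.ndarray]]:
    """Tile the (rotated) cloud into windows; every point lands in exactly one.

    Windows stride by ``field`` in x and by ``depth`` in y from the cloud's
    minimum corner; all share the cloud's minimum z with height ``field``.
    Empty windows are omitted.  Returns ``(window, point_indices)`` pairs.
    """
    if field <= 0 or depth <= 0:
        raise ValueError("field and depth must be positive")
    if len(cloud) == 0:
        return []
    xyz = cloud.xyz
    x_min, y_min, z_min = xyz[:, 0].min(), xyz[:, 1].min(), xyz[:, 2].min()
    ix = np.floor((xyz[:, 0] - x_min) / field).astype(np.int64)
    iy = np.floor((xyz[:, 1] - y_min) / depth).astype(np.int64)
    # points exactly on the top boundary belong to the last window
    nx = max(int(ix.max()) + 1, 1)
    ny = max(int(iy.max()) + 1, 1)
    key = ix * ny + iy
    order = np.argsort(key, kind="stable")
    sorted_keys = key[order]
    boundaries = np.flatnonzero(np.diff(sorted_keys)) + 1
    groups = np.split(order, boundaries)
    uniq = sorted_keys[np.concatenate([[0], boundaries])] if len(order) else []
    out: List[Tuple[SliceWindow, np.ndarray]] = []
    for k, idx in zip(uniq, groups):
        wx, wy = divmod(int(k), ny)
        window = SliceWindow(
            direction=direction,
            origin=(x_min + wx * field, y_min + wy * depth, z_min),
            field_x=field, field_z=field, depth_y=depth,
            rotation_center=rotation_center,
        )
        out.append((window, idx))
    return out


def rasterize(cloud: PointCloud, window: SliceWindow,
              pixel_size: float = DEFAULT_PIXEL) -> DepthImage:
    """Compress one window's points into a depth image.

    Each point falls into pixel ``(floor((x-x0)/px), floor((z-z0)/px))``; the
    pixel takes intensity ``1 - (y_nearest - y0) / depth_y`` where y_nearest
    is the smallest y among its points, floored at 1/255 so that zero remains
    reserved for empty pixels.  All points must lie inside the window.
    """
    x0, y0, z0 = window.origin
    cols = int(round(window.field_x / pixel_size))
    rows = int(round(window.field_z / pixel_size))
    xyz = cloud.xyz
    if len(cloud):
        if not window.contains(xyz).all():
            raise ValueError("rasterize: points outside the window; pre-filter them")
        col = np.minimum(np.floor((xyz[:, 0] - x0) / pixel_size).astype(np.int64),
                         cols - 1)
        row = np.minimum(np.floor((xyz[:, 2] - z0) / pixel_size).astype(np.int64),
                         rows - 1)
        col = np.maximum(col, 0)
        row = np.maximum(row, 0)
        flat = row * cols + col
        nearest = np.full(rows * cols, np.inf)
        np.minimum.at(nearest, flat, xyz[:, 1])
        img = np.zeros(rows * cols, dtype=np.float64)
        occ = np.isfinite(nearest)
        img[occ] = np.clip(1.0 - (nearest[occ] - y0) / window.depth_y,
                           _MIN_INTENSITY, 1.0)
        pixels = img.reshape(rows, cols)
    else:
        pixels = np.zeros((rows, cols), dtype=np.float64)
    return DepthImage(pixels, pixel_size, window)


def _pixel_bbox(col: np.ndarray, row: np.ndarray) -> Box2D:
    return Box2D(float(col.min()), float(row.min()),
                 float(col.max()) + 1.0, float(row.max()) + 1.0)


def make_training_samples(cloud: PointCloud, truths: Sequence[PlantTruth],
                          n_views: int = 32,
                          field: float = DEFAULT_FIELD,
                          depth: float = DEFAULT_TRAIN_DEPTH,
                          pixel_size: float = DEFAULT_PIXEL,
                          stem_fraction: float = 1.0 / 3.0,
                          ) -> List[TrainingSample]:
    """Per plant x view: an ROI depth image with plant and stem boxes.

    For every plant the cloud is viewed from ``n_views`` directions; in each
    rotated frame a ``field x field x depth`` ROI is centered on the plant's
    points (its z floor at the plant's lowest point) and rasterized with the
    full background.  The stem box bounds the plant's points whose height
    above its own base is below ``stem_fraction`` of the plant height.
    Plants with no stem points are skipped with a warning.
    """
    if cloud.plant_label is None:
        raise ValueError("make_training_samples needs a labeled cloud")
    labels = cloud.plant_label
    center = rotation_center_of(cloud)
    by_plant = {t.plant_id: np.flatnonzero(labels == t.plant_id) for t in truths}
    for t in truths:
        if by_plant[t.plant_id].size == 0:
            raise ValueError(f"plant {t.plant_id} has no points in the cloud")
    samples: List[TrainingSample] = []
    for view in range(n_views):
        direction = ViewDirection(view, n_views)
        rot = rotate_xy(cloud.xyz, direction.angle, center)
        for t in truths:
            idx = by_plant[t.plant_id]
            pts = rot[idx]
            z_base = pts[:, 2].min()
            stem_mask = pts[:, 2] - z_base < stem_fraction * t.height
            if not stem_mask.any():
                warnings.warn(f"plant {t.plant_id}: no stem points below "
                              f"{stem_fraction:.3g} of its height; sample skipped")
                continue
            cx, cy = pts[:, 0].mean(), pts[:, 1].mean()
            window = SliceWindow(
                direction=direction,
                origin=(cx - field / 2.0, cy - depth / 2.0, z_base),
                field_x=field, field_z=field, depth_y=depth,
                rotation_center=center,
            )
            roi = window.contains(rot)
            image = rasterize(PointCloud(rot[roi]), window, pixel_size)
            in_roi = roi[idx]
            if not (stem_mask & in_roi).any():
                warnings.warn(f"plant {t.plant_id}: stem points fell outside "
                              f"the ROI in view {view}; sample skipped")
                continue
            p_col, p_row = image.meters_to_pixel(pts[in_roi, 0], pts[in_roi, 2])
            rows, cols = image.shape
            p_col = np.clip(p_col, 0, cols - 1)
            p_row = np.clip(p_row, 0, rows - 1)
            plant_box = _pixel_bbox(p_col, p_row)
            s_sel = stem_mask & in_roi
            s_col, s_row = image.meters_to_pixel(pts[s_sel, 0], pts[s_sel, 2])
            s_col = np.clip(s_col, 0, cols - 1)
            s_row = np.clip(s_row, 0, rows - 1)
            stem_box = _pixel_bbox(s_col, s_row)
            samples.append(TrainingSample(image, plant_box, stem_box, t.plant_id))
    return samples
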