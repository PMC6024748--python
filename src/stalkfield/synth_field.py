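"""Synthetic maize-field point clouds with known per-plant ground truth.

The generator emulates a young (elongation-stage) maize field scanned by a
terrestrial laser scanner: plants on a 0.5 m (row) x 0.2 m (within-row) grid,
a ridged ground surface with micro-topography (plants sit on ridge tops), and
per-plant geometry consisting of

* a near-vertical stalk cylinder from the base to ~60 % of plant height,
* a rolled-whorl leaf — a slender tapering cone no wider than the stalk —
  continuing from the stalk top to the full plant height (the newest leaf of
  young maize points straight up), and
* arcing strap leaves attached at nodes along the stalk, modeled as tapered
  ribbons along quadratic Bezier curves.

Surfaces are sampled at a target inter-point spacing with Gaussian noise and
random dropout standing in for occlusion.  Everything is driven by one seeded
generator, so a fixed seed reproduces the field bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import List, Optional, Tuple

import numpy as np

from .pointcloud_io import PointCloud

__all__ = ["FieldSpec", "PlantTruth", "generate_plant", "generate_field", "PRESETS"]

# Site presets: grid dimensions sized so that n_plants / area reproduces the
# published site densities (sparse 2.69, moderate 6.19, dense 8.96 plants/m²,
# training 3.35) within a few percent, with the published plant counts exact.
#   name: (n_rows, n_cols, n_plants, height_range)
PRESETS = {
    "sparse":   (10, 23, 62,  (0.13, 0.49)),
    "moderate": (7,  16, 71,  (0.29, 0.69)),
    "dense":    (7,  14, 88,  (0.14, 0.73)),
    "training": (20, 50, 337, (0.09, 0.68)),
}


@dataclass
class FieldSpec:
    """Geometry and sampling parameters of one synthetic field."""

    row_spacing: float = 0.5          # m between rows (x)
    plant_spacing: float = 0.2        # m within a row (y)
    density_preset: str = "moderate"
    n_rows: int = 7
    n_cols: int = 16
    n_plants: Optional[int] = None    # default: preset count
    height_range: Tuple[float, float] = (0.29, 0.69)
    leaf_count_range: Tuple[int, int] = (5, 9)
    point_spacing: float = 0.005      # m target spacing on plant surfaces
    ground_point_spacing: float = 0.015  # m grid spacing of ground returns
    noise_sd: float = 0.002           # m Gaussian jitter per coordinate
    dropout_rate: float = 0.15        # fraction of surface points dropped
    ground_relief_amp: float = 0.03   # m ridge amplitude (plants on ridge tops;
                                      # ridge-to-furrow drop ~2x this stays below
                                      # the 0.1 m ground cut, so the cut bites a
                                      # few cm into each plant's base)
    stem_diameter_range: Tuple[float, float] = (0.01, 0.03)
    stem_lean_max: float = 0.012      # rad, max stalk tilt from vertical
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.row_spacing <= 0 or self.plant_spacing <= 0:
            raise ValueError("spacings must be positive")
        if not (self.height_range[0] < self.height_range[1]):
            raise ValueError("height_range must satisfy min < max")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.point_spacing <= 0 or self.ground_point_spacing <= 0:
            raise ValueError("point spacings must be positive")
        d_lo, d_hi = self.stem_diameter_range
        if not (0 < d_lo <= d_hi):
            raise ValueError("stem_diameter_range must be positive")

    @classmethod
    def preset(cls, name: str, rng_seed: int = 0, **overrides) -> "FieldSpec":
        """Spec for a named site preset (sparse/moderate/dense/training)."""
        if name not in PRESETS:
            raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
        n_rows, n_cols, n_plants, h_range = PRESETS[name]
        base = cls(density_preset=name, n_rows=n_rows, n_cols=n_cols,
                   n_plants=n_plants, height_range=h_range, rng_seed=rng_seed)
        return replace(base, **overrides) if overrides else base

    @property
    def area(self) -> float:
        """Field area in m² (one grid cell per planting site)."""
        return self.n_rows * self.row_spacing * self.n_cols * self.plant_spacing

    @property
    def plant_count(self) -> int:
        if self.n_plants is not None:
            return self.n_plants
        return PRESETS.get(self.density_preset, (0, 0, 0, None))[2]


@dataclass
class PlantTruth:
    """Ground truth for one plant."""

    plant_id: int
    stem_base: Tuple[float, float]    # (x, y) m
    height: float                     # m above the stem base
    stem_diameter: float              # m
    base_z: float = 0.0               # ground elevation under the stem

    def __post_init__(self) -> None:
        if self.plant_id < 1:
            raise ValueError("plant_id must be >= 1")
        if self.height <= 0 or self.stem_diameter <= 0:
            raise ValueError("height and stem_diameter must be positive")


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _surface_count(area: float, spacing: float) -> int:
    return max(1, int(round(area / spacing**2)))


def _ground_elevation(x: np.ndarray, y: np.ndarray, spec: FieldSpec,
                      phases: Tuple[float, float]) -> np.ndarray:
    """Ridge-and-furrow relief plus low-frequency micro-topography.

    Ridges run along the rows (constant x), with crests at the row lines so
    plants sit on top of the ridge; amplitude is ``ground_relief_amp``.
    """
    a = spec.ground_relief_amp
    ridge = a * np.cos(2.0 * np.pi * x / spec.row_spacing)
    micro = 0.3 * a * np.sin(2.0 * np.pi * (0.21 * x) + phases[0]) \
        * np.sin(2.0 * np.pi * (0.17 * y) + phases[1])
    return ridge + micro


def generate_plant(truth: PlantTruth, spec: FieldSpec,
                   rng: np.random.Generator) -> PointCloud:
    """Sample one maize plant, labeled ``truth.plant_id``, in field coordinates.

    The stem base sits at ``(truth.stem_base, truth.base_z)``; the plant's top
    reaches ``base_z + height`` up to noise and sampling shortfall.
    """
    ps = spec.point_spacing
    h = truth.height
    r_stem = truth.stem_diameter / 2.0
    stem_top = 0.6 * h
    bx, by = truth.stem_base

    # leaning stalk axis: horizontal offset grows linearly with z
    lean = rng.uniform(0.0, spec.stem_lean_max)
    lean_az = rng.uniform(0.0, 2.0 * np.pi)
    lean_dir = np.array([math.cos(lean_az), math.sin(lean_az)])

    def axis_xy(z: np.ndarray) -> np.ndarray:
        return np.array([bx, by]) + np.tan(lean) * z[:, None] * lean_dir

    chunks = []

    # stalk cylinder
    n = _surface_count(np.pi * truth.stem_diameter * stem_top, ps)
    z = rng.uniform(0.0, stem_top, n)
    th = rng.uniform(0.0, 2.0 * np.pi, n)
    xy = axis_xy(z) + r_stem * np.column_stack([np.cos(th), np.sin(th)])
    chunks.append(np.column_stack([xy, z]))

    # rolled-whorl leaf: tapering near-vertical cone from stalk top to height
    r_whorl = 0.8 * r_stem
    n = _surface_count(np.pi * 2 * r_whorl * (h - stem_top), ps)
    z = rng.uniform(stem_top, h, n)
    frac = (z - stem_top) / max(h - stem_top, 1e-9)
    rr = r_whorl * (1.0 - frac) ** 0.7
    th = rng.uniform(0.0, 2.0 * np.pi, n)
    xy = axis_xy(z) + rr[:, None] * np.column_stack([np.cos(th), np.sin(th)])
    chunks.append(np.column_stack([xy, z]))

    # strap leaves: tapered ribbons along quadratic Bezier arcs
    n_leaves = int(rng.integers(spec.leaf_count_range[0],
                                spec.leaf_count_range[1] + 1))
    rank_az = rng.uniform(0.0, 2.0 * np.pi)  # leaves alternate in two ranks
    if n_leaves > 0:
        nodes = np.linspace(0.25 * stem_top, stem_top, n_leaves) \
            + rng.uniform(-0.05, 0.05, n_leaves) * stem_top
        nodes = np.clip(nodes, 0.02 * h, stem_top)
        for j in range(n_leaves):
            za = float(nodes[j])
            az = rank_az + (j % 2) * np.pi + rng.uniform(-0.5, 0.5)
            length = float(np.clip(rng.uniform(0.5, 0.9) * h, 0.05, 0.35))
            width = min(rng.uniform(0.015, 0.04), 0.3 * length)
            theta0 = rng.uniform(np.deg2rad(10), np.deg2rad(30))
            e_r = np.array([math.cos(az), math.sin(az)])
            p0 = np.array([*(axis_xy(np.array([za]))[0] + r_stem * e_r), za])
            d0 = np.array([math.sin(theta0) * e_r[0], math.sin(theta0) * e_r[1],
                           math.cos(theta0)])
            p1 = p0 + 0.5 * length * d0
            p1[2] = min(p1[2], 0.97 * h)          # whorl stays the highest organ
            reach = rng.uniform(0.5, 0.75) * length
            rise = rng.uniform(0.2, 0.45) * length
            p2 = p0 + np.array([reach * e_r[0], reach * e_r[1], min(rise, 0.9 * h - za)])
            n = _surface_count(0.6 * length * width, ps)
            t = rng.uniform(0.0, 1.0, n)
            om = 1.0 - t
            curve = (om**2)[:, None] * p0 + (2 * t * om)[:, None] * p1 \
                + (t**2)[:, None] * p2
            tang = 2 * om[:, None] * (p1 - p0) + 2 * t[:, None] * (p2 - p1)
            side = np.cross(tang, np.array([0.0, 0.0, 1.0]))
            norm = np.linalg.norm(side, axis=1, keepdims=True)
            norm[norm < 1e-9] = 1.0
            side /= norm
            lateral = rng.uniform(-0.5, 0.5, n) * (width * (1.0 - t**1.5))
            chunks.append(curve + side * lateral[:, None])

    pts = np.vstack(chunks)
    if spec.noise_sd > 0:
        pts = pts + rng.normal(0.0, spec.noise_sd, pts.shape)
    if spec.dropout_rate > 0:
        pts = pts[rng.random(len(pts)) > spec.dropout_rate]
    pts[:, 2] += truth.base_z
    labels = np.full(len(pts), truth.plant_id, dtype=np.int64)
    return PointCloud(pts, labels)


def generate_field(spec: FieldSpec) -> Tuple[PointCloud, List[PlantTruth]]:
    """Generate a labeled field cloud (ground label 0) plus its truth list.

    Plants occupy a random subset of the row/plant grid so that the plant
    count matches the preset (or ``spec.n_plants``); each occupied site gets a
    small positional jitter.  The ground surface covers the full field extent.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n_sites = spec.n_rows * spec.n_cols
    n_plants = spec.plant_count
    if n_sites == 0 or not n_plants:
        raise ValueError("degenerate grid: field would contain no plants")
    if n_plants > n_sites:
        raise ValueError(f"{n_plants} plants do not fit on {n_sites} grid sites")

    phases = tuple(rng.uniform(0.0, 2.0 * np.pi, 2))
    occupied = np.sort(rng.choice(n_sites, size=n_plants, replace=False))

    d_lo, d_hi = spec.stem_diameter_range
    truths: List[PlantTruth] = []
    clouds = []
    for pid, site in enumerate(occupied, start=1):
        i, j = divmod(int(site), spec.n_cols)
        x = i * spec.row_spacing + rng.uniform(-0.015, 0.015)
        y = j * spec.plant_spacing + rng.uniform(-0.015, 0.015)
        height = rng.uniform(*spec.height_range)
        diameter = rng.uniform(d_lo, d_hi)
        base_z = float(_ground_elevation(np.array([x]), np.array([y]), spec, phases)[0])
        truth = PlantTruth(pid, (x, y), height, diameter, base_z=base_z)
        truths.append(truth)
        clouds.append(generate_plant(truth, spec, rng))

    # ground: jittered grid over the field extent (half a cell beyond sites)
    x_lo = -spec.row_spacing / 2.0
    x_hi = (spec.n_rows - 0.5) * spec.row_spacing
    y_lo = -spec.plant_spacing / 2.0
    y_hi = (spec.n_cols - 0.5) * spec.plant_spacing
    gs = spec.ground_point_spacing
    gx = np.arange(x_lo, x_hi, gs)
    gy = np.arange(y_lo, y_hi, gs)
    gxx, gyy = np.meshgrid(gx, gy, indexing="ij")
    gxx = gxx.ravel() + rng.uniform(-gs / 2, gs / 2, gxx.size)
    gyy = gyy.ravel() + rng.uniform(-gs / 2, gs / 2, gyy.size)
    gzz = _ground_elevation(gxx, gyy, spec, phases)
    ground = np.column_stack([gxx, gyy, gzz])
    if spec.noise_sd > 0:
        ground = ground + rng.normal(0.0, spec.noise_sd, ground.shape)
    if spec.dropout_rate > 0:
        ground = ground[rng.random(len(ground)) > spec.dropout_rate]

    xyz = np.vstack([ground] + [c.xyz for c in clouds])
    labels = np.concatenate([np.zeros(len(ground), dtype=np.int64)]
                            + [c.plant_label for c in clouds])
    return PointCloud(xyz, labels), truths


def truths_to_frame(truths: List[PlantTruth]):
    """Truth list as a pandas DataFrame (plant_id, x, y, height, diameter)."""
    import pandas as pd

    return pd.DataFrame({
        "plant_id": [t.plant_id for t in truths],
        "x": [t.stem_base[0] for t in truths],
        "y": [t.stem_base[1] for t in truths],
        "height": [t.height for t in truths],
        "diameter": [t.stem_diameter for t in truths],
        "base_z": [t.base_z for t in truths],
    })
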