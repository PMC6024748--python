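"""End-to-end orchestration: ground filter → multi-view stem detection →
seed fusion → comparative-shortest-path growth → traits and evaluation.

All of the method's constants live in :class:`PipelineConfig` (32 views,
1.024 m field, 0.016 m test slice depth, 0.004 m pixels, the strict 0.9
confidence gate, the 0.1 m ground threshold, ...), round-trip through YAML,
and can be overridden per run.  With the baseline detector the whole run is
deterministic for a fixed input cloud.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import yaml

from .csp_segmentation import SegmentConfig, SegmentationResult, segment
from .evaluation_traits import EvalReport, evaluate_segmentation, plant_height
from .fusion_mapping import StemSeed3D, EmptySeedError, filter_confidence, \
    fuse_directions, map_to_3d
from .ground_filter import fit_ground, remove_ground
from .pointcloud_io import PointCloud, read_cloud, write_cloud
from .projection import ViewDirection, rasterize, rotate_xy, rotation_center_of, \
    slice_windows
from .stem_detection import BaselineDetector, detect

__all__ = ["PipelineConfig", "NoStemsDetectedError", "run_pipeline",
           "detect_stem_seeds"]

log = logging.getLogger("stalkfield")


class NoStemsDetectedError(RuntimeError):
    """The detection/fusion stages produced no stem seeds."""


@dataclass
class PipelineConfig:
    """Every tunable constant of the segmentation method, with the published
    defaults."""

    n_views: int = 32
    field: float = 1.024            # m, window size in x and z
    test_depth: float = 0.016       # m, slice depth for detection
    train_depth: float = 0.256      # m, ROI depth for training samples
    pixel_size: float = 0.004       # m per pixel (256 px field)
    min_conf: float = 0.9           # keep detections strictly above this
    merge_radius: float = 0.1       # m, same-maize clustering radius
    ground_threshold: float = 0.1   # m, global ground cut
    ground_cell: float = 0.25       # m, ground-model cell size
    k: int = 10                     # k-NN graph degree
    radius_cap: float = 0.05        # m, max graph edge length
    stem_fraction: float = 1.0 / 3.0  # training stem label: z < fraction * H
    backend: str = "baseline"
    min_window_points: int = 10     # skip windows too sparse to hold a stem
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_views", "field", "test_depth", "train_depth",
                     "pixel_size", "merge_radius", "ground_threshold",
                     "ground_cell", "k", "radius_cap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.stem_fraction < 1.0):
            raise ValueError("stem_fraction must lie in (0, 1)")
        if not (0.0 <= self.min_conf <= 1.0):
            raise ValueError("min_conf must lie in [0, 1]")

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        return cls(**data)


def detect_stem_seeds(cloud: PointCloud, config: PipelineConfig
                      ) -> List[StemSeed3D]:
    """Multi-view detection: rotate, slice, rasterize, detect, gate, map.

    ``cloud`` must already be ground-filtered.  Returns the raw (unfused)
    seed list across all viewing directions.
    """
    backend = BaselineDetector() if config.backend == "baseline" else config.backend
    center = rotation_center_of(cloud)
    seeds: List[StemSeed3D] = []
    for view in range(config.n_views):
        direction = ViewDirection(view, config.n_views)
        rot = rotate_xy(cloud.xyz, direction.angle, center)
        rot_cloud = PointCloud(rot)
        windows = slice_windows(rot_cloud, config.field, config.test_depth,
                                direction=direction, rotation_center=center)
        kept = 0
        for window, idx in windows:
            if idx.size < config.min_window_points:
                continue
            image = rasterize(PointCloud(rot[idx]), window, config.pixel_size)
            dets = filter_confidence(detect(image, backend), config.min_conf)
            for det in dets:
                try:
                    seeds.append(map_to_3d(det, window, cloud,
                                           pixel_size=config.pixel_size,
                                           rotated_xyz=None if idx is None else rot,
                                           candidates=idx))
                    kept += 1
                except EmptySeedError:
                    log.warning("direction %d: detection mapped to empty box; "
                                "dropped", view)
        log.info("direction %2d/%d: %d windows, %d confident stems",
                 view, config.n_views, len(windows), kept)
    return seeds


def run_pipeline(cloud: Union[PointCloud, str, Path],
                 config: Optional[PipelineConfig] = None,
                 outdir: Optional[Union[str, Path]] = None,
                 ) -> Tuple[SegmentationResult, Optional[EvalReport], Optional[Path]]:
    """Segment every plant in a cloud and (when labels exist) evaluate.

    Returns the segmentation over the ground-filtered cloud, an evaluation
    report when the input carries reference plant labels, and the artifact
    directory (when requested).  Automatic plant heights are the vertical
    extent of each segment; reference heights are the vertical extent of each
    labeled plant *before* the ground cut, which reproduces the cut-induced
    height underestimation of field practice.
    """
    config = config or PipelineConfig()
    if not isinstance(cloud, PointCloud):
        cloud = read_cloud(cloud)
    if len(cloud) == 0:
        raise ValueError("empty input cloud")
    t0 = time.perf_counter()

    model = fit_ground(cloud, config.ground_cell, config.ground_threshold)
    filtered, n_removed = remove_ground(cloud, model)
    log.info("ground filter: removed %d of %d points (cell %.2f m, cut %.2f m)",
             n_removed, len(cloud), config.ground_cell, config.ground_threshold)
    if len(filtered) == 0:
        raise NoStemsDetectedError("no stems detected: every point lies within "
                                   "the ground threshold")

    raw_seeds = detect_stem_seeds(filtered, config)
    fused = fuse_directions(raw_seeds, config.merge_radius, world=filtered)
    log.info("fusion: %d raw seeds -> %d stems", len(raw_seeds), len(fused))
    if not fused:
        raise NoStemsDetectedError(
            f"no stems detected: {len(raw_seeds)} raw detections survived the "
            f"{config.min_conf:.0%} gate across {config.n_views} directions")

    seg = segment(filtered, fused, SegmentConfig(config.k, config.radius_cap))

    auto_heights: Dict[int, float] = {}
    for pid in seg.plant_ids():
        auto_heights[int(pid)] = plant_height(filtered.xyz[seg.label == pid])

    report: Optional[EvalReport] = None
    ref = filtered.labels
    if ref.any():
        ref_heights = {int(rid): plant_height(cloud.xyz[cloud.labels == rid])
                       for rid in np.unique(ref[ref > 0])}
        report = evaluate_segmentation(seg.label, ref, auto_heights, ref_heights)
        log.info("evaluation: TP=%d FP=%d FN=%d r=%.2f p=%.2f F=%.2f",
                 report.counts.tp, report.counts.fp, report.counts.fn,
                 report.r, report.p, report.f)

    out_path: Optional[Path] = None
    if outdir is not None:
        out_path = Path(outdir)
        out_path.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out_path / "config.yaml")
        write_cloud(PointCloud(filtered.xyz, seg.label), out_path / "segmented.ply")
        _write_seed_csv(fused, out_path / "seeds.csv")
        summary = {
            "n_points_in": len(cloud), "n_ground_removed": n_removed,
            "n_raw_seeds": len(raw_seeds), "n_stems": len(fused),
            "auto_heights": auto_heights,
            "runtime_s": round(time.perf_counter() - t0, 2),
        }
        if report is not None:
            summary["evaluation"] = report.to_dict()
        (out_path / "report.json").write_text(json.dumps(summary, indent=2))
    log.info("pipeline done in %.1f s", time.perf_counter() - t0)
    return seg, report, out_path


def _write_seed_csv(seeds: List[StemSeed3D], path: Path) -> None:
    import pandas as pd

    pd.DataFrame({
        "seed_id": np.arange(1, len(seeds) + 1),
        "x": [s.centroid[0] for s in seeds],
        "y": [s.centroid[1] for s in seeds],
        "z": [s.centroid[2] for s in seeds],
        "confidence": [s.confidence for s in seeds],
        "diameter": [s.diameter for s in seeds],
        "n_points": [s.n_points for s in seeds],
        "direction": [s.source[0] for s in seeds],
    }).to_csv(path, index=False)
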