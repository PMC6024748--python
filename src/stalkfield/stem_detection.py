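"""Stem detection on depth images behind a backend-agnostic contract.

Two backends honor the same ``detect`` signature:

* a deterministic geometric baseline (connected components filtered by the
  width / height / elongation / bottom-position profile of a maize stalk),
  which is the reference implementation used throughout the test suite; and
* an optional learned anchor-based detector (region-proposal style).  The
  anchor scheme — 20 anchors per location from 4 areas x 5 aspect ratios,
  foreground above 0.7 overlap, background below 0.3, the max-overlap anchor
  always foreground — is implemented here; actually training the network
  needs the optional ``torch`` dependency and fails with a clear capability
  error when it is absent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

__all__ = [
    "Box2D", "StemDetection", "AnchorConfig", "TrainConfig", "BaselineConfig",
    "iou", "label_anchors", "generate_anchors", "detect_baseline", "detect",
    "train_learned_backend", "BaselineDetector", "MissingDependencyError",
]


class MissingDependencyError(RuntimeError):
    """An optional backend dependency is not installed."""


@dataclass(frozen=True)
class Box2D:
    """Axis-aligned box in pixel coordinates, half-open, x = column, z = row."""

    x_min: float
    z_min: float
    x_max: float
    z_max: float

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.z_max > self.z_min):
            raise ValueError("box must have positive width and height")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.z_max - self.z_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> Tuple[float, float]:
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.z_min + self.z_max))


@dataclass
class StemDetection:
    """A scored stem bounding box on one depth image."""

    box: Box2D
    confidence: float
    image_ref: Optional[object] = None   # the DepthImage the box lives on

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError("confidence must lie in [0, 1]")


def iou(a: Box2D, b: Box2D) -> float:
    """Intersection-over-union of two boxes (the anchor 'degree of overlap')."""
    iw = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    ih = min(a.z_max, b.z_max) - max(a.z_min, b.z_min)
    if iw <= 0.0 or ih <= 0.0:
        return 0.0
    inter = iw * ih
    return inter / (a.area + b.area - inter)


# ---------------------------------------------------------------------------
# anchor scheme
# ---------------------------------------------------------------------------

@dataclass
class AnchorConfig:
    """Anchor areas/ratios and the foreground/background overlap gates.

    Defaults give 4 areas x 5 ratios = 20 anchors per feature-map location;
    a ratio is height/width, so 8 is the tall-thin stem shape.
    """

    areas: Sequence[float] = (1.0, 49.0, 196.0, 3481.0)   # px², i.e. 1² 7² 14² 59²
    ratios: Sequence[float] = (0.13, 0.51, 0.84, 1.3, 8.0)
    fg_iou: float = 0.7
    bg_iou: float = 0.3

    def __post_init__(self) -> None:
        if not (0.0 < self.bg_iou < self.fg_iou < 1.0):
            raise ValueError("need 0 < bg_iou < fg_iou < 1")

    @property
    def anchors_per_location(self) -> int:
        return len(self.areas) * len(self.ratios)


@dataclass
class TrainConfig:
    """SGD hyper-parameters for the learned backend."""

    base_lr: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 0.0005
    stop_loss: float = 0.01     # stop when both loss terms fall below this
    max_epochs: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("base_lr", "momentum", "weight_decay", "stop_loss", "max_epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def generate_anchors(center: Tuple[float, float],
                     cfg: AnchorConfig) -> List[Box2D]:
    """The area x ratio anchor set centered at a feature location (pixels)."""
    cx, cz = center
    out = []
    for area in cfg.areas:
        for ratio in cfg.ratios:
            w = math.sqrt(area / ratio)
            h = w * ratio
            out.append(Box2D(cx - w / 2, cz - h / 2, cx + w / 2, cz + h / 2))
    return out


def label_anchors(anchors: Sequence[Box2D], gt: Box2D, cfg: AnchorConfig):
    """Foreground/background/ignore labels plus regression offsets.

    The max-IoU anchor is foreground regardless of threshold; anchors above
    ``fg_iou`` are foreground, below ``bg_iou`` background, the ambiguous band
    in between is ignored.  Foreground anchors get the standard center-shift
    and log-scale offsets ``(dx, dz, dw, dh)`` to the ground-truth box.
    """
    if len(anchors) == 0:
        raise ValueError("need at least one anchor")
    ious = np.array([iou(a, gt) for a in anchors])
    labels = np.full(len(anchors), "ignore", dtype=object)
    labels[ious > cfg.fg_iou] = "foreground"
    labels[ious < cfg.bg_iou] = "background"
    labels[int(np.argmax(ious))] = "foreground"   # best anchor is never background
    offsets = np.full((len(anchors), 4), np.nan)
    gcx, gcz = gt.center
    for i, a in enumerate(anchors):
        if labels[i] != "foreground":
            continue
        acx, acz = a.center
        offsets[i] = (
            (gcx - acx) / a.width,
            (gcz - acz) / a.height,
            math.log(gt.width / a.width),
            math.log(gt.height / a.height),
        )
    return labels, offsets


# ---------------------------------------------------------------------------
# deterministic geometric baseline
# ---------------------------------------------------------------------------

@dataclass
class BaselineConfig:
    """Geometric stem profile used by the baseline detector.

    Lengths are in meters and converted to pixels with the image's pixel
    size.  A candidate component must present a narrow (``max_width``), tall
    (``min_height``), elongated (``min_aspect``) core whose foot lies in the
    bottom ``bottom_fraction`` of the image's occupied height.
    """

    max_width: float = 0.05       # m
    min_height: float = 0.05      # m
    min_aspect: float = 2.0       # height / width
    bottom_fraction: float = 0.25
    core_support: float = 0.5     # keep columns with >= this fraction of the
                                  # peak per-column pixel count (stub pruning)
    close_gaps: bool = True       # one binary closing of the occupancy mask,
                                  # bridging sub-pixel sampling gaps in the bar


def _core_box(mask: np.ndarray, sl: Tuple[slice, slice],
              support: float) -> Optional[Tuple[int, int, int, int, int]]:
    """Column-support refinement of one labeled component.

    Leaf stubs attached to a stalk contribute a few pixels in extra columns;
    keeping only columns whose pixel count reaches ``support`` x the peak
    column recovers the vertical stalk core.  Returns (row_min, row_max,
    col_min, col_max, n_core_pixels) in image coordinates, or None.
    """
    sub = mask[sl]
    col_counts = sub.sum(axis=0)
    peak = col_counts.max()
    if peak == 0:
        return None
    keep = np.flatnonzero(col_counts >= support * peak)
    lo, hi = keep.min(), keep.max()
    core = sub[:, lo:hi + 1]
    rows = np.flatnonzero(core.any(axis=1))
    r0, r1 = rows.min(), rows.max()
    n_pix = int(core[r0:r1 + 1].sum())
    return (sl[0].start + r0, sl[0].start + r1,
            sl[1].start + lo, sl[1].start + hi, n_pix)


def detect_baseline(image, params: Optional[BaselineConfig] = None) -> List[StemDetection]:
    """Find stalk-like components on a depth image, deterministically.

    Occupied pixels are 8-connected into components; each component is
    reduced to its column-support core and kept when the core is narrow,
    tall, elongated and rooted near the bottom of the image's occupied
    z-range.  Confidence is ``0.5 * elongation + 0.5 * fill`` of the core box,
    clamped to [0, 1], so a clean dense stalk scores close to 1.
    """
    params = params or BaselineConfig()
    pixels = image.pixels
    occ = pixels > 0.0
    if not occ.any():
        return []
    if params.close_gaps:
        # point spacings near the pixel size leave pinholes in a solid stalk
        # bar; a single closing restores the surface without inventing mass
        # beyond a one-pixel bridge
        occ = occ | ndimage.binary_closing(occ, structure=np.ones((3, 3), bool))
    px = image.pixel_size
    w_max = params.max_width / px
    h_min = params.min_height / px
    occ_rows = np.flatnonzero(occ.any(axis=1))
    r_lo, r_hi = occ_rows.min(), occ_rows.max()
    bottom_limit = r_lo + params.bottom_fraction * max(r_hi - r_lo, 1)
    labels, n_comp = ndimage.label(occ, structure=np.ones((3, 3), dtype=int))
    detections: List[StemDetection] = []
    for comp, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is None:
            continue
        core = _core_box(labels == comp, sl, params.core_support)
        if core is None:
            continue
        r0, r1, c0, c1, n_pix = core
        h = r1 - r0 + 1
        w = c1 - c0 + 1
        if w > w_max or h < h_min or h / w < params.min_aspect:
            continue
        if r0 > bottom_limit:       # lowest pixel must sit near the image foot
            continue
        elongation = min(1.0, (h / w) / 4.0)
        fill = n_pix / (h * w)
        conf = min(1.0, max(0.0, 0.5 * elongation + 0.5 * fill))
        box = Box2D(float(c0), float(r0), float(c1 + 1), float(r1 + 1))
        detections.append(StemDetection(box, conf, image_ref=image))
    detections.sort(key=lambda d: (d.box.x_min, d.box.z_min))
    return detections


class BaselineDetector:
    """Detector handle wrapping :func:`detect_baseline`."""

    name = "baseline"

    def __init__(self, params: Optional[BaselineConfig] = None) -> None:
        self.params = params or BaselineConfig()

    def detect(self, image) -> List[StemDetection]:
        return detect_baseline(image, self.params)


def detect(image, backend) -> List[StemDetection]:
    """Run a detector backend on one depth image.

    ``backend`` is any object with a ``detect(image)`` method (the baseline
    detector or a trained learned backend), or the string ``"baseline"``.
    """
    if backend == "baseline":
        backend = BaselineDetector()
    if not hasattr(backend, "detect"):
        raise TypeError("backend must expose a detect(image) method")
    dets = backend.detect(image)
    rows, cols = image.pixels.shape
    for d in dets:
        b = d.box
        if b.x_min < 0 or b.z_min < 0 or b.x_max > cols or b.z_max > rows:
            raise ValueError(f"backend returned out-of-bounds box {b}")
    return dets


def train_learned_backend(samples, anchor_cfg: Optional[AnchorConfig] = None,
                          train_cfg: Optional[TrainConfig] = None):
    """Train the anchor-based learned detector (requires ``torch``).

    The learned backend is optional: the package is fully functional with the
    geometric baseline.  Calling this without ``torch`` installed raises
    :class:`MissingDependencyError` at call time, never at import time.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("cannot train a detector on zero samples")
    anchor_cfg = anchor_cfg or AnchorConfig()
    train_cfg = train_cfg or TrainConfig()
    try:
        import torch  # noqa: F401
    except ImportError:
        raise MissingDependencyError(
            "the learned detector backend requires the optional 'torch' "
            "dependency; install torch or use the baseline backend"
        ) from None
    raise NotImplementedError(
        "learned backend training is not implemented in this build; "
        "use the deterministic baseline backend"
    )
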