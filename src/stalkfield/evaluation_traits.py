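"""Plant-level segmentation accuracy and height traits.

Predicted plants are matched one-to-one to reference plants by point
overlap (greedy on descending overlap; a match is a true positive when it
covers at least half the reference plant's points).  From the TP/FP/FN
counts,

    r = TP / (TP + FN),   p = TP / (TP + FP),   F = 2 r p / (r + p),

reported to two decimals.  For the truly segmented plants, automatic heights
are regressed against reference heights (least squares), reporting R², RMSE
of the fit, and the mean bias (auto − reference).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .ground_filter import GroundModel
__all__ = ["ConfusionCounts", "EvalReport", "match_plants", "prf",
           "plant_height", "height_regression", "MATCH_COVERAGE"]

MATCH_COVERAGE = 0.5    # a TP must cover >= this fraction of the ref plant


@dataclass
class ConfusionCounts:
    """Plant-level true/false positives and false negatives."""

    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class EvalReport:
    """Segmentation accuracy plus the height-regression summary."""

    counts: ConfusionCounts
    r: float
    p: float
    f: float
    height_pairs: List[Tuple[float, float]] = field(default_factory=list)
    r2: Optional[float] = None
    rmse: Optional[float] = None
    mean_bias: Optional[float] = None
    matches: List[Tuple[int, int]] = field(default_factory=list)  # (pred, ref)

    def to_dict(self) -> dict:
        return {
            "tp": self.counts.tp, "fp": self.counts.fp, "fn": self.counts.fn,
            "r": self.r, "p": self.p, "f": self.f,
            "r2": self.r2, "rmse": self.rmse, "mean_bias": self.mean_bias,
            "n_height_pairs": len(self.height_pairs),
        }


def _round2(x: float) -> float:
    """Round half up to two decimals, matching printed report precision."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def prf(counts: ConfusionCounts, ndigits: Optional[int] = 2
        ) -> Tuple[float, float, float]:
    """Recall, precision and F-score from TP/FP/FN.

    F is the harmonic mean computed from the *unrounded* r and p; all three
    are then rounded to ``ndigits`` decimals (None = no rounding).
    """
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    if tp + fn == 0 or tp + fp == 0:
        raise ZeroDivisionError("r and p are undefined: empty reference or prediction")
    r = tp / (tp + fn)
    p = tp / (tp + fp)
    f = 0.0 if r + p == 0 else 2.0 * r * p / (r + p)
    if ndigits is None:
        return r, p, f
    if ndigits != 2:
        return round(r, ndigits), round(p, ndigits), round(f, ndigits)
    return _round2(r), _round2(p), _round2(f)


def match_plants(pred_labels: np.ndarray, ref_labels: np.ndarray,
                 coverage: float = MATCH_COVERAGE
                 ) -> Tuple[ConfusionCounts, List[Tuple[int, int]]]:
    """Greedy one-to-one matching of predicted to reference plants.

    Both inputs are per-point label arrays over the *same* points (0 =
    ground/unassigned).  Pairs are taken in order of descending point
    overlap; a pair is a true positive when the overlap reaches ``coverage``
    of the reference plant's point count.  Unmatched reference plants are
    false negatives, unmatched predicted plants false positives.
    Returns the counts and the matched (pred_label, ref_label) pairs.
    """
    pred_labels = np.asarray(pred_labels).ravel()
    ref_labels = np.asarray(ref_labels).ravel()
    if pred_labels.shape != ref_labels.shape:
        raise ValueError("pred and ref must label the same points")
    pred_ids = np.unique(pred_labels[pred_labels > 0])
    ref_ids = np.unique(ref_labels[ref_labels > 0])
    ref_sizes = {int(rid): int((ref_labels == rid).sum()) for rid in ref_ids}
    both = (pred_labels > 0) & (ref_labels > 0)
    if both.any():
        pairs, overlaps = np.unique(
            np.column_stack([pred_labels[both], ref_labels[both]]),
            axis=0, return_counts=True)
    else:
        pairs = np.zeros((0, 2), dtype=np.int64)
        overlaps = np.zeros(0, dtype=np.int64)
    order = np.lexsort((pairs[:, 1], pairs[:, 0], -overlaps))
    used_pred, used_ref = set(), set()
    matches: List[Tuple[int, int]] = []
    for idx in order:
        pl, rl = int(pairs[idx, 0]), int(pairs[idx, 1])
        if pl in used_pred or rl in used_ref:
            continue
        if overlaps[idx] < coverage * ref_sizes[rl]:
            continue
        used_pred.add(pl)
        used_ref.add(rl)
        matches.append((pl, rl))
    tp = len(matches)
    fn = len(ref_ids) - tp
    fp = len(pred_ids) - tp
    return ConfusionCounts(tp, fp, fn), matches


def plant_height(points: np.ndarray, ground: Optional[GroundModel] = None) -> float:
    """Height of one plant's point set, in meters.

    With a ground model: the maximum elevation above the local cell minimum
    (insensitive to a basal cut).  Without: the vertical extent
    ``max z − min z`` of the point set, which is how heights are read off
    manually segmented clouds and *is* sensitive to a basal ground cut.
    """
    points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    if points.shape[0] == 0:
        raise ValueError("cannot measure the height of an empty point set")
    if ground is not None:
        return float((points[:, 2] - ground.min_z_at(points)).max())
    return float(points[:, 2].max() - points[:, 2].min())


def height_regression(pairs: Sequence[Tuple[float, float]]
                      ) -> Tuple[float, float, float]:
    """Least-squares fit of automatic on reference heights.

    Returns (R², RMSE of the fit residuals, mean bias auto − reference).
    Requires at least two pairs and non-constant reference heights.
    """
    arr = np.asarray(pairs, dtype=np.float64).reshape(-1, 2)
    if arr.shape[0] < 2:
        raise ValueError("height regression needs at least two pairs")
    auto, ref = arr[:, 0], arr[:, 1]
    if np.allclose(ref, ref[0]):
        raise ValueError("degenerate fit: reference heights are constant")
    fit = stats.linregress(ref, auto)
    resid = auto - (fit.intercept + fit.slope * ref)
    r2 = float(fit.rvalue ** 2)
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    bias = float(np.mean(auto - ref))
    return r2, rmse, bias


def evaluate_segmentation(pred_labels: np.ndarray, ref_labels: np.ndarray,
                          auto_heights: Optional[dict] = None,
                          ref_heights: Optional[dict] = None) -> EvalReport:
    """Full report: match plants, compute r/p/F, and (optionally) regress
    matched automatic heights on reference heights keyed by label."""
    counts, matches = match_plants(pred_labels, ref_labels)
    r, p, f = prf(counts)
    report = EvalReport(counts, r, p, f, matches=matches)
    if auto_heights and ref_heights:
        pairs = [(auto_heights[pl], ref_heights[rl]) for pl, rl in matches
                 if pl in auto_heights and rl in ref_heights]
        report.height_pairs = pairs
        if len(pairs) >= 2:
            report.r2, report.rmse, report.mean_bias = height_regression(pairs)
    return report
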