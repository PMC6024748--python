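"""IoU, anchor labeling, and the geometric baseline detector."""

import numpy as np
import pytest

from stalkfield.projection import DepthImage, SliceWindow, ViewDirection
from stalkfield.stem_detection import (AnchorConfig, BaselineConfig, Box2D,
                                       MissingDependencyError, detect,
                                       detect_baseline, generate_anchors, iou,
                                       label_anchors, train_learned_backend)


def pixel_iou_oracle(a: Box2D, b: Box2D, grid: int) -> float:
    """Independent IoU: literally count member pixels on a grid."""
    xx, zz = np.meshgrid(np.arange(grid) + 0.5, np.arange(grid) + 0.5)
    in_a = (xx > a.x_min) & (xx < a.x_max) & (zz > a.z_min) & (zz < a.z_max)
    in_b = (xx > b.x_min) & (xx < b.x_max) & (zz > b.z_min) & (zz < b.z_max)
    union = (in_a | in_b).sum()
    return (in_a & in_b).sum() / union if union else 0.0


def _image(pixels, pixel_size=0.004):
    win = SliceWindow(direction=ViewDirection(0, 1), origin=(0, 0, 0),
                      field_x=pixels.shape[1] * pixel_size,
                      field_z=pixels.shape[0] * pixel_size)
    return DepthImage(np.asarray(pixels, dtype=float), pixel_size, win)


class TestIoU:
    def test_examples(self):
        a = Box2D(0, 0, 2, 2)
        assert iou(a, a) == 1.0
        assert iou(a, Box2D(5, 5, 7, 7)) == 0.0
        assert iou(a, Box2D(1, 0, 3, 2)) == pytest.approx(1 / 3)

    def test_matches_pixel_enumeration_exhaustively_on_small_grid(self):
        grid = 6
        boxes = [Box2D(x0, z0, x1, z1)
                 for x0 in range(grid) for x1 in range(x0 + 1, grid + 1)
                 for z0 in range(grid) for z1 in range(z0 + 1, grid + 1)]
        for a in boxes[::7]:
            for b in boxes[::5]:
                assert iou(a, b) == pytest.approx(pixel_iou_oracle(a, b, grid))

    def test_symmetry_and_bounds_random(self, rng):
        for _ in range(200):
            x = np.sort(rng.integers(0, 13, 4).astype(float))
            a = Box2D(x[0], x[0], x[1] + 1, x[2] + 1)
            b = Box2D(x[1], x[0], x[3] + 1, x[1] + 2)
            v = iou(a, b)
            assert 0.0 <= v <= 1.0
            assert v == pytest.approx(iou(b, a))
            assert v == pytest.approx(pixel_iou_oracle(a, b, 16))


class TestAnchorLabeling:
    def test_single_positive_overlap_anchor_is_foreground(self):
        gt = Box2D(10, 10, 20, 40)
        anchors = [Box2D(12, 12, 18, 30)]
        labels, _ = label_anchors(anchors, gt, AnchorConfig())
        assert labels[0] == "foreground"

    def test_perfect_anchor_zero_offsets(self):
        gt = Box2D(5, 5, 15, 45)
        labels, offs = label_anchors([gt], gt, AnchorConfig())
        assert labels[0] == "foreground"
        np.testing.assert_allclose(offs[0], 0.0, atol=1e-12)

    def test_threshold_bands(self):
        gt = Box2D(0, 0, 10, 10)
        # widths chosen to produce IoU ~0.2, ~0.5, ~0.8 against gt
        anchors = [Box2D(0, 0, 10, 2.0), Box2D(0, 0, 10, 5.0), Box2D(0, 0, 10, 8.0)]
        ious = [iou(a, gt) for a in anchors]
        assert ious[0] < 0.3 < ious[1] < 0.7 < ious[2]
        labels, offs = label_anchors(anchors, gt, AnchorConfig())
        assert list(labels) == ["background", "ignore", "foreground"]
        # regression offsets defined only for foreground anchors
        assert np.isnan(offs[0]).all() and np.isfinite(offs[2]).all()

    def test_max_iou_anchor_never_background(self, rng):
        gt = Box2D(20, 20, 30, 60)
        cfg = AnchorConfig()
        for _ in range(50):
            centers = rng.uniform(0, 80, size=(3, 2))
            anchors = [a for c in centers for a in generate_anchors(tuple(c), cfg)]
            labels, _ = label_anchors(anchors, gt, cfg)
            ious = np.array([iou(a, gt) for a in anchors])
            assert labels[int(np.argmax(ious))] == "foreground"
            assert set(labels) <= {"foreground", "background", "ignore"}

    def test_default_scheme_yields_twenty_anchors(self):
        cfg = AnchorConfig()
        assert cfg.anchors_per_location == 20
        assert len(generate_anchors((50, 50), cfg)) == 20


class TestBaselineDetector:
    def test_blank_image_no_detections(self):
        assert detect_baseline(_image(np.zeros((64, 64)))) == []

    def test_vertical_bar_detected_with_its_bounding_box(self):
        img = np.zeros((64, 64))
        img[0:40, 30:33] = 0.9          # 3 px wide, 40 px tall, at the base
        dets = detect_baseline(_image(img))
        assert len(dets) == 1
        d = dets[0]
        assert (d.box.x_min, d.box.z_min, d.box.x_max, d.box.z_max) == (30, 0, 33, 40)
        assert d.confidence > 0.9

    def test_horizontal_bar_rejected(self):
        img = np.zeros((64, 64))
        img[5:8, 10:50] = 0.9           # elongation fails
        assert detect_baseline(_image(img)) == []

    def test_floating_bar_rejected_by_bottom_rule(self):
        img = np.zeros((128, 128))
        img[0:10, 5:50] = 0.5           # ground-level clutter sets the z-range
        img[80:120, 60:63] = 0.9        # bar floats mid-air
        dets = detect_baseline(_image(img))
        assert all(d.box.x_min != 60 for d in dets)

    def test_translation_equivariance(self):
        img = np.zeros((64, 64))
        img[0:30, 10:13] = 0.8
        shifted = np.roll(img, 20, axis=1)
        d1 = detect_baseline(_image(img))
        d2 = detect_baseline(_image(shifted))
        assert len(d1) == len(d2) == 1
        assert d2[0].box.x_min - d1[0].box.x_min == 20
        assert d2[0].confidence == pytest.approx(d1[0].confidence)

    def test_leaf_stub_does_not_sink_confidence(self):
        """A small lateral attachment must not drag the score below the gate."""
        img = np.zeros((64, 64))
        img[0:40, 30:33] = 0.9
        img[20:23, 33:40] = 0.9         # leaf stub, 8-connected to the bar
        dets = detect_baseline(_image(img))
        assert len(dets) == 1
        assert dets[0].confidence > 0.9
        assert dets[0].box.x_max <= 34  # stub columns pruned from the core


class TestDetectContract:
    def test_string_backend_dispatches_to_baseline(self):
        img = np.zeros((64, 64))
        img[0:40, 30:33] = 0.9
        image = _image(img)
        assert [d.box for d in detect(image, "baseline")] \
            == [d.box for d in detect_baseline(image)]

    def test_out_of_bounds_box_rejected(self):
        class Bad:
            def detect(self, image):
                from stalkfield.stem_detection import StemDetection
                return [StemDetection(Box2D(0, 0, 1000, 1000), 0.5)]
        with pytest.raises(ValueError, match="out-of-bounds"):
            detect(_image(np.ones((8, 8))), Bad())

    def test_training_without_samples_rejected(self):
        with pytest.raises(ValueError, match="zero samples"):
            train_learned_backend([])

    def test_training_without_torch_is_capability_error(self):
        try:
            import torch  # noqa: F401
            pytest.skip("torch installed; capability error not applicable")
        except ImportError:
            pass
        with pytest.raises(MissingDependencyError, match="torch"):
            train_learned_backend([object()])
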