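"""Rotation, window tiling, depth-image encoding, and training samples."""

import numpy as np
import pytest

from stalkfield.pointcloud_io import PointCloud
from stalkfield.projection import (DepthImage, SliceWindow, ViewDirection,
                                   make_training_samples, rasterize,
                                   rotate_cloud, slice_windows)


def _window(depth=0.016, origin=(0.0, 0.0, 0.0), direction=ViewDirection(0, 1)):
    return SliceWindow(direction=direction, origin=origin, depth_y=depth)


class TestRotation:
    def test_zero_and_full_turn_are_identity(self, random_cloud):
        r0 = rotate_cloud(random_cloud, ViewDirection(0, 32))
        np.testing.assert_allclose(r0.xyz, random_cloud.xyz, atol=1e-12)
        r_full = rotate_cloud(random_cloud, ViewDirection(31, 32))
        # one more step would close the circle
        again = rotate_cloud(r_full, ViewDirection(1, 32),
                             center=(float(random_cloud.xyz[:, 0].mean()),
                                     float(random_cloud.xyz[:, 1].mean())))
        np.testing.assert_allclose(again.xyz, random_cloud.xyz, atol=1e-9)

    def test_quarter_turn_about_origin(self):
        cloud = PointCloud([[2.0, 0.0, 0.3]])
        rot = rotate_cloud(cloud, ViewDirection(8, 32), center=(0.0, 0.0))
        np.testing.assert_allclose(rot.xyz[0], [0.0, 2.0, 0.3], atol=1e-12)

    def test_distances_and_z_preserved(self, random_cloud):
        rot = rotate_cloud(random_cloud, ViewDirection(5, 32))
        np.testing.assert_array_equal(rot.xyz[:, 2], random_cloud.xyz[:, 2])
        pairs = np.random.default_rng(3).integers(0, len(random_cloud), (50, 2))
        d0 = np.linalg.norm(random_cloud.xyz[pairs[:, 0]]
                            - random_cloud.xyz[pairs[:, 1]], axis=1)
        d1 = np.linalg.norm(rot.xyz[pairs[:, 0]] - rot.xyz[pairs[:, 1]], axis=1)
        np.testing.assert_allclose(d0, d1, atol=1e-9)

    def test_source_frame_records_direction(self, random_cloud):
        rot = rotate_cloud(random_cloud, ViewDirection(5, 32))
        assert rot.source_frame.startswith("view:5/32")


class TestSliceWindows:
    def test_three_windows_per_column(self, rng):
        xyz = np.column_stack([rng.uniform(0, 0.5, 300),
                               rng.uniform(0, 0.048 - 1e-6, 300),
                               rng.uniform(0, 0.4, 300)])
        wins = slice_windows(PointCloud(xyz), field=1.024, depth=0.016)
        assert len(wins) == 3
        y0s = sorted(w.origin[1] for w, _ in wins)
        np.testing.assert_allclose(np.diff(y0s), 0.016, atol=1e-12)

    def test_empty_cloud_no_windows(self):
        assert slice_windows(PointCloud(np.zeros((0, 3)))) == []

    def test_partition_property(self, rng):
        cloud = PointCloud(rng.uniform([-2, -3, 0], [4, 2, 1.0], size=(800, 3)))
        wins = slice_windows(cloud, field=1.024, depth=0.016)
        seen = np.concatenate([idx for _, idx in wins])
        assert len(seen) == len(cloud)
        assert len(np.unique(seen)) == len(cloud)
        for w, idx in wins:
            assert w.contains(cloud.xyz[idx]).all()


class TestRasterize:
    def test_empty_window_all_zero(self):
        img = rasterize(PointCloud(np.zeros((0, 3))), _window())
        assert img.pixels.shape == (256, 256)
        assert not img.pixels.any()

    def test_center_point_maps_to_center_pixel_full_brightness(self):
        img = rasterize(PointCloud([[0.512, 0.0, 0.512]]), _window())
        assert img.pixels[128, 128] == pytest.approx(1.0)
        assert (img.pixels > 0).sum() == 1

    def test_nearest_point_sets_depth_intensity(self):
        # two points in one pixel at depths 0.004 and 0.012 of a 0.016 window
        pts = PointCloud([[0.1001, 0.004, 0.2001], [0.1002, 0.012, 0.2002]])
        img = rasterize(pts, _window())
        col, row = img.meters_to_pixel(0.1001, 0.2001)
        assert img.pixels[row, col] == pytest.approx(1 - 0.004 / 0.016)

    def test_permutation_invariance(self, rng):
        pts = np.column_stack([rng.uniform(0, 1.024, 200),
                               rng.uniform(0, 0.016, 200),
                               rng.uniform(0, 1.024, 200)])
        img1 = rasterize(PointCloud(pts), _window())
        img2 = rasterize(PointCloud(pts[rng.permutation(200)]), _window())
        np.testing.assert_array_equal(img1.pixels, img2.pixels)

    def test_pixel_meter_round_trip_on_centers(self):
        img = rasterize(PointCloud(np.zeros((0, 3))), _window())
        cols = np.arange(0, 256, 17)
        rows = np.arange(0, 256, 13)
        x, z = img.pixel_center_meters(cols, rows[:len(cols)])
        c2, r2 = img.meters_to_pixel(x, z)
        np.testing.assert_array_equal(c2, cols)
        np.testing.assert_array_equal(r2, rows[:len(cols)])

    def test_outside_points_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            rasterize(PointCloud([[2.0, 0.0, 0.5]]), _window())


class TestTrainingSamples:
    def test_sample_count_is_plants_times_views(self, tiny_field):
        _, cloud, truths = tiny_field
        samples = make_training_samples(cloud, truths, n_views=4)
        assert len(samples) == len(truths) * 4

    def test_stem_box_matches_brute_force(self, tiny_field):
        _, cloud, truths = tiny_field
        samples = make_training_samples(cloud, truths, n_views=1)
        for s, t in zip(samples, truths):
            # brute force: bounding box of this plant's sub-threshold pixels
            pts = cloud.xyz[cloud.labels == t.plant_id]
            z0 = pts[:, 2].min()
            stem = pts[pts[:, 2] - z0 < t.height / 3.0]
            in_roi = s.image.window.contains(stem)
            col, row = s.image.meters_to_pixel(stem[:, 0], stem[:, 2])
            col, row = np.clip(col, 0, 255), np.clip(row, 0, 255)
            inside = in_roi
            assert s.stem_box.x_min == col[inside].min()
            assert s.stem_box.x_max == col[inside].max() + 1
            assert s.stem_box.z_min == row[inside].min()
            assert s.stem_box.z_max == row[inside].max() + 1

    def test_stem_threshold_is_one_third_of_height(self, tiny_field):
        _, cloud, truths = tiny_field
        t = truths[0]
        pts = cloud.xyz[cloud.labels == t.plant_id]
        z0 = pts[:, 2].min()
        frac = 1.0 / 3.0
        below = pts[:, 2] - z0 < frac * t.height
        assert below.any() and not below.all()

    def test_unlabeled_cloud_rejected(self, random_cloud):
        cloud = PointCloud(random_cloud.xyz)
        with pytest.raises(ValueError, match="labeled"):
            make_training_samples(cloud, [], n_views=1)
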