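"""Graph construction, transport distances, and DvN assignment."""

import numpy as np
import pytest

from stalkfield.csp_segmentation import (SegmentConfig, assign_labels,
                                         build_graph, segment,
                                         transport_distances)
from stalkfield.fusion_mapping import StemSeed3D
from stalkfield.pointcloud_io import PointCloud
from stalkfield.synth_field import FieldSpec, PlantTruth, generate_plant


def _seed(indices, diameter=0.02, conf=0.95):
    return StemSeed3D(np.asarray(indices), (0, 0, 0), conf, diameter)


def floyd_warshall_oracle(n, edges):
    """Independent all-pairs shortest paths by min-plus iteration."""
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i, j, w in edges:
        d[i, j] = min(d[i, j], w)
        d[j, i] = min(d[j, i], w)
    for k in range(n):
        d = np.minimum(d, d[:, k, None] + d[None, k, :])
    return d


def brute_force_knn_edges(xyz, k, cap):
    edges = set()
    n = len(xyz)
    dist = np.linalg.norm(xyz[:, None] - xyz[None, :], axis=2)
    for i in range(n):
        order = np.argsort(dist[i], kind="stable")
        nbrs = [j for j in order if j != i][:k]
        for j in nbrs:
            if dist[i, j] <= cap:
                edges.add((min(i, j), max(i, j)))
    return edges


class TestBuildGraph:
    def test_two_points_within_cap(self):
        g = build_graph(PointCloud([[0, 0, 0], [0.03, 0, 0]]), k=1, radius_cap=0.05)
        assert {(i, j) for i, j, _ in g.edge_set()} == {(0, 1)}
        (_, _, w), = g.edge_set()
        assert w == pytest.approx(0.03)

    def test_two_points_beyond_cap(self):
        g = build_graph(PointCloud([[0, 0, 0], [0.2, 0, 0]]), k=1, radius_cap=0.05)
        assert g.edge_set() == set()

    def test_matches_brute_force_knn(self, rng):
        xyz = rng.uniform(0, 0.3, size=(200, 3))
        g = build_graph(PointCloud(xyz), k=4, radius_cap=0.08)
        got = {(i, j) for i, j, _ in g.edge_set()}
        assert got == brute_force_knn_edges(xyz, 4, 0.08)

    def test_empty_cloud_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_graph(PointCloud(np.zeros((0, 3))), k=3)


class TestTransportDistances:
    def test_seed_distance_zero_and_chain_sums(self):
        pts = PointCloud([[0, 0, 0], [0.01, 0, 0], [0.02, 0, 0]])
        g = build_graph(pts, k=1, radius_cap=0.05)
        d = transport_distances(g, [_seed([0])])
        np.testing.assert_allclose(d[0], [0.0, 0.01, 0.02], atol=1e-12)

    def test_matches_shortest_path_oracle(self, rng):
        for trial in range(20):
            n = int(rng.integers(10, 80))
            xyz = rng.uniform(0, 0.5, size=(n, 3))
            g = build_graph(PointCloud(xyz), k=3, radius_cap=0.2)
            oracle = floyd_warshall_oracle(n, g.edge_set())
            seed_sets = [rng.choice(n, size=2, replace=False) for _ in range(3)]
            d = transport_distances(g, [_seed(s) for s in seed_sets])
            for row, s in zip(d, seed_sets):
                np.testing.assert_allclose(row, oracle[s].min(axis=0), atol=1e-9)

    def test_unreachable_is_infinite(self):
        pts = PointCloud([[0, 0, 0], [5, 5, 5]])
        g = build_graph(pts, k=1, radius_cap=0.05)
        d = transport_distances(g, [_seed([0])])
        assert d[0, 1] == np.inf


class TestAssignment:
    def test_equal_diameters_reduce_to_nearest_seed(self, rng):
        n = 60
        dist = rng.uniform(0.1, 1.0, size=(2, n))
        seeds = [_seed([0], diameter=0.02), _seed([1], diameter=0.02)]
        res = assign_labels(dist, seeds)
        np.testing.assert_array_equal(res.label, np.argmin(dist, axis=0) + 1)

    def test_diameter_power_two_thirds_hand_example(self):
        # equal path distance 1.0; diameters 1 and 8 -> DvN 1.0 vs 1/4
        dist = np.array([[1.0], [1.0]])
        seeds = [_seed([0], diameter=1.0), _seed([1], diameter=8.0)]
        res = assign_labels(dist, seeds)
        assert res.label[0] == 2
        assert res.dvn[0] == pytest.approx(0.25)

    def test_single_seed_claims_everything_reachable(self):
        dist = np.array([[0.0, 0.3, np.inf]])
        res = assign_labels(dist, [_seed([0])])
        np.testing.assert_array_equal(res.label, [1, 1, 0])
        assert res.dvn[2] == np.inf

    def test_uniform_diameter_rescaling_is_invariant(self, rng):
        dist = rng.uniform(0, 1, size=(4, 100))
        diams = [0.01, 0.02, 0.015, 0.03]
        res1 = assign_labels(dist, [_seed([i], diameter=d)
                                    for i, d in enumerate(diams)])
        res2 = assign_labels(dist, [_seed([i], diameter=5 * d)
                                    for i, d in enumerate(diams)])
        np.testing.assert_array_equal(res1.label, res2.label)

    def test_growing_a_diameter_never_shrinks_its_region(self, rng):
        dist = rng.uniform(0, 1, size=(3, 200))
        diams = [0.02, 0.02, 0.02]
        base = assign_labels(dist, [_seed([i], diameter=d)
                                    for i, d in enumerate(diams)])
        grown = assign_labels(dist, [_seed([0], diameter=0.04),
                                     _seed([1], diameter=0.02),
                                     _seed([2], diameter=0.02)])
        assert set(np.flatnonzero(base.label == 1)) \
            <= set(np.flatnonzero(grown.label == 1))


@pytest.fixture(scope="module")
def two_plants():
    spec = FieldSpec(n_rows=2, n_cols=2, n_plants=2, noise_sd=0.0,
                     dropout_rate=0.0, height_range=(0.35, 0.45), rng_seed=2)
    rng = np.random.default_rng(0)
    t1 = PlantTruth(1, (0.0, 0.0), 0.40, 0.02)
    t2 = PlantTruth(2, (0.5, 0.0), 0.42, 0.02)
    c1 = generate_plant(t1, spec, rng)
    c2 = generate_plant(t2, spec, rng)
    xyz = np.vstack([c1.xyz, c2.xyz])
    labels = np.concatenate([c1.plant_label, c2.plant_label])
    return PointCloud(xyz, labels), (t1, t2)


class TestSegment:

    def test_two_separated_plants_fully_recovered(self, two_plants):
        cloud, (t1, t2) = two_plants
        stem1 = np.flatnonzero((cloud.labels == 1)
                               & (cloud.xyz[:, 2] < 0.1)
                               & (np.hypot(cloud.xyz[:, 0], cloud.xyz[:, 1]) < 0.02))
        stem2 = np.flatnonzero((cloud.labels == 2)
                               & (cloud.xyz[:, 2] < 0.1)
                               & (np.hypot(cloud.xyz[:, 0] - 0.5, cloud.xyz[:, 1]) < 0.02))
        seeds = [StemSeed3D(stem1, (0, 0, 0.05), 0.95, 0.02),
                 StemSeed3D(stem2, (0.5, 0, 0.05), 0.95, 0.02)]
        res = segment(cloud, seeds)
        agree = (res.label == cloud.labels).mean()
        assert agree >= 0.99

    def test_single_plant_single_seed_no_mislabels(self):
        spec = FieldSpec(n_rows=1, n_cols=1, n_plants=1, noise_sd=0.0,
                         dropout_rate=0.0, height_range=(0.3, 0.4), rng_seed=3)
        cloud = generate_plant(PlantTruth(1, (0, 0), 0.35, 0.02), spec,
                               np.random.default_rng(1))
        seeds = [_seed(np.flatnonzero(cloud.xyz[:, 2] < 0.05))]
        res = segment(cloud, seeds)
        assert (res.label == 1).all()

    def test_no_seeds_rejected(self, two_plants):
        cloud, _ = two_plants
        with pytest.raises(ValueError, match="seed"):
            segment(cloud, [])
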