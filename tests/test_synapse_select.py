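import numpy as np
import pytest
import shapely.affinity
from shapely.geometry import Point

from _oracles import brute_force_dbscan, canonical_labels, csr_in_disc
from aznano.errors import DegenerateGeometryError
from aznano.synapse_select import (
    alpha_shape,
    detect_synaptic_clusters,
    remove_nonspecific_clusters,
    restrict_to_active_zone,
    select_enface,
)
from aznano.synthetic import simulate_field


class TestDetectSynapticClusters:
    def test_single_dense_disc_is_one_cluster(self, rng, table_factory):
        pts = csr_in_disc(rng, 100, 40.0)
        table = table_factory(pts[:, 0], pts[:, 1])
        labels = detect_synaptic_clusters(table)
        oracle = brute_force_dbscan(pts, 48.0, 10)
        np.testing.assert_array_equal(canonical_labels(labels), canonical_labels(oracle))
        assert (labels == 0).sum() == 100

    def test_two_separated_clumps(self, rng, table_factory):
        pts = np.vstack([csr_in_disc(rng, 80, 40.0), csr_in_disc(rng, 80, 40.0, (500.0, 0.0))])
        table = table_factory(pts[:, 0], pts[:, 1])
        labels = detect_synaptic_clusters(table)
        assert len(set(labels) - {-1}) == 2

    def test_small_cluster_relabeled_noise(self, rng, table_factory):
        pts = csr_in_disc(rng, 60, 40.0)
        table = table_factory(pts[:, 0], pts[:, 1])
        labels = detect_synaptic_clusters(table, min_cluster_size=75)
        assert (labels == -1).all()

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_oracle(self, seed, table_factory):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(50, 400))
        pts = rng.uniform(0, 600, (n, 2))
        table = table_factory(pts[:, 0], pts[:, 1])
        labels = detect_synaptic_clusters(table, min_cluster_size=1)
        oracle = brute_force_dbscan(pts, 48.0, 10)
        np.testing.assert_array_equal(canonical_labels(labels), canonical_labels(oracle))


class TestRemoveNonspecificClusters:
    def _table(self, table_factory, frames_per_cluster):
        xs, frames = [], []
        for i, fr in enumerate(frames_per_cluster):
            xs.extend([1000.0 * i] * len(fr))
            frames.extend(fr)
        n = len(xs)
        return table_factory(xs, np.zeros(n), frame=frames), np.repeat(
            np.arange(len(frames_per_cluster)), [len(f) for f in frames_per_cluster]
        )

    def test_uniform_frames_kept_narrow_removed(self, rng, table_factory):
        uniform = [rng.integers(0, 30000, 100) for _ in range(3)]
        narrow = [rng.integers(1000, 2001, 100)]
        table, labels = self._table(table_factory, uniform + narrow)
        out = remove_nonspecific_clusters(table, labels)
        # uniform over 30000 frames: SD ~ 8660, inside (2500, 11000)
        for lab in range(3):
            assert (out == lab).any()
        assert not (out == 3).any()

    def test_mean_frame_outlier_removed(self, rng, table_factory):
        clusters = [15000 + rng.integers(-9000, 9000, 80) for _ in range(20)]
        outlier = [1500 + rng.integers(-9000, 9000, 80)]
        table, labels = self._table(table_factory, clusters + [np.clip(o, 0, 29999) for o in outlier])
        out = remove_nonspecific_clusters(table, labels, frame_sd_bounds=(0.0, np.inf))
        means = [np.mean(c) for c in clusters]
        mu, sd = np.mean(means + [np.mean(outlier)]), np.std(means + [np.mean(outlier)])
        assert not (out == 20).any()  # the early-time cluster goes

    def test_fewer_than_three_clusters_warns_and_applies_sd_only(self, rng, table_factory):
        table, labels = self._table(
            table_factory, [rng.integers(0, 30000, 100), rng.integers(500, 1500, 100)]
        )
        with pytest.warns(UserWarning):
            out = remove_nonspecific_clusters(table, labels)
        assert (out == 0).any() and not (out == 1).any()


class TestAlphaShape:
    def test_convex_hull_limit_on_unit_square(self):
        pts = np.array(
            [[0, 0], [1, 0], [1, 1], [0, 1], [0.5, 0], [1, 0.5], [0.5, 1], [0, 0.5], [0.5, 0.5]],
            float,
        )
        poly, area = alpha_shape(pts, 1e9)
        assert area == pytest.approx(1.0)

    def test_disc_area(self, rng):
        th = np.linspace(0, 2 * np.pi, 200, endpoint=False)
        boundary = 100.0 * np.column_stack([np.cos(th), np.sin(th)])
        pts = np.vstack([boundary, csr_in_disc(rng, 400, 100.0)])
        _, area = alpha_shape(pts, 150.0)
        assert area == pytest.approx(np.pi * 100**2, rel=0.05)

    def test_two_points_degenerate(self):
        with pytest.raises(DegenerateGeometryError):
            alpha_shape(np.array([[0.0, 0.0], [1.0, 1.0]]), 10.0)

    def test_collinear_degenerate(self):
        pts = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(DegenerateGeometryError):
            alpha_shape(pts, 10.0)

    def test_area_monotone_in_alpha(self, rng):
        pts = csr_in_disc(rng, 150, 100.0)
        areas = []
        for alpha in (30.0, 60.0, 120.0, 1e9):
            try:
                areas.append(alpha_shape(pts, alpha)[1])
            except DegenerateGeometryError:
                areas.append(0.0)
        assert all(a <= b + 1e-9 for a, b in zip(areas, areas[1:]))


class TestSelectEnface:
    @staticmethod
    def _disc_points(rng, n, radius, center=(0, 0), aspect=1.0):
        pts = csr_in_disc(rng, n, radius)
        pts[:, 0] *= aspect
        return pts + np.asarray(center)

    def test_concentric_discs_accepted(self, rng):
        bas = self._disc_points(rng, 400, 200.0)
        psd = self._disc_points(rng, 400, 180.0)
        roi = select_enface(bas, psd)
        assert roi.accepted
        assert roi.overlap_fraction > 0.9
        assert roi.shape_metric == pytest.approx(1.0, abs=0.25)

    def test_half_overlap_rejected(self, rng):
        bas = self._disc_points(rng, 400, 200.0)
        psd = self._disc_points(rng, 400, 200.0, center=(260.0, 0.0))
        roi = select_enface(bas, psd)
        assert not roi.accepted
        assert roi.overlap_fraction < 0.70

    def test_elongated_scaffold_rejected(self, rng):
        bas = self._disc_points(rng, 500, 120.0, aspect=3.0)
        psd = self._disc_points(rng, 500, 120.0, aspect=3.0)
        roi = select_enface(bas, psd)
        assert not roi.accepted
        assert roi.shape_metric > 2.0

    def test_planted_synthetic_synapses(self):
        accepted_enface = 0
        for seed in range(10):
            tables, _ = simulate_field(seed=seed)
            bas, psd = tables["bassoon"].xy, tables["psd95"].xy
            # use only the synapse-local points (field also has nonspecific clumps)
            center = np.array([1000.0, 1000.0])
            bas = bas[np.linalg.norm(bas - center, axis=1) < 400]
            psd = psd[np.linalg.norm(psd - center, axis=1) < 400]
            accepted_enface += select_enface(bas, psd).accepted
        assert accepted_enface >= 9
        tables, _ = simulate_field(seed=0, aspect_ratio=3.0)
        center = np.array([1000.0, 1000.0])
        bas = tables["bassoon"].xy
        psd = tables["psd95"].xy
        bas = bas[np.linalg.norm(bas - center, axis=1) < 700]
        psd = psd[np.linalg.norm(psd - center, axis=1) < 700]
        assert not select_enface(bas, psd).accepted


class TestRestrictToActiveZone:
    def _roi(self):
        poly = Point(0, 0).buffer(100.0, quad_segs=32)
        from aznano.synapse_select import SynapseROI

        return SynapseROI(poly, poly, 1.0, 1.0, True)

    def test_boundary_count_rule(self, rng, table_factory):
        pts = csr_in_disc(rng, 24, 90.0)
        tables = {"munc13": table_factory(pts[:, 0], pts[:, 1])}
        roi = restrict_to_active_zone(self._roi(), tables, min_locs=25)
        assert not roi.accepted
        pts = csr_in_disc(rng, 25, 90.0)
        roi = restrict_to_active_zone(
            self._roi(), {"munc13": table_factory(pts[:, 0], pts[:, 1])}, min_locs=25
        )
        assert roi.accepted
        assert len(roi.restricted["munc13"]) == 25

    def test_outside_points_dropped(self, rng, table_factory):
        pts = np.vstack([csr_in_disc(rng, 30, 90.0), csr_in_disc(rng, 10, 50.0, (500.0, 0.0))])
        roi = restrict_to_active_zone(
            self._roi(), {"munc13": table_factory(pts[:, 0], pts[:, 1])}, min_locs=25
        )
        assert len(roi.restricted["munc13"]) == 30

    def test_boundary_point_counts_inside(self, table_factory):
        from aznano.synapse_select import SynapseROI
        from shapely.geometry import Polygon

        square = Polygon([(0, 0), (100, 0), (100, 100), (0, 100)])
        roi = SynapseROI(square, square, 1.0, 1.0, True)
        table = table_factory([0.0, 50.0], [0.0, 50.0])
        out = restrict_to_active_zone(roi, {"t": table}, min_locs=1)
        assert len(out.restricted["t"]) == 2  # (0, 0) lies on the boundary
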