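import numpy as np
import pytest
from scipy import stats as sps
from shapely.geometry import Point, Polygon

from _oracles import csr_in_disc
from aznano.cross_stats import (
    classify_enrichment,
    cross_enrichment,
    enrichment_statistic,
    randomize_in_roi,
    separation_index,
    smooth_profiles_across_synapses,
)
from aznano.errors import DegenerateGeometryError, ParameterError
from aznano.nanoclusters import Nanocluster, nanocluster_geometry


def circle_nanocluster(center, radius, nc_id=0):
    poly = Point(*center).buffer(radius, quad_segs=128)
    return Nanocluster(
        member_indices=np.empty(0, int),
        centroid_nm=np.asarray(center, float),
        polygon=poly,
        area_nm2=poly.area,
        effective_radius_nm=radius,
        n_locs=10,
        cluster_id=nc_id,
    )


class TestRandomizeInRoi:
    def test_containment_and_count(self, disc_roi, rng):
        sets = randomize_in_roi(137, disc_roi, 3, rng)
        assert len(sets) == 3
        for pts in sets:
            assert len(pts) == 137
            assert np.all(np.hypot(pts[:, 0], pts[:, 1]) <= 200.0 + 1e-6)

    def test_deterministic_given_seed(self, disc_roi):
        a = randomize_in_roi(50, disc_roi, 2, 42)
        b = randomize_in_roi(50, disc_roi, 2, 42)
        for s1, s2 in zip(a, b):
            np.testing.assert_array_equal(s1, s2)

    def test_uniformity_chi_square(self):
        square = Polygon([(0, 0), (400, 0), (400, 400), (0, 400)])
        rejections = 0
        n_seeds = 40
        for seed in range(n_seeds):
            pts = randomize_in_roi(1600, square, 1, seed)[0]
            counts, *_ = np.histogram2d(pts[:, 0], pts[:, 1], bins=4, range=[[0, 400], [0, 400]])
            chi2 = ((counts - 100.0) ** 2 / 100.0).sum()
            if chi2 > sps.chi2.ppf(0.99, 15):
                rejections += 1
        assert rejections <= 0.05 * n_seeds + 1

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            randomize_in_roi(10, Polygon(), 1, 0)


class TestCrossEnrichment:
    def test_csr_opposite_protein_is_flat(self, disc_roi):
        edges = np.arange(0.0, 110.0, 10.0)
        vals = []
        for seed in range(100):
            r = np.random.default_rng(seed)
            centers = csr_in_disc(r, 4, 120.0)
            pts_b = csr_in_disc(r, 300, 200.0)
            prof = cross_enrichment(centers, pts_b, disc_roi, edges, rng=r, n_rand=40)
            vals.append(prof.enrichment)
        mean = np.nanmean(vals, axis=0)
        assert np.all(np.abs(mean - 1.0) < 0.15)

    def test_concentrated_at_centers(self, disc_roi, rng):
        centers = np.array([[0.0, 0.0]])
        pts_b = rng.normal(0, 5.0, (100, 2))
        prof = cross_enrichment(centers, pts_b, disc_roi, rng=rng, n_rand=30)
        assert prof.enrichment[0] > 10.0
        assert prof.enrichment[0] > 10 * np.nanmean(prof.enrichment[5:])

    def test_intensity_scale_invariance(self, disc_roi):
        edges = np.arange(0.0, 110.0, 10.0)
        r1 = np.random.default_rng(0)
        centers = csr_in_disc(r1, 3, 100.0)
        base = csr_in_disc(r1, 150, 200.0)
        doubled = np.vstack([base, csr_in_disc(r1, 150, 200.0)])
        p1 = cross_enrichment(centers, base, disc_roi, edges, rng=1, n_rand=60)
        p2 = cross_enrichment(centers, doubled, disc_roi, edges, rng=1, n_rand=60)
        sel = np.isfinite(p1.enrichment) & np.isfinite(p2.enrichment)
        assert np.nanmean(p1.enrichment[sel]) == pytest.approx(
            np.nanmean(p2.enrichment[sel]), abs=0.25
        )


class TestClassifyEnrichment:
    def test_planted_colocalization_enriched(self, disc_roi, rng):
        centers = np.array([[0.0, 0.0]])
        pts_b = np.vstack([rng.normal(0, 10.0, (60, 2)), csr_in_disc(rng, 60, 200.0)])
        norm_sets = randomize_in_roi(len(pts_b), disc_roi, 100, 1)
        class_sets = randomize_in_roi(len(pts_b), disc_roi, 50, 2)
        prof = cross_enrichment(centers, pts_b, disc_roi, rand_sets_b=norm_sets)
        label, stat, mu, sd = classify_enrichment(prof, class_sets)
        assert label == "enriched"
        assert stat > mu + 1.96 * sd

    def test_statistic_equal_to_mean_is_indistinguishable(self, disc_roi):
        prof = cross_enrichment(
            np.array([[0.0, 0.0]]),
            csr_in_disc(np.random.default_rng(3), 100, 200.0),
            disc_roi,
            rng=4,
            n_rand=20,
        )
        # a single randomization gives no spread estimate -> never a strict tail call
        label, *_ = classify_enrichment(prof, [csr_in_disc(np.random.default_rng(5), 100, 200.0)])
        assert label in ("indistinguishable", "unclassifiable")

    def test_null_calibration_small(self, disc_roi):
        """Under CSR, the two-sided 1.96-SD rule fires on a few percent of cases."""
        tails = 0
        n_cases = 60
        edges = np.arange(0.0, 70.0, 10.0)
        for seed in range(n_cases):
            r = np.random.default_rng(seed)
            center = csr_in_disc(r, 1, 100.0)
            pts_b = csr_in_disc(r, 120, 200.0)
            norm = randomize_in_roi(120, disc_roi, 40, 1000 + seed)
            cls = randomize_in_roi(120, disc_roi, 50, 2000 + seed)
            prof = cross_enrichment(center, pts_b, disc_roi, edges, rand_sets_b=norm)
            label, *_ = classify_enrichment(prof, cls)
            tails += label in ("enriched", "de_enriched")
        assert tails / n_cases < 0.25


class TestSmoothing:
    def test_high_outlier_capped_per_bin(self):
        curves = np.ones((30, 5))
        curves[0, 2] = 50.0
        out = smooth_profiles_across_synapses(curves)
        assert out[0, 2] == pytest.approx(1.0)
        assert np.all(out <= 50.0)

    def test_no_outliers_untouched(self, rng):
        curves = 1.0 + 0.05 * rng.normal(size=(20, 4))
        out = smooth_profiles_across_synapses(curves)
        np.testing.assert_allclose(out, curves)


class TestSeparationIndex:
    def test_analytic_circle_pair(self):
        a = circle_nanocluster((0.0, 0.0), 20.0, 0)
        b = circle_nanocluster((100.0, 0.0), 30.0, 1)
        res = separation_index(a, [b])
        assert res.r1_nm == pytest.approx(20.0, rel=1e-3)
        assert res.r2_nm == pytest.approx(30.0, rel=1e-3)
        assert res.si == pytest.approx(2.0, rel=1e-3)
        assert not res.overlap

    def test_tangent_circles_boundary_case(self):
        a = circle_nanocluster((0.0, 0.0), 20.0)
        b = circle_nanocluster((50.0, 0.0), 30.0, 1)
        res = separation_index(a, [b])
        assert res.si == pytest.approx(1.0, rel=1e-3)

    def test_concentric_degenerate(self):
        a = circle_nanocluster((0.0, 0.0), 20.0)
        b = circle_nanocluster((0.0, 0.0), 30.0, 1)
        res = separation_index(a, [b])
        assert res.si == 0.0
        assert res.overlap
        assert res.degenerate

    def test_symmetry_for_circle_pairs(self):
        a = circle_nanocluster((0.0, 0.0), 25.0, 0)
        b = circle_nanocluster((80.0, 35.0), 15.0, 1)
        assert separation_index(a, [b]).si == pytest.approx(separation_index(b, [a]).si, rel=1e-6)

    def test_scale_invariance(self):
        for c in (1.0, 3.5):
            a = circle_nanocluster((0.0, 0.0), 20.0 * c, 0)
            b = circle_nanocluster((70.0 * c, 0.0), 30.0 * c, 1)
            res = separation_index(a, [b])
            assert res.si == pytest.approx(70.0 / 50.0, rel=1e-3)

    def test_nearest_opposite_chosen(self):
        a = circle_nanocluster((0.0, 0.0), 20.0, 0)
        near = circle_nanocluster((60.0, 0.0), 10.0, 1)
        far = circle_nanocluster((300.0, 0.0), 10.0, 2)
        assert separation_index(a, [far, near]).opposite_id == 1

    def test_irregular_polygon_border_distance(self, rng):
        pts = csr_in_disc(rng, 80, 30.0)
        src = nanocluster_geometry(pts)
        opp = circle_nanocluster((200.0, 0.0), 10.0, 1)
        res = separation_index(src, [opp])
        assert 0 < res.r1_nm < 60.0
        assert res.si > 1.0

    def test_empty_opposite_rejected(self):
        with pytest.raises(ParameterError):
            separation_index(circle_nanocluster((0, 0), 10.0), [])
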