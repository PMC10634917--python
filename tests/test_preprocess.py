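import numpy as np
import pytest

from aznano.errors import InsufficientDataError, ParameterError, UnderdeterminedError
from aznano.preprocess import (
    apply_transform,
    correct_residual_offset,
    drift_correct_rcc,
    filter_quality,
    fit_chromatic_transform,
    link_localizations,
    photon_mode_threshold,
)
from aznano.synthetic import linear_drift, simulate_fiducial_field


class TestFilterQuality:
    def test_sigma_bounds_are_exclusive_for_removal(self, table_factory):
        table = table_factory(np.arange(5.0), np.zeros(5), sigma=[0.2, 0.3, 1.0, 1.6, 1.7])
        out, report = filter_quality(table)
        assert sorted(out.df["sigma_px"]) == [0.3, 1.0, 1.6]
        assert report.rows_removed_sigma == 2
        assert report.rows_out == 3

    def test_photon_mode_bin_rule(self, table_factory):
        table = table_factory(np.arange(5.0), np.zeros(5), photons=[90, 100, 100, 100, 450])
        out, report = filter_quality(table)
        assert photon_mode_threshold(np.array([90, 100, 100, 100, 450.0])) == 150.0
        assert len(out) == 4
        assert 450 not in out.df["photons"].to_numpy()
        assert report.rows_removed_photons == 1

    def test_precision_boundary_strict(self, table_factory):
        table = table_factory(np.arange(3.0), np.zeros(3), precision=[5.0, 20.0, 21.0])
        out, report = filter_quality(table)
        assert sorted(out.df["precision_nm"]) == [5.0, 20.0]
        assert report.rows_removed_precision == 1

    def test_count_conservation_and_idempotence(self, rng, table_factory):
        n = 400
        table = table_factory(
            rng.uniform(0, 1000, n), rng.uniform(0, 1000, n),
            photons=rng.normal(3000, 200, n).clip(1),
            sigma=rng.uniform(0.1, 1.8, n),
            precision=rng.uniform(1, 30, n),
        )
        out, rep = filter_quality(table)
        assert rep.rows_out == rep.rows_in - (
            rep.rows_removed_sigma + rep.rows_removed_precision + rep.rows_removed_photons
        )
        again, rep2 = filter_quality(out)
        assert len(again) == len(out)
        assert rep2.rows_out == rep2.rows_in

    def test_all_rows_removed_warns_not_raises(self, table_factory):
        table = table_factory([0.0, 1.0], [0.0, 0.0], sigma=[0.1, 2.0])
        with pytest.warns(UserWarning):
            out, _ = filter_quality(table)
        assert len(out) == 0


class TestLinkLocalizations:
    def test_consecutive_frames_merge_and_sum_photons(self, table_factory):
        table = table_factory([100.0] * 3, [100.0] * 3, frame=[10, 11, 12], photons=[500, 600, 700])
        out = link_localizations(table)
        assert len(out) == 1
        assert out.df.loc[0, "photons"] == 1800
        assert out.df.loc[0, "frame"] == 10
        assert out.df.loc[0, "last_frame"] == 12

    def test_five_dark_frames_allowed_six_not(self, table_factory):
        five = link_localizations(table_factory([0, 0], [0, 0], frame=[10, 16]))
        six = link_localizations(table_factory([0, 0], [0, 0], frame=[10, 17]))
        assert len(five) == 1
        assert len(six) == 2

    def test_radius_contract(self, table_factory):
        # 0.5 px = 80 nm apart at 160 nm/px: outside the 0.3 px radius
        table = table_factory([0.0, 80.0], [0.0, 0.0], frame=[10, 11])
        assert len(link_localizations(table)) == 2

    def test_same_frame_never_merges(self, table_factory):
        table = table_factory([0.0, 1.0], [0.0, 0.0], frame=[5, 5])
        assert len(link_localizations(table)) == 2

    def test_photon_conservation_and_row_count(self, rng, table_factory):
        n = 300
        table = table_factory(
            rng.uniform(0, 2000, n), rng.uniform(0, 2000, n),
            frame=np.sort(rng.integers(0, 500, n)), photons=rng.uniform(100, 1000, n),
        )
        out = link_localizations(table)
        assert len(out) <= n
        assert out.df["photons"].sum() == pytest.approx(table.df["photons"].sum())
        assert out.df["n_merged"].sum() == n

    def test_idempotent(self, rng, table_factory):
        n = 200
        table = table_factory(
            rng.uniform(0, 2000, n), rng.uniform(0, 2000, n),
            frame=rng.integers(0, 1000, n), photons=rng.uniform(100, 1000, n),
        )
        once = link_localizations(table)
        twice = link_localizations(once)
        assert len(twice) == len(once)
        np.testing.assert_allclose(
            np.sort(twice.df["x_nm"].to_numpy()), np.sort(once.df["x_nm"].to_numpy())
        )

    def test_merged_precision_is_member_minimum(self, table_factory):
        table = table_factory([0, 0], [0, 0], frame=[1, 2], precision=[9.0, 4.0])
        out = link_localizations(table)
        assert out.df.loc[0, "precision_nm"] == 4.0


class TestDriftCorrectRCC:
    def test_zero_drift_null(self):
        table = simulate_fiducial_field(n_sites=60, events_per_site=120, n_frames=6000, seed=2)
        corrected, est = drift_correct_rcc(table, 1000)
        assert np.sqrt((est**2).mean()) < 5.0
        # corrected positions stay close to the input
        assert np.abs(corrected.xy - table.xy).max() < 10.0

    def test_linear_drift_recovered(self):
        table = simulate_fiducial_field(n_sites=80, events_per_site=150, n_frames=6000, seed=3)
        drift = linear_drift(6000, 90.0, 0.0)
        df = table.df.copy()
        fr = df["frame"].to_numpy(int)
        df["x_nm"] += drift[fr, 0]
        _, est = drift_correct_rcc(table.with_df(df), 1000)
        assert est[-1, 0] == pytest.approx(90.0, rel=0.10)
        resid = est - drift
        assert np.sqrt((resid**2).mean()) < 10.0

    def test_too_few_frames_rejected(self, table_factory):
        table = table_factory([0.0], [0.0], n_frames=1500)
        with pytest.raises(ParameterError):
            drift_correct_rcc(table, 1000)


class TestChromaticTransform:
    def test_identity_pairs_give_identity(self, rng):
        pts = rng.uniform(0, 40000, (20, 2))
        model = fit_chromatic_transform(pts, pts)
        assert model.fit_rmse_nm < 1e-9
        np.testing.assert_allclose(apply_transform(model, pts), pts, atol=1e-9)

    def test_known_polynomial_recovered_exactly(self, rng):
        coeffs = np.array(
            [[5.0, 1.001, 2e-4, 1e-8, -2e-8, 5e-9], [-3.0, -1e-4, 0.999, 2e-8, 1e-8, -1e-8]]
        )
        moving = rng.uniform(0, 40000, (30, 2))
        x, y = moving[:, 0], moving[:, 1]
        basis = np.column_stack([np.ones_like(x), x, y, x * x, x * y, y * y])
        fixed = np.column_stack([basis @ coeffs[0], basis @ coeffs[1]])
        model = fit_chromatic_transform(fixed, moving)
        assert model.fit_rmse_nm < 1e-6
        np.testing.assert_allclose(model.coefficients_x, coeffs[0], atol=1e-9)
        np.testing.assert_allclose(model.coefficients_y, coeffs[1], atol=1e-9)

    def test_pure_translation(self, rng):
        moving = rng.uniform(0, 10000, (12, 2))
        fixed = moving + [40.0, -20.0]
        model = fit_chromatic_transform(fixed, moving)
        np.testing.assert_allclose(apply_transform(model, moving), fixed, atol=1e-6)

    def test_underdetermined_rejected(self, rng):
        pts = rng.uniform(0, 100, (5, 2))
        with pytest.raises(UnderdeterminedError):
            fit_chromatic_transform(pts, pts)

    def test_collinear_configuration_warns(self):
        x = np.linspace(0, 100, 10)
        pts = np.column_stack([x, 2 * x])
        with pytest.warns(UserWarning):
            fit_chromatic_transform(pts, pts)


class TestResidualOffset:
    def test_known_shift_recovered(self, rng, table_factory):
        base = simulate_fiducial_field(n_sites=50, events_per_site=60, n_frames=3000, seed=4)
        shifted = base.copy()
        shifted.df["x_nm"] += 40.0
        shifted.df["y_nm"] -= 20.0
        corrected, shift, low_conf = correct_residual_offset(base, shifted)
        assert shift[0] == pytest.approx(-40.0, abs=20.0)
        assert shift[1] == pytest.approx(20.0, abs=20.0)
        assert not low_conf
        # corrected table is back on the reference within a render pixel
        assert abs(corrected.df["x_nm"].mean() - base.df["x_nm"].mean()) < 20.0

    def test_zero_shift_for_identical_tables(self):
        base = simulate_fiducial_field(n_sites=50, events_per_site=60, n_frames=3000, seed=5)
        _, shift, low_conf = correct_residual_offset(base, base.copy())
        assert np.abs(shift).max() < 20.0
        assert not low_conf

    def test_unrelated_patterns_flagged_low_confidence(self, rng, table_factory):
        a = table_factory(rng.uniform(0, 3000, 800), rng.uniform(0, 3000, 800))
        b = table_factory(rng.uniform(0, 3000, 800), rng.uniform(0, 3000, 800))
        _, shift, low_conf = correct_residual_offset(a, b)
        assert low_conf

    def test_disjoint_bounding_boxes_rejected(self, table_factory):
        a = table_factory([0.0, 10.0], [0.0, 10.0])
        b = table_factory([5000.0, 5010.0], [5000.0, 5010.0])
        with pytest.raises(InsufficientDataError):
            correct_residual_offset(a, b)
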