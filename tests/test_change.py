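"""Change-map construction, sphere ROIs, and order-of-operations identities."""

import numpy as np
import pytest

from agekernel import (
    ActivationMatrix,
    AgeWeightedSeries,
    GrayMatterMask,
    KernelSpec,
    build_roi_table,
    cross_sectional_change,
    gaussian_weights,
    generate_activation,
    generate_cohort,
    global_curve,
    longitudinal_change,
    roi_change_curves,
    weighted_series,
)
from conftest import linear_truth_config


def full_mask(shape=(4, 4, 4), voxel=3.0):
    return GrayMatterMask(grid_shape=shape, voxel_size_mm=voxel, included=np.ones(shape, bool))


class TestCrossSectionalChange:
    def test_61_row_series_yields_56_change_maps(self):
        series = AgeWeightedSeries(np.arange(20, 81), np.zeros((61, 3)))
        cms = cross_sectional_change(series)
        assert cms.maps.shape == (56, 3)
        assert cms.baseline_ages[0] == 20 and cms.baseline_ages[-1] == 75

    def test_constant_series_gives_zero_change(self):
        series = AgeWeightedSeries(np.arange(20, 81), np.full((61, 2), 4.0))
        assert np.all(cross_sectional_change(series).maps == 0)

    def test_linear_series_gives_lag_slope(self):
        ages = np.arange(20, 81)
        series = AgeWeightedSeries(ages, ages[:, None].astype(float))
        cms = cross_sectional_change(series)
        assert cms.maps == pytest.approx(np.full((56, 1), 5.0))

    def test_too_short_series_rejected(self):
        series = AgeWeightedSeries(np.array([40, 41]), np.zeros((2, 1)))
        with pytest.raises(ValueError):
            cross_sectional_change(series, lag=5)


class TestLongitudinalChange:
    def _matrices(self, n=20, v=6, seed=0):
        rng = np.random.default_rng(seed)
        base = ActivationMatrix(rng.normal(size=(n, v)), np.arange(n))
        ages = rng.integers(20, 81, size=n)
        return base, ages

    def test_identical_timepoints_give_zero(self):
        base, ages = self._matrices()
        cms = longitudinal_change(base, base, ages)
        assert np.all(cms.maps == 0)
        assert cms.baseline_ages[-1] == 75 and len(cms.baseline_ages) == 56

    def test_constant_shift_appears_at_every_age_and_voxel(self):
        base, ages = self._matrices()
        fup = ActivationMatrix(base.values + 3.0, base.participant_ids)
        cms = longitudinal_change(base, fup, ages)
        assert cms.maps == pytest.approx(np.full(cms.maps.shape, 3.0))

    def test_linear_truth_with_cohort_effect_recovers_5_beta(self):
        # f(a) = beta*a and arbitrary cohort slope: D_i == 5*beta for all,
        # so the weighted series is exactly 5*beta -- the cohort term cancels
        beta = 0.8
        cfg = linear_truth_config(slope=beta, cohort_effect=0.3, n=60, grid=(3, 3, 3))
        cohort, truth = generate_cohort(cfg)
        b = generate_activation(cohort, truth, "MEM", "baseline")
        f = generate_activation(cohort, truth, "MEM", "followup")
        cms = longitudinal_change(b, f, cohort.baseline_ages)
        assert cms.maps == pytest.approx(np.full(cms.maps.shape, 5 * beta), abs=1e-10)

    def test_row_misalignment_rejected(self):
        base, ages = self._matrices()
        fup = ActivationMatrix(base.values.copy(), base.participant_ids[::-1])
        with pytest.raises(ValueError):
            longitudinal_change(base, fup, ages)


class TestGlobalCurve:
    def test_single_voxel_curve_is_that_voxel(self):
        from agekernel.change import ChangeMapSeries

        maps = np.array([[1.0], [2.0], [-3.0]])
        cms = ChangeMapSeries(np.array([20, 21, 22]), maps, "cross_sectional")
        assert global_curve(cms).values == pytest.approx([1.0, 2.0, -3.0])

    def test_antisymmetric_voxels_cancel(self):
        from agekernel.change import ChangeMapSeries

        maps = np.array([[2.0, -2.0], [0.5, -0.5]])
        cms = ChangeMapSeries(np.array([20, 21]), maps, "longitudinal")
        assert global_curve(cms).values == pytest.approx([0.0, 0.0])

    def test_hand_computed_row_means(self):
        from agekernel.change import ChangeMapSeries

        cms = ChangeMapSeries(np.array([20, 21]), np.array([[1.0, 3.0], [2.0, 6.0]]), "cross_sectional")
        assert global_curve(cms).values == pytest.approx([2.0, 4.0])

    def test_commutes_with_cross_sectional_subtraction(self):
        # voxel-mean of M(t+5)-M(t) equals mean(M(t+5)) - mean(M(t)) exactly
        rng = np.random.default_rng(4)
        series = AgeWeightedSeries(np.arange(20, 81), rng.normal(size=(61, 9)))
        curve = global_curve(cross_sectional_change(series))
        vox_mean = series.values.mean(axis=1)
        assert curve.values == pytest.approx(vox_mean[5:] - vox_mean[:-5], abs=1e-12)


class TestSphereROIs:
    def test_interior_full_grid_sphere_has_257_voxels(self):
        # independent oracle: brute-force lattice enumeration of offsets
        # with (3i)^2+(3j)^2+(3k)^2 <= 12^2
        expected = sum(
            1
            for i in range(-4, 5)
            for j in range(-4, 5)
            for k in range(-4, 5)
            if 9 * (i * i + j * j + k * k) <= 144
        )
        assert expected == 257
        mask = full_mask(shape=(12, 12, 12))
        rois = build_roi_table(mask, radius_mm=12.0)
        coords = mask.voxel_coordinates
        interior = np.flatnonzero(np.all((coords >= 4) & (coords <= 7), axis=1))
        assert all(len(rois.members[r]) == expected for r in interior)

    def test_isolated_voxel_is_its_own_roi(self):
        inc = np.zeros((9, 9, 9), bool)
        inc[0, 0, 0] = True
        inc[8, 8, 8] = True  # 41.6 mm apart at 3 mm voxels
        mask = GrayMatterMask((9, 9, 9), 3.0, inc)
        rois = build_roi_table(mask, radius_mm=12.0)
        assert all(len(m) == 1 for m in rois.members)

    def test_radius_below_voxel_size_gives_singletons(self):
        rois = build_roi_table(full_mask(), radius_mm=2.0)
        assert all(len(m) == 1 and m[0] == c for m, c in zip(rois.members, rois.centers))

    def test_center_membership_and_radius_invariant(self):
        mask = full_mask(shape=(5, 6, 5))
        rois = build_roi_table(mask, radius_mm=12.0)
        coords = mask.coordinates_mm
        for r in range(rois.n_rois):
            assert rois.centers[r] in rois.members[r]
            d = np.linalg.norm(coords[rois.members[r]] - coords[rois.centers[r]], axis=1)
            assert d.max() <= 12.0 + 1e-9

    def test_anisotropic_voxels_use_mm_distance(self):
        mask = GrayMatterMask((7, 7, 7), (1.0, 2.0, 4.0), np.ones((7, 7, 7), bool))
        rois = build_roi_table(mask, radius_mm=4.0)
        coords = mask.coordinates_mm
        center = rois.centers[rois.n_rois // 2]
        d = np.linalg.norm(coords - coords[center], axis=1)
        assert set(rois.members[rois.n_rois // 2]) == set(np.flatnonzero(d <= 4.0))

    def test_empty_or_bad_radius_rejected(self):
        with pytest.raises(ValueError):
            build_roi_table(full_mask(), radius_mm=0.0)
        with pytest.raises(ValueError):
            GrayMatterMask((3, 3, 3), 3.0, np.zeros((3, 3, 3), bool))


class TestROIChangeCurves:
    def test_singleton_and_uniform_rois(self):
        from agekernel.change import ChangeMapSeries

        mask = full_mask(shape=(2, 2, 1))
        rois = build_roi_table(mask, radius_mm=1.0)  # all singletons
        maps = np.arange(8, dtype=float).reshape(2, 4)
        cms = ChangeMapSeries(np.array([20, 21]), maps, "longitudinal")
        curves = roi_change_curves(cms, rois)
        assert curves == pytest.approx(maps.T)

    def test_two_member_roi_means(self):
        from agekernel.change import ChangeMapSeries, SphereROIs

        mask = full_mask(shape=(2, 1, 1))
        rois = SphereROIs(
            centers=np.array([0]), members=[np.array([0, 1])], radius_mm=5.0, mask=mask
        )
        cms = ChangeMapSeries(np.array([20, 21]), np.array([[1.0, 3.0], [2.0, 6.0]]), "longitudinal")
        assert np.allclose(roi_change_curves(cms, rois), [[2.0, 4.0]])

    def test_equivalence_with_literal_per_roi_order_of_operations(self):
        """Restricting the precomputed change-map series to ROI members must
        match a literal re-implementation that weights each voxel subset
        separately (weight subset -> subtract -> average), both ways."""
        rng = np.random.default_rng(12)
        mask = full_mask(shape=(3, 3, 3))
        n, v = 10, mask.n_voxels
        ages = rng.integers(20, 81, size=n)
        base = ActivationMatrix(rng.normal(size=(n, v)), np.arange(n))
        fup = ActivationMatrix(base.values + rng.normal(size=(n, v)), np.arange(n))
        spec = KernelSpec(target_ages=tuple(range(20, 41)))
        rois = build_roi_table(mask, radius_mm=5.0)

        series = weighted_series(base, ages, spec)
        cross = cross_sectional_change(series)
        longi = longitudinal_change(base, fup, ages, spec)
        fast_cross = roi_change_curves(cross, rois)
        fast_long = roi_change_curves(longi, rois)

        lag = 5
        out_ages = [t for t in spec.target_ages if t + lag <= max(spec.target_ages)]
        for r in range(rois.n_rois):
            members = rois.members[r]
            for a_i, t in enumerate(out_ages):
                # cross-sectional: weight subset at t and t+5, subtract, average voxels
                w_t = gaussian_weights(ages, float(t), spec.sigma).weights
                w_t5 = gaussian_weights(ages, float(t + lag), spec.sigma).weights
                sub = base.values[:, members]
                m_t = (w_t @ sub) / w_t.sum()
                m_t5 = (w_t5 @ sub) / w_t5.sum()
                assert fast_cross[r, a_i] == pytest.approx(np.mean(m_t5 - m_t), abs=1e-10)
                # longitudinal: subtract per participant, weight subset, average voxels
                d = (fup.values - base.values)[:, members]
                assert fast_long[r, a_i] == pytest.approx(np.mean((w_t @ d) / w_t.sum()), abs=1e-10)

    def test_voxel_count_mismatch_rejected(self):
        from agekernel.change import ChangeMapSeries

        rois = build_roi_table(full_mask(shape=(3, 3, 3)))
        cms = ChangeMapSeries(np.array([20]), np.zeros((1, 5)), "longitudinal")
        with pytest.raises(ValueError):
            roi_change_curves(cms, rois)


class TestCohortIdentifiability:
    def test_cross_minus_longitudinal_recovers_cohort_gradient(self):
        """Planted linear f with cohort slope c, noise-free, dense uniform
        ages: longitudinal curve == 5*beta; cross-sectional ~= 5*(beta+c)
        at interior ages; the difference recovers 5c."""
        beta, c = 0.4, 0.25
        cfg = linear_truth_config(
            slope=beta, cohort_effect=c, n=244, grid=(3, 3, 3), seed=21,
            age_sampling="uniform_grid",
        )
        cohort, truth = generate_cohort(cfg)
        ages = cohort.baseline_ages
        b = generate_activation(cohort, truth, "MEM", "baseline")
        f = generate_activation(cohort, truth, "MEM", "followup")
        longi = global_curve(longitudinal_change(b, f, ages))
        cross = global_curve(cross_sectional_change(weighted_series(b, ages)))
        assert longi.values == pytest.approx(np.full(56, 5 * beta), abs=1e-10)
        interior = (longi.baseline_ages >= 30) & (longi.baseline_ages <= 65)
        diff = cross.values - longi.values
        assert diff[interior] == pytest.approx(np.full(interior.sum(), 5 * c), rel=0.05)
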