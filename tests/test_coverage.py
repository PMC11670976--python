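import numpy as np
import pytest
from scipy.spatial.distance import cdist

from neurodrain import coverage as cov
from neurodrain.phantom import PhantomSpec, analytic_profile, make_phantom
from neurodrain.volumes import BinaryMask
from conftest import make_mask, make_volume


def brute_force_touch(drain, ich, spacing):
    """Exhaustive nearest-non-drain search; returns (membership, tie_mask).

    A drain voxel belongs to V iff its nearest non-drain voxel (world mm)
    is ICH.  Voxels whose two nearest non-drain candidates are closer
    than 1e-9 mm apart are marked as ties and excluded from comparison.
    """
    drain = np.asarray(drain, bool)
    ich = np.asarray(ich, bool) & ~drain
    sp = np.asarray(spacing, float)
    drain_idx = np.argwhere(drain)
    non_idx = np.argwhere(~drain)
    non_is_ich = ich[tuple(non_idx.T)]
    d = cdist(drain_idx * sp, non_idx * sp)
    order = np.argsort(d, axis=1)
    nearest = order[:, 0]
    tie = d[np.arange(len(d)), order[:, 1]] - d[np.arange(len(d)), nearest] < 1e-9
    member = non_is_ich[nearest]
    v = np.zeros_like(drain)
    t = np.zeros_like(drain)
    v[tuple(drain_idx.T)] = member
    t[tuple(drain_idx.T)] = tie
    return v, t


class TestTouchVolume:
    def test_fully_surrounded_drain_is_all_touch(self):
        drain = np.zeros((7, 7, 7), bool)
        drain[2:5, 2:5, 2:5] = True
        ich = ~drain
        tv = cov.compute_touch_volume(make_mask(drain), make_mask(ich))
        np.testing.assert_array_equal(tv.mask.data, drain)

    def test_empty_ich_gives_empty_touch(self):
        drain = np.zeros((5, 5, 5), bool)
        drain[2, 2, 1:4] = True
        tv = cov.compute_touch_volume(make_mask(drain),
                                      make_mask(np.zeros((5, 5, 5))))
        assert tv.n_voxels == 0

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grids"):
            cov.compute_touch_volume(make_mask(np.ones((3, 3, 3))),
                                     make_mask(np.ones((4, 4, 4))))

    def test_flanked_column_matches_exhaustive_search(self):
        # 9^3: drain column, ICH on one flank at 1 voxel, background
        # nearest at >= 2 voxels on the other sides
        drain = np.zeros((9, 9, 9), bool)
        drain[4, 4, 3:6] = True
        ich = np.zeros((9, 9, 9), bool)
        ich[5, 4, 2:7] = True
        oracle, tie = brute_force_touch(drain, ich, (1, 1, 1))
        tv = cov.compute_touch_volume(make_mask(drain), make_mask(ich))
        np.testing.assert_array_equal(tv.mask.data[~tie], oracle[~tie])

    @pytest.mark.parametrize("seed,spacing", [
        (0, (1, 1, 1)), (1, (0.5, 0.5, 2.0)), (2, (0.4, 0.45, 3.0)),
    ])
    def test_matches_oracle_on_random_grids(self, seed, spacing):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(6, 13, 3))
        drain = rng.random(shape) < 0.12
        ich = rng.random(shape) < 0.25
        oracle, tie = brute_force_touch(drain, ich, spacing)
        tv = cov.compute_touch_volume(make_mask(drain, spacing),
                                      make_mask(ich, spacing))
        np.testing.assert_array_equal(tv.mask.data[~tie], oracle[~tie])

    def test_touch_always_subset_of_drain(self, rng):
        for _ in range(10):
            drain = rng.random((8, 8, 8)) < 0.3
            ich = rng.random((8, 8, 8)) < 0.3
            tv = cov.compute_touch_volume(make_mask(drain), make_mask(ich))
            assert not np.any(tv.mask.data & ~drain)


class TestPrincipalFrame:
    def test_line_along_z_gives_z_major_axis(self):
        w = np.zeros((9, 9, 31))
        w[4, 4, 3:28] = 1.0
        frame = cov.principal_frame(w, np.eye(4))
        np.testing.assert_allclose(np.abs(frame.axes[0]), [0, 0, 1], atol=1e-12)
        assert frame.eigenvalues[1] == pytest.approx(frame.eigenvalues[2])
        # axes orthonormal
        np.testing.assert_allclose(frame.axes @ frame.axes.T, np.eye(3),
                                   atol=1e-8)

    def test_single_voxel_degenerate(self):
        w = np.zeros((5, 5, 5))
        w[2, 2, 2] = 1.0
        with pytest.raises(ValueError, match="degenerate"):
            cov.principal_frame(w, np.eye(4))

    def test_zero_weight_rejected(self):
        with pytest.raises(ValueError, match="weight"):
            cov.principal_frame(np.zeros((3, 3, 3)), np.eye(4))

    def test_permutation_equivariance(self, rng):
        w = rng.random((6, 7, 8)) * (rng.random((6, 7, 8)) < 0.3)
        w[1, 2, 3] = 1.0  # ensure nonzero
        frame = cov.principal_frame(w, np.eye(4))
        perm = (2, 0, 1)
        frame_p = cov.principal_frame(np.transpose(w, perm), np.eye(4))
        np.testing.assert_allclose(frame_p.eigenvalues, frame.eigenvalues,
                                   atol=1e-9)
        np.testing.assert_allclose(np.abs(frame_p.axes[0]),
                                   np.abs(frame.axes[0][list(perm)]), atol=1e-9)

    def test_near_isotropic_cloud_warns(self, rng):
        w = np.ones((6, 6, 6))
        with pytest.warns(RuntimeWarning, match="degenerate"):
            cov.principal_frame(w, np.eye(4))


class TestRegridAndSmooth:
    def test_constant_volume_unchanged(self):
        vol = make_volume(np.full((6, 6, 6), 0.42), spacing=(1, 1, 2))
        out, aff = cov.regrid_and_smooth(vol)
        np.testing.assert_allclose(out, 0.42, atol=1e-12)
        np.testing.assert_allclose(np.diag(aff)[:3], 0.5)

    def test_impulse_mass_preserved_and_gaussian_shaped(self):
        data = np.zeros((15, 15, 15))
        data[7, 7, 7] = 1.0
        vol = make_volume(data)
        out, aff = cov.regrid_and_smooth(vol)
        in_mass = data.sum() * 1.0 ** 3
        out_mass = out.sum() * 0.5 ** 3
        assert out_mass == pytest.approx(in_mass, rel=0.01)
        # FWHM along an axis ~ combined interp+smoothing width >= 1 mm
        center = np.unravel_index(np.argmax(out), out.shape)
        line = out[center[0], center[1], :]
        half = line >= line.max() / 2
        fwhm = half.sum() * 0.5
        assert 0.9 <= fwhm <= 2.1

    def test_step_edge_width_matches_error_function(self):
        data = np.zeros((9, 9, 40))
        data[:, :, 20:] = 1.0
        out, _ = cov.regrid_and_smooth(make_volume(data))
        line = out[9, 9, :]
        # 25-75% rise distance of a Gaussian-blurred step at sigma 0.4247 mm
        # is 2 * 0.6745 * sigma ~ 0.57 mm; regridding adds a little width
        z = 0.5 * np.arange(len(line))
        z25 = np.interp(0.25, line, z)
        z75 = np.interp(0.75, line, z)
        assert 0.4 <= z75 - z25 <= 1.0


class TestLocateTip:
    def test_deep_end_chosen_as_tip(self):
        spec = PhantomSpec(blur_sigma=0.0, noise_sd=0.0)
        case = make_phantom(spec)
        support = case.gt_drain
        tip, axis = cov.locate_tip(support, np.array([0, 0, 1.0]))
        assert np.linalg.norm(tip - case.truth_tip) < 1.0
        # axis points tip -> entry (+z here)
        assert axis[2] > 0

    def test_override_returned_verbatim(self):
        spec = PhantomSpec(blur_sigma=0.0, noise_sd=0.0)
        case = make_phantom(spec)
        override = np.array([23.0, 23.0, 60.0])   # entry end
        tip, axis = cov.locate_tip(case.gt_drain, np.array([0, 0, 1.0]),
                                   override=override)
        np.testing.assert_array_equal(tip, override)
        assert axis[2] < 0                         # re-signed toward tip end

    def test_tie_break_warns(self):
        data = np.zeros((5, 5, 9), bool)
        data[2, 2, 2:7] = True                     # centered: both ends tie
        with pytest.warns(RuntimeWarning, match="tie"):
            cov.locate_tip(make_mask(data), np.array([0, 0, 1.0]))


class TestCoverageProfile:
    def test_fully_embedded_cylinder_profile_near_one(self):
        spec = PhantomSpec(shape=(56, 56, 64), tip=(27.0, 27.0, 18.0),
                          ich_kind="ellipsoid", ich_center=(27.0, 27.0, 38.0),
                          ich_semi_axes=(22.0, 22.0, 27.0),
                          blur_sigma=0.0, noise_sd=0.0)
        case = make_phantom(spec)
        p = cov.coverage_profile(case.gt_drain, case.gt_ich)
        interior = p.values[(p.positions >= 2)
                            & (p.positions <= p.positions[-1] - 2)]
        assert interior.mean() >= 0.95

    def test_no_ich_profile_identically_zero(self):
        spec = PhantomSpec(ich_kind="none", blur_sigma=0.0, noise_sd=0.0)
        case = make_phantom(spec)
        p = cov.coverage_profile(case.gt_drain, case.gt_ich)
        np.testing.assert_array_equal(p.values, 0.0)
        assert p.frame_source == "drain_fallback"

    def test_half_space_step_profile(self):
        spec = PhantomSpec(embedded_fraction=0.4, blur_sigma=0.0, noise_sd=0.0)
        case = make_phantom(spec)
        p = cov.coverage_profile(case.gt_drain, case.gt_ich)
        truth = analytic_profile(spec)
        n = min(len(p.values), len(truth.values))
        pos = p.positions[:n]
        trans = spec.embedded_fraction * spec.length
        keep = (pos >= 2) & (pos <= spec.length - 2) & (abs(pos - trans) > 2)
        err = np.abs(p.values[:n] - truth.values[:n])
        assert err[keep].mean() <= 0.05
        # transition is sharp: from ~1 to ~0 within 2 mm
        vals, full_pos = p.values, p.positions
        assert vals[full_pos < trans - 2].min() > 0.9
        assert vals[(full_pos > trans + 2)
                    & (full_pos < spec.length - 2)].max() < 0.1

    def test_empty_drain_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cov.coverage_profile(make_mask(np.zeros((4, 4, 4))),
                                 make_mask(np.ones((4, 4, 4))))

    def test_values_bounded(self):
        spec = PhantomSpec(embedded_fraction=0.7, blur_sigma=0.0, noise_sd=0.0)
        case = make_phantom(spec)
        p = cov.coverage_profile(case.gt_drain, case.gt_ich)
        assert np.all(p.values >= 0) and np.all(p.values <= 1)
        assert p.positions[0] == 0.0
        assert len(p.positions) == len(p.values)

    def test_mean_coverage_monotone_in_embedded_fraction(self):
        means = []
        for f in [0.0, 0.3, 0.6, 1.0]:
            spec = PhantomSpec(embedded_fraction=f, blur_sigma=0.0,
                               noise_sd=0.0)
            case = make_phantom(spec)
            p = cov.coverage_profile(case.gt_drain, case.gt_ich)
            means.append(p.values.mean())
        assert all(b >= a - 1e-9 for a, b in zip(means, means[1:]))


class TestProfileFeatures:
    def _profile(self, positions, values):
        return cov.CoverageProfile(np.asarray(positions, float),
                                   np.asarray(values, float),
                                   np.zeros(3), np.array([0, 0, 1.0]))

    def test_constant_profiles(self):
        n = 80
        pos = 0.5 * np.arange(n)
        ones = cov.profile_features(self._profile(pos, np.ones(n)))
        zeros = cov.profile_features(self._profile(pos, np.zeros(n)))
        np.testing.assert_array_equal(ones.values, 1.0)
        np.testing.assert_array_equal(zeros.values, 0.0)
        assert not ones.short_drain_flag

    def test_short_drain_zero_padded_and_flagged(self):
        pos = 0.5 * np.arange(20)          # 10-mm drain
        feats = cov.profile_features(self._profile(pos, 0.8 * np.ones(20)))
        np.testing.assert_allclose(feats.values[:10], 0.8)
        np.testing.assert_array_equal(feats.values[10:], 0.0)
        assert feats.short_drain_flag
        assert len(feats.values) == 15


class TestQuantificationMask:
    def test_identical_components_identity(self):
        data = np.zeros((8, 8, 8))
        data[2:5, 2:5, 2:5] = 0.95
        vol = make_volume(data)
        obj = make_mask(data >= 0.9)
        out = cov.extract_quantification_mask(vol, obj, 0.44)
        np.testing.assert_array_equal(out.data, obj.data)

    def test_lower_threshold_component_is_superset(self):
        data = np.zeros((10, 10, 10))
        data[2:7, 4, 4] = 0.5              # halo at the quantification level
        data[3:5, 4, 4] = 0.95             # detected core
        vol = make_volume(data)
        obj = make_mask(data >= 0.9)
        out = cov.extract_quantification_mask(vol, obj, 0.44)
        assert np.all(out.data[obj.data])  # superset, never smaller
        assert out.data.sum() == 5

    def test_disconnected_noise_not_resurrected(self):
        data = np.zeros((10, 10, 10))
        data[2:4, 2, 2] = 0.95             # real drain
        data[7:9, 7, 7] = 0.6              # noise above 0.44, below 0.9
        vol = make_volume(data)
        obj = make_mask(data >= 0.9)
        out = cov.extract_quantification_mask(vol, obj, 0.44)
        assert not out.data[7:9, 7, 7].any()

    def test_empty_object_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cov.extract_quantification_mask(make_volume(np.zeros((4, 4, 4))),
                                            make_mask(np.zeros((4, 4, 4))))
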