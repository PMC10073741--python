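"""Vorticity, helicity, sigma/TKE, systole-window and Reynolds tests."""

import numpy as np
import pytest

import aortaflow as af
from aortaflow.hemodynamics import HemoParams


def _grid_coords(shape, spacing):
    idx = np.indices(shape).astype(float)
    return idx * spacing  # mm


class TestComputeVorticity:
    def test_solid_body_rotation(self):
        """V = Omega x r about z with Omega=2 -> curl = (0, 0, 4) exactly."""
        shape = (12, 12, 12)
        spacing = 2.0
        x, y, _ = _grid_coords(shape, spacing) / 1000.0  # metres
        omega_rot = 2.0
        v = np.zeros(shape + (3,))
        v[..., 0] = -omega_rot * (y - y.mean())
        v[..., 1] = omega_rot * (x - x.mean())
        mask = np.ones(shape, dtype=bool)
        vort = af.compute_vorticity(v, mask, spacing)
        interior = vort.defined
        np.testing.assert_allclose(vort.omega[interior, 2], 4.0, atol=1e-9)
        np.testing.assert_allclose(vort.omega[interior, :2], 0.0, atol=1e-9)

    def test_uniform_translation_zero_curl(self):
        shape = (8, 8, 8)
        v = np.ones(shape + (3,))
        vort = af.compute_vorticity(v, np.ones(shape, dtype=bool), 2.5)
        np.testing.assert_allclose(vort.omega[vort.defined], 0.0, atol=1e-12)

    def test_poiseuille_vorticity_magnitude(self, straight_phantom):
        """|omega| = 2 W0 r / R^2 for a parabolic axial profile."""
        spec, data, gt = straight_phantom
        w = spec.temporal_waveform[0]
        vort = af.compute_vorticity(data.velocity[0], gt.lumen_mask, data.voxel_spacing)
        vox = np.argwhere(gt.lumen_mask) * spec.voxel_spacing
        r = np.linalg.norm(vox[:, :2] - gt.points[0, :2], axis=1) / 1000.0
        R = spec.lumen_radius / 1000.0
        W0 = spec.peak_axial_velocity * w
        # vorticity of the swirl adds an axial component; compare azimuthal part
        # on voxels whose 6 neighbours are all in-mask (central differences)
        from scipy import ndimage

        core = ndimage.binary_erosion(
            gt.lumen_mask, structure=ndimage.generate_binary_structure(3, 1)
        )
        expected_az = 2 * W0 * r / R**2
        interior = core[gt.lumen_mask] & (r > 0)
        observed_az = np.linalg.norm(vort.omega[gt.lumen_mask][:, :2], axis=1)
        np.testing.assert_allclose(
            observed_az[interior], expected_az[interior], rtol=0.02, atol=1e-9
        )

    def test_undefined_flagged_not_zero_filled(self, straight_phantom):
        spec, data, gt = straight_phantom
        vort = af.compute_vorticity(data.velocity[0], gt.lumen_mask, data.voxel_spacing)
        assert not vort.defined[~gt.lumen_mask].any()


class TestComputeLnh:
    def _forced_vortex_plug(self, swirl=1.0):
        spec = af.PhantomSpec(
            geometry_kind="straight",
            geometry_params={"length": 80.0},
            axial_profile="plug",
            swirl_ratio=swirl,
            lumen_radius=8.0,
            n_timeframes=2,
            snr=np.inf,
            voxel_spacing=2.0,
        )
        data, gt = af.generate_phantom(spec)
        return spec, data, gt

    def test_closed_form_forced_vortex(self):
        """Plug axial + forced vortex: LNH = W / sqrt(W^2 + (Omega r)^2);
        where Omega r = W it equals 1/sqrt(2)."""
        spec, data, gt = self._forced_vortex_plug(swirl=1.0)
        w = spec.temporal_waveform[0]
        vort = af.compute_vorticity(data.velocity[0], gt.lumen_mask, data.voxel_spacing)
        lnh, defined = af.compute_lnh(data.velocity[0], vort)
        vox = np.argwhere(gt.lumen_mask) * spec.voxel_spacing
        r = np.linalg.norm(vox[:, :2] - gt.points[0, :2], axis=1)
        W = spec.peak_axial_velocity * w
        omega_r = spec.swirl_ratio * spec.peak_axial_velocity * w * (r / spec.lumen_radius)
        expected = W / np.sqrt(W**2 + omega_r**2)
        interior = defined[gt.lumen_mask] & (r < 0.75 * spec.lumen_radius)
        np.testing.assert_allclose(
            lnh[gt.lumen_mask][interior], expected[interior], rtol=0.02
        )
        # voxels where the swirl speed matches the axial speed: LNH = 1/sqrt(2)
        match = interior & (np.abs(omega_r - W) < 0.05 * W)
        if match.any():
            np.testing.assert_allclose(
                lnh[gt.lumen_mask][match], 1 / np.sqrt(2), rtol=0.05
            )

    def test_pure_poiseuille_lnh_zero(self):
        """Axial parabolic flow: velocity is orthogonal to the azimuthal
        vorticity, so LNH vanishes on every defined voxel."""
        spec = af.PhantomSpec(
            geometry_kind="straight",
            geometry_params={"length": 80.0},
            swirl_ratio=0.0,
            n_timeframes=2,
            snr=np.inf,
        )
        data, gt = af.generate_phantom(spec)
        vort = af.compute_vorticity(data.velocity[0], gt.lumen_mask, data.voxel_spacing)
        lnh, defined = af.compute_lnh(data.velocity[0], vort)
        sel = defined & gt.lumen_mask
        assert sel.any()
        assert np.abs(lnh[sel]).max() < 1e-9

    def test_on_axis_lnh_approaches_one(self):
        spec, data, gt = self._forced_vortex_plug(swirl=1.0)
        vort = af.compute_vorticity(data.velocity[0], gt.lumen_mask, data.voxel_spacing)
        lnh, defined = af.compute_lnh(data.velocity[0], vort)
        vox = np.argwhere(gt.lumen_mask) * spec.voxel_spacing
        r = np.linalg.norm(vox[:, :2] - gt.points[0, :2], axis=1)
        near_axis = defined[gt.lumen_mask] & (r < 0.3 * spec.voxel_spacing)
        if near_axis.any():
            assert lnh[gt.lumen_mask][near_axis].min() > 0.99

    def test_lnh_in_unit_interval_random_fields(self):
        rng = np.random.default_rng(7)
        shape = (10, 10, 10)
        v = rng.normal(0, 1, shape + (3,))
        mask = rng.random(shape) > 0.3
        vort = af.compute_vorticity(v, mask, 2.5)
        lnh, defined = af.compute_lnh(v, vort)
        assert lnh[defined].min() >= 0.0
        assert lnh[defined].max() <= 1.0

    def test_orthogonality_oracle(self):
        """Explicitly constructed V ⊥ omega pairs give LNH = 0 exactly."""
        rng = np.random.default_rng(11)
        v = rng.normal(0, 1, (100, 3))
        w = np.cross(v, rng.normal(0, 1, (100, 3)))  # w ⊥ v by construction
        dot = np.abs(np.einsum("ij,ij->i", v, w))
        denom = np.linalg.norm(v, axis=1) * np.linalg.norm(w, axis=1)
        lnh = dot / denom
        np.testing.assert_allclose(lnh, 0.0, atol=1e-12)


class TestSigmaAndTke:
    def test_equal_magnitudes_zero_sigma(self):
        mags = np.full((4, 3, 3, 3), 50.0)
        sigma2, defined = af.compute_sigma_squared(mags, 1.5)
        assert defined.all()
        np.testing.assert_allclose(sigma2, 0.0, atol=1e-15)

    def test_known_attenuation_recovers_sigma(self):
        kv = np.pi / 1.5
        mags = np.full((4, 2, 2, 2), 100.0)
        mags[1:] *= np.exp(-(kv**2) * 0.01 / 2)
        sigma2, _ = af.compute_sigma_squared(mags, 1.5)
        np.testing.assert_allclose(sigma2, 0.01, rtol=1e-12)

    def test_negative_sigma_squared_when_encoded_exceeds_reference(self):
        mags = np.full((4, 2, 2, 2), 100.0)
        mags[1] = 105.0  # noise pushed |S_i| above |S|
        sigma2, _ = af.compute_sigma_squared(mags, 1.5)
        assert (sigma2[0] < 0).all()
        tke = af.compute_tke(sigma2)
        assert (tke < 0).all()

    def test_tke_value_and_cancellation(self):
        sigma2 = np.full((3, 2, 2, 2), 0.01)
        tke = af.compute_tke(sigma2, HemoParams())
        np.testing.assert_allclose(tke, 0.5 * 1060 * 0.03)
        np.testing.assert_allclose(tke, 15.9, rtol=1e-12)
        mixed = np.stack([np.full((2,), 0.01), np.full((2,), -0.01), np.zeros(2)])
        np.testing.assert_allclose(af.compute_tke(mixed), 0.0, atol=1e-12)


class TestFindPeakSystole:
    def _dataset(self, n_frames, waveform=None):
        shape = (4, 4, 4)
        wf = waveform if waveform is not None else np.ones(n_frames)
        velocity = np.zeros((n_frames,) + shape + (3,))
        velocity[..., 2] = wf[:, None, None, None]
        return af.FlowDataset(
            velocity=velocity,
            magnitudes=np.full((n_frames, 4) + shape, 10.0),
            venc=1.5,
            voxel_spacing=2.5,
            timeframe_fractions=np.arange(n_frames) / n_frames,
        )

    def test_window_is_five_frames_of_forty(self):
        wf = np.ones(40)
        wf[12] = 2.0
        data = self._dataset(40, wf)
        peak, window = af.find_peak_systole(data, np.ones((4, 4, 4), bool))
        assert peak == 12
        assert list(window) == [10, 11, 12, 13, 14]

    def test_constant_waveform_tie_break(self):
        data = self._dataset(8)
        peak, _ = af.find_peak_systole(data, np.ones((4, 4, 4), bool))
        assert peak == 0

    def test_single_frame(self):
        data = self._dataset(1)
        peak, window = af.find_peak_systole(data, np.ones((4, 4, 4), bool))
        assert peak == 0
        assert list(window) == [0]

    @pytest.mark.parametrize("n", [10, 20, 21, 40, 33])
    def test_window_covers_ten_percent_of_cycle(self, n):
        wf = np.ones(n)
        wf[n // 2] = 2.0
        data = self._dataset(n, wf)
        _, window = af.find_peak_systole(data, np.ones((4, 4, 4), bool))
        assert int(np.floor(0.1 * n)) <= len(window) <= int(np.ceil(0.1 * n)) + 1

    def test_cyclic_window_wraps(self):
        wf = np.ones(20)
        wf[0] = 2.0
        data = self._dataset(20, wf)
        _, window = af.find_peak_systole(data, np.ones((4, 4, 4), bool))
        assert set(window) == {0, 1, 19}


class TestComputeReynolds:
    def test_zero_velocity(self):
        assert af.compute_reynolds(0.0, 20.0) == 0.0

    def test_reference_value(self):
        assert af.compute_reynolds(1.0, 20.0) == pytest.approx(6057.14, rel=1e-4)

    def test_young_whole_aorta_scale(self):
        """Velocity 0.74 m/s and diameter 18 mm give Re ~ 4000, the scale
        reported for healthy young whole aortas."""
        re = af.compute_reynolds(0.74, 18.0)
        assert re == pytest.approx(4033, rel=0.01)
        assert 3697 < re < 4323

    def test_linear_in_velocity_and_diameter(self):
        base = af.compute_reynolds(0.5, 15.0)
        assert af.compute_reynolds(1.0, 15.0) == pytest.approx(2 * base)
        assert af.compute_reynolds(0.5, 30.0) == pytest.approx(2 * base)


class TestAggregateRegionalMetrics:
    def test_tke_roundtrip_through_regions(self):
        """Noise-free phantom with sigma = 0.1: every region reports
        TKE = 15.9 J/m^3 to machine precision (ground-truth partition)."""
        spec = af.PhantomSpec(sigma_level=0.1, venc=1.5, n_timeframes=6, snr=np.inf, seed=0)
        data, gt = af.generate_phantom(spec)
        mask = SegmentationMask = af.SegmentationMask(
            mask=gt.lumen_mask, voxel_spacing=spec.voxel_spacing
        )
        cl = gt.centerline
        lms = af.landmarks_from_positions(cl, gt.landmarks_xyz)
        part = af.partition_regions(cl, lms, mask=mask)
        geo = af.region_geometry(cl, lms, part, mask)
        table = af.aggregate_regional_metrics(data, part, geo)
        np.testing.assert_allclose(table["tke"], 15.9, rtol=1e-12)

    def test_helicity_monotone_in_swirl(self):
        vals = {}
        for swirl in (0.0, 1.0):
            spec = af.PhantomSpec(swirl_ratio=swirl, n_timeframes=6, snr=np.inf, seed=0)
            data, gt = af.generate_phantom(spec)
            mask = af.SegmentationMask(mask=gt.lumen_mask, voxel_spacing=spec.voxel_spacing)
            cl = gt.centerline
            lms = af.landmarks_from_positions(cl, gt.landmarks_xyz)
            part = af.partition_regions(cl, lms, mask=mask)
            geo = af.region_geometry(cl, lms, part, mask)
            table = af.aggregate_regional_metrics(data, part, geo).set_index("region")
            vals[swirl] = table["helicity"]
        assert (vals[1.0] > vals[0.0]).all()
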