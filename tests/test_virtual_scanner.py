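"""Virtual acquisition: partial-volume voxelization, frames, venc noise."""

import numpy as np
import pytest

from flowres.flow_model import VesselModel
from flowres.virtual_scanner import (
    AcquisitionSettings,
    acquire,
    add_noise,
    load_hdf5,
    load_nifti,
    save_hdf5,
    save_nifti,
    velocity_noise_sigma,
)


def uniform_field(points, t):
    return np.tile([0.0, 1.0, 0.0], (np.atleast_2d(points).shape[0], 1))


def linear_field(points, t):
    """v_y = 1 + 3x + 5z: mean over any point set = value at the centroid."""
    p = np.atleast_2d(points)
    v = np.zeros_like(p)
    v[:, 1] = 1.0 + 3.0 * p[:, 0] + 5.0 * p[:, 2]
    return v


@pytest.fixture(scope="module")
def small_vessel():
    return VesselModel(radius=0.0125, length=0.012)


class TestSettings:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(voxel_size=0),
            dict(temporal_resolution=-1),
            dict(venc=0),
            dict(subsamples_per_axis=1),
            dict(grid_offset=(0.0, 1.0, 0.0)),
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            AcquisitionSettings(**kwargs)

    def test_unit_conversions(self):
        s = AcquisitionSettings(voxel_size=2.0, temporal_resolution=35.0, venc=150.0)
        assert s.voxel_size_m == 2e-3
        assert s.dt_s == 0.035
        assert s.venc_ms == 1.5


class TestAcquire:
    def test_frame_count_is_floor_of_period_over_dt(self, small_vessel):
        s = AcquisitionSettings(voxel_size=4.0, temporal_resolution=35.0)
        vox = acquire(uniform_field, small_vessel, s, 0.9)
        assert vox.dimensions[3] == 25  # floor(900/35)
        s42 = AcquisitionSettings(voxel_size=4.0, temporal_resolution=42.0)
        assert acquire(uniform_field, small_vessel, s42, 0.9).dimensions[3] == 21

    def test_interior_voxel_reads_uniform_field_exactly(self, small_vessel):
        s = AcquisitionSettings(voxel_size=2.0)
        vox = acquire(uniform_field, small_vessel, s, 0.9, frame_times=[0.0])
        interior = vox.magnitude == 1.0
        assert interior.any()
        assert np.all(vox.velocity[interior, 0, 1] == 1.0)
        assert np.all(vox.velocity[interior, 0, 0] == 0.0)

    def test_exterior_voxel_is_zero(self, small_vessel):
        s = AcquisitionSettings(voxel_size=2.0)
        vox = acquire(uniform_field, small_vessel, s, 0.9, frame_times=[0.0])
        outside = vox.magnitude == 0.0
        assert outside.any()
        assert np.all(vox.velocity[outside] == 0.0)

    def test_half_covered_voxel_has_magnitude_half(self):
        # wall locally planar: tube radius 10 voxels, boundary through a
        # voxel-centre column (grid offset 0 puts centres at half-voxel
        # positions, so choose the centre so the wall bisects a voxel)
        h = 2e-3
        vessel = VesselModel(radius=10 * h, length=4 * h, center=(-10 * h, 0.0, 0.0))
        s = AcquisitionSettings(voxel_size=2.0, grid_offset=(0.5, 0.0, 0.0))
        vox = acquire(uniform_field, vessel, s, 0.9, frame_times=[0.0])
        x = vox.voxel_centers_1d(0)
        i = int(np.argmin(np.abs(x)))  # column whose centre sits on the wall
        assert abs(x[i]) < 1e-12
        k = int(np.argmin(np.abs(vox.voxel_centers_1d(2))))
        j = vox.velocity.shape[1] // 2
        assert vox.magnitude[i, j, k] == pytest.approx(0.5, abs=1e-12)

    def test_linear_field_centroid_oracle_without_dilution(self, small_vessel):
        """Undiluted mode: voxel value = field at the lumen-subsample centroid."""
        s = AcquisitionSettings(voxel_size=2.0, grid_offset=(0.3, 0.1, 0.7),
                                signal_dilution=False)
        vox = acquire(linear_field, small_vessel, s, 0.9, frame_times=[0.0])
        h = s.voxel_size_m
        m = s.subsamples_per_axis
        sub = ((np.arange(m) + 0.5) / m - 0.5) * h
        got = checked = 0
        for i, j, k in zip(*np.nonzero(vox.magnitude)):
            cx = vox.origin[0] + (i + 0.5) * h
            cy = vox.origin[1] + (j + 0.5) * h
            cz = vox.origin[2] + (k + 0.5) * h
            px, py, pz = np.meshgrid(cx + sub, cy + sub, cz + sub, indexing="ij")
            pts = np.column_stack([px.ravel(), py.ravel(), pz.ravel()])
            rel = pts - small_vessel.center_array
            ax = rel @ small_vessel.axis_array
            rad = np.linalg.norm(rel - np.outer(ax, small_vessel.axis_array), axis=1)
            inside = (rad <= small_vessel.radius) & (np.abs(ax) <= small_vessel.length / 2)
            centroid = pts[inside].mean(axis=0)
            expected = 1.0 + 3.0 * centroid[0] + 5.0 * centroid[2]
            assert vox.velocity[i, j, k, 0, 1] == pytest.approx(expected, abs=1e-10)
            checked += 1
        assert checked > 50

    def test_dilution_scales_rim_voxels_by_lumen_fraction(self, small_vessel):
        s_on = AcquisitionSettings(voxel_size=2.0, grid_offset=(0.3, 0.1, 0.7))
        s_off = AcquisitionSettings(voxel_size=2.0, grid_offset=(0.3, 0.1, 0.7),
                                    signal_dilution=False)
        von = acquire(uniform_field, small_vessel, s_on, 0.9, frame_times=[0.0])
        voff = acquire(uniform_field, small_vessel, s_off, 0.9, frame_times=[0.0])
        lumen = von.magnitude > 0
        assert np.allclose(
            von.velocity[lumen, 0, 1],
            voff.velocity[lumen, 0, 1] * von.magnitude[lumen],
            atol=1e-14,
        )

    def test_max_voxel_speed_bounded_by_field_max(self, field, vessel):
        s = AcquisitionSettings(voxel_size=4.0)
        vox = acquire(field, vessel, s, 0.9)
        peak = vox.speed().max()
        r = np.linspace(0, vessel.radius, 800)
        analytic_max = max(np.abs(field.profile(r, t)).max() for t in vox.frame_times)
        assert peak <= analytic_max

    def test_max_speed_error_shrinks_with_voxel_size(self, poiseuille_field, poiseuille_vessel):
        """Mean peak-speed error decreases monotonically 4 -> 3 -> 2 -> 1.5 mm."""
        errors = []
        for res in (4.0, 3.0, 2.0, 1.5):
            errs = []
            for i in range(20):
                off = tuple(np.random.default_rng(i).random(3))
                s = AcquisitionSettings(voxel_size=res, grid_offset=off)
                vox = acquire(poiseuille_field, poiseuille_vessel, s, 0.9, frame_times=[0.0])
                errs.append(1.0 - vox.speed().max())  # analytic max is 1 m/s
            errors.append(np.mean(errs))
        assert all(e > 0 for e in errors)
        assert all(a > b for a, b in zip(errors, errors[1:]))


class TestNoise:
    def test_sigma_closed_form(self):
        s = AcquisitionSettings(venc=150.0, snr=30.0)
        assert velocity_noise_sigma(s) == pytest.approx(np.sqrt(2) * 1.5 / (np.pi * 30), rel=1e-12)
        assert velocity_noise_sigma(s) == pytest.approx(0.02251, abs=5e-5)

    def test_infinite_snr_is_identity(self, small_vessel):
        s = AcquisitionSettings(voxel_size=3.0, snr=np.inf)
        vox = acquire(uniform_field, small_vessel, s, 0.9, frame_times=[0.0])
        assert add_noise(vox) is vox

    def test_missing_snr_rejected(self, small_vessel):
        s = AcquisitionSettings(voxel_size=3.0)
        vox = acquire(uniform_field, small_vessel, s, 0.9, frame_times=[0.0])
        with pytest.raises(ValueError):
            add_noise(vox)

    def test_seeded_noise_is_reproducible_and_lumen_only(self, small_vessel):
        s = AcquisitionSettings(voxel_size=3.0, snr=30.0, seed=11)
        vox = acquire(uniform_field, small_vessel, s, 0.9, frame_times=[0.0, 0.1])
        n1, n2 = add_noise(vox), add_noise(vox)
        assert np.array_equal(n1.velocity, n2.velocity)
        assert not np.array_equal(n1.velocity, vox.velocity)
        outside = vox.magnitude == 0
        assert np.all(n1.velocity[outside] == 0.0)

    def test_noise_is_zero_mean_with_stated_sigma(self, small_vessel):
        s = AcquisitionSettings(voxel_size=2.0, snr=30.0, seed=5)
        vox = acquire(uniform_field, small_vessel, s, 0.9, frame_times=list(np.arange(10) * 0.05))
        noisy = add_noise(vox)
        delta = (noisy.velocity - vox.velocity)[vox.magnitude > 0]
        sigma = velocity_noise_sigma(s)
        assert abs(delta.mean()) < 5 * sigma / np.sqrt(delta.size)
        assert delta.std() == pytest.approx(sigma, rel=0.05)


class TestIO:
    def test_hdf5_roundtrip(self, tmp_path, small_vessel):
        s = AcquisitionSettings(voxel_size=3.0, snr=25.0, grid_offset=(0.2, 0.0, 0.4), seed=9)
        vox = acquire(uniform_field, small_vessel, s, 0.9, frame_times=[0.0, 0.1])
        p = tmp_path / "scan.h5"
        save_hdf5(vox, p)
        back = load_hdf5(p)
        assert np.array_equal(back.velocity, vox.velocity)
        assert np.array_equal(back.magnitude, vox.magnitude)
        assert back.settings == vox.settings
        assert back.period == vox.period

    def test_nifti_roundtrip(self, tmp_path, small_vessel):
        s = AcquisitionSettings(voxel_size=3.0, temporal_resolution=35.0)
        vox = acquire(uniform_field, small_vessel, s, 0.9)
        prefix = str(tmp_path / "scan")
        paths = save_nifti(vox, prefix)
        assert len(paths) == 4
        back = load_nifti(prefix, s, 0.9)
        assert np.allclose(back.velocity, vox.velocity)
        assert np.allclose(back.magnitude, vox.magnitude)
        assert np.allclose(back.origin, vox.origin)
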