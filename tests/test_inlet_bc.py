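"""Inlet-plane extraction, polynomial surface fits, and flow rate."""

import numpy as np
import pytest

from flowres.errors import EmptyRegionError, InsufficientSamplesError
from flowres.geometry import PlaneRole, PlaneSpec, segment
from flowres.inlet_bc import (
    InletFit,
    InletSampleSet,
    evaluate_fit,
    extract_inlet_samples,
    fit_inlet_surface,
    flow_rate,
    flow_rate_from_fit,
    load_fit_text,
    monomial_exponents,
    save_fit_text,
    save_flow_csv,
)
from flowres.virtual_scanner import AcquisitionSettings, Voxel4DFlow, acquire


@pytest.fixture()
def uniform_vox():
    """Hand-built 9x3x9 grid: 25-voxel square lumen, 26 frames, v_y = 1."""
    nx = nz = 9
    ny, nf = 3, 26
    magnitude = np.zeros((nx, ny, nz))
    magnitude[2:7, :, 2:7] = 1.0
    velocity = np.zeros((nx, ny, nz, nf, 3))
    velocity[2:7, :, 2:7, :, 1] = 1.0
    return Voxel4DFlow(
        origin=np.zeros(3),
        voxel_size=2.0,
        velocity=velocity,
        magnitude=magnitude,
        frame_times=(np.arange(nf) + 0.5) * (0.9 / 26),
        settings=AcquisitionSettings(voxel_size=2.0),
        period=0.9,
    )


@pytest.fixture()
def uniform_samples(uniform_vox):
    mask = segment(uniform_vox, 0.5)
    return extract_inlet_samples(uniform_vox, mask, PlaneSpec(3e-3, PlaneRole.INLET))


class TestExtract:
    def test_record_counts(self, uniform_samples):
        assert uniform_samples.n_points == 25
        assert uniform_samples.n_frames == 26
        assert uniform_samples.velocity.shape == (25, 26)

    def test_uniform_field_values(self, uniform_samples):
        assert np.all(uniform_samples.velocity == 1.0)

    def test_empty_plane_raises(self, uniform_vox):
        mask = segment(uniform_vox, 0.5)
        mask.mask[:] = False
        with pytest.raises(EmptyRegionError):
            extract_inlet_samples(uniform_vox, mask, PlaneSpec(3e-3))

    def test_poiseuille_samples_match_voxel_average_oracle(
        self, poiseuille_field, poiseuille_vessel, fine_poiseuille_vox
    ):
        """Extracted values equal an independently recomputed subsample mean."""
        vox = fine_poiseuille_vox
        mask = segment(vox, 0.5)
        plane = PlaneSpec(0.0)
        samples = extract_inlet_samples(vox, mask, plane)
        j = mask.slice_index(plane)
        h = vox.voxel_size_m
        m = vox.settings.subsamples_per_axis
        sub = ((np.arange(m) + 0.5) / m - 0.5) * h
        y = vox.voxel_centers_1d(1)[j]
        rng = np.random.default_rng(0)
        for idx in rng.choice(samples.n_points, 40, replace=False):
            x, z = samples.x[idx], samples.z[idx]
            px, py, pz = np.meshgrid(x + sub, y + sub, z + sub, indexing="ij")
            pts = np.column_stack([px.ravel(), py.ravel(), pz.ravel()])
            r = np.hypot(pts[:, 0], pts[:, 2])
            inside = (r <= poiseuille_vessel.radius) & (
                np.abs(pts[:, 1]) <= poiseuille_vessel.length / 2
            )
            u = np.where(inside, poiseuille_field.profile(np.clip(r, 0, poiseuille_vessel.radius), 0.0), 0.0)
            oracle = u[inside].sum() / pts.shape[0]  # dilution: zero-extended mean
            assert samples.velocity[idx, 0] == pytest.approx(oracle, abs=1e-6)


def _samples_from_function(func, n_side=9, radius=0.0125, n_frames=2):
    s = np.linspace(-radius, radius, n_side)
    gx, gz = np.meshgrid(s, s, indexing="ij")
    keep = np.hypot(gx, gz) <= radius
    x, z = gx[keep], gz[keep]
    vals = np.tile(func(x, z)[:, None], (1, n_frames))
    return InletSampleSet(
        x=x,
        z=z,
        velocity=vals,
        frame_times=np.linspace(0.1, 0.5, n_frames),
        voxel_size=(s[1] - s[0]) * 1e3,  # declared pitch matches the grid
        period=0.9,
    )


class TestFit:
    def test_quadratic_surface_is_reproduced_exactly(self):
        R = 0.0125
        samples = _samples_from_function(lambda x, z: 1 - (x**2 + z**2) / R**2)
        fit = fit_inlet_surface(samples, degree=2)
        got = evaluate_fit(fit, samples.x, samples.z, samples.frame_times[0])
        assert np.allclose(got, samples.velocity[:, 0], rtol=1e-10, atol=1e-12)

    def test_constant_samples_give_constant_fit(self):
        samples = _samples_from_function(lambda x, z: 0.37 * np.ones_like(x))
        fit = fit_inlet_surface(samples, degree=3)
        pts = np.array([0.0, 2e-3, -4e-3])
        got = evaluate_fit(fit, pts, pts, samples.frame_times[1])
        assert np.allclose(got, 0.37, rtol=1e-10)

    def test_underdetermined_frame_raises(self):
        samples = _samples_from_function(lambda x, z: x + z, n_side=3)  # < 15 points
        assert samples.n_points < 15
        with pytest.raises(InsufficientSamplesError):
            fit_inlet_surface(samples, degree=4)

    def test_normal_equations_oracle(self):
        """lstsq solution matches an explicit normal-equations solve."""
        rng = np.random.default_rng(4)
        samples = _samples_from_function(lambda x, z: np.sin(300 * x) + z * 80)
        samples.velocity[:, 0] += rng.normal(0, 0.05, samples.n_points)
        fit = fit_inlet_surface(samples, degree=3)
        cx, cz = fit.center
        terms = monomial_exponents(3)
        A = np.column_stack(
            [((samples.x - cx) / fit.scale) ** a * ((samples.z - cz) / fit.scale) ** b for a, b in terms]
        )
        oracle = np.linalg.solve(A.T @ A, A.T @ samples.velocity[:, 0])
        assert np.allclose(fit.coefficients[0], oracle, rtol=1e-8)


class TestEvaluate:
    def test_frame_time_returns_that_frame(self):
        samples = _samples_from_function(lambda x, z: x * 100)
        samples.velocity[:, 1] = 5.0
        fit = fit_inlet_surface(samples, degree=1)
        v0 = evaluate_fit(fit, 1e-3, 0.0, samples.frame_times[0])
        assert v0 == pytest.approx(0.1, rel=1e-8)

    def test_outside_lumen_clamps_to_zero(self):
        samples = _samples_from_function(lambda x, z: np.ones_like(x))
        fit = fit_inlet_surface(samples, degree=1)
        assert evaluate_fit(fit, 10 * fit.lumen_radius, 0.0, 0.2) == 0.0

    def test_midway_time_interpolates_linearly(self):
        samples = _samples_from_function(lambda x, z: np.ones_like(x))
        samples.velocity[:, 0] = 0.2
        samples.velocity[:, 1] = 0.4
        fit = fit_inlet_surface(samples, degree=0)
        t_mid = samples.frame_times.mean()
        assert evaluate_fit(fit, 0.0, 0.0, t_mid) == pytest.approx(0.3, rel=1e-12)

    def test_time_wraps_cyclically(self):
        samples = _samples_from_function(lambda x, z: np.ones_like(x))
        fit = fit_inlet_surface(samples, degree=0)
        a = evaluate_fit(fit, 0.0, 0.0, 0.25)
        b = evaluate_fit(fit, 0.0, 0.0, 0.25 + fit.period)
        assert a == pytest.approx(b, rel=1e-12)


class TestFlowRate:
    def test_uniform_voxel_sum(self, uniform_samples):
        q = flow_rate(uniform_samples)
        assert q.shape == (26,)
        assert np.allclose(q, 25 * (2e-3) ** 2)

    def test_zero_frame_gives_zero(self, uniform_samples):
        uniform_samples.velocity[:, 3] = 0.0
        assert flow_rate(uniform_samples)[3] == 0.0

    def test_poiseuille_fine_voxels_within_two_percent(
        self, fine_poiseuille_vox, poiseuille_vessel
    ):
        mask = segment(fine_poiseuille_vox, 0.5)
        samples = extract_inlet_samples(fine_poiseuille_vox, mask, PlaneSpec(0.0))
        q = flow_rate(samples)[0]
        q_true = 0.5 * np.pi * poiseuille_vessel.radius**2  # U_max = 1 m/s
        assert q == pytest.approx(q_true, rel=0.02)
        assert q == pytest.approx(2.454e-4, rel=0.02)

    def test_fit_based_integral_is_close_but_distinct(self):
        samples = _samples_from_function(lambda x, z: 1 - (x**2 + z**2) / 0.0125**2)
        fit = fit_inlet_surface(samples, degree=2)
        q_fit = flow_rate_from_fit(fit)
        q_vox = flow_rate(samples)
        assert q_fit[0] == pytest.approx(q_vox[0], rel=0.25)
        assert q_fit[0] != q_vox[0]


class TestFitQualityVsResolution:
    def test_coarse_scans_fit_worse_on_parabolic_inflow(
        self, poiseuille_field, poiseuille_vessel
    ):
        """Degree-4 surface-fit RMS error vs the analytic field is larger at
        4 mm than at 1.5 mm (10 seeded grid offsets, steady parabolic flow)."""
        plane = PlaneSpec(0.0, PlaneRole.INLET)
        rms = {}
        for res in (4.0, 1.5):
            errs = []
            for i in range(10):
                off = tuple(np.random.default_rng(i).random(3))
                s = AcquisitionSettings(voxel_size=res, grid_offset=off)
                vox = acquire(poiseuille_field, poiseuille_vessel, s, 0.9, frame_times=[0.0])
                samples = extract_inlet_samples(vox, segment(vox, 0.5), plane)
                fit = fit_inlet_surface(samples, degree=4)
                r = np.linspace(0, poiseuille_vessel.radius * 0.98, 60)
                ang = np.linspace(0, 2 * np.pi, 24, endpoint=False)
                gx = np.outer(r, np.cos(ang)).ravel()
                gz = np.outer(r, -np.sin(ang)).ravel()
                u_fit = evaluate_fit(fit, gx, gz, float(vox.frame_times[0]))
                u_true = poiseuille_field.profile(np.hypot(gx, gz), 0.0)
                errs.append(np.sqrt(np.mean((u_fit - u_true) ** 2)))
            rms[res] = np.mean(errs)
        assert rms[4.0] > rms[1.5]


def test_fit_text_roundtrip(tmp_path):
    samples = _samples_from_function(lambda x, z: x * 50 + z**2 * 1e4)
    fit = fit_inlet_surface(samples, degree=2)
    p = tmp_path / "fit.txt"
    save_fit_text(fit, p)
    back = load_fit_text(p)
    assert back.degree == fit.degree
    assert np.allclose(back.coefficients, fit.coefficients, rtol=0, atol=0)
    assert back.lumen_radius == fit.lumen_radius
    pts = np.linspace(-0.01, 0.01, 7)
    assert np.allclose(
        evaluate_fit(back, pts, pts, 0.3), evaluate_fit(fit, pts, pts, 0.3)
    )


def test_flow_csv_export(tmp_path, uniform_samples):
    q = flow_rate(uniform_samples)
    p = tmp_path / "q.csv"
    save_flow_csv(uniform_samples.frame_times, q, p)
    data = np.loadtxt(p, delimiter=",", skiprows=1)
    assert np.allclose(data[:, 1], q)
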