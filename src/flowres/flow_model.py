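"""Analytic pulsatile flow in a rigid straight tube (Womersley solution).

This module provides the ground-truth velocity field for the resolution
study: a periodic volumetric inflow waveform Q(t), its Fourier (harmonic)
decomposition, and the resulting axial velocity profile u(r, t) in a rigid
circular tube.  The flow-driven form of the Womersley solution is used: each
harmonic is normalised so that the cross-section integral of the profile
reproduces that harmonic's flow amplitude exactly, and the steady (k = 0)
component is plain Poiseuille flow.

The field doubles as both "scan subject" and "model solution" in the
cross-resolution comparisons: its closed-form wall shear stress and
centreline velocity are the reference values that the voxelised estimates
are measured against.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from scipy.special import jv

__all__ = [
    "FluidProperties",
    "VesselModel",
    "FlowWaveform",
    "HarmonicDecomposition",
    "BLOOD",
    "make_waveform",
    "decompose",
    "womersley_number",
    "velocity_profile",
    "analytic_wss",
    "WomersleyField",
    "save_waveform_csv",
    "load_waveform_csv",
]


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian fluid constants.

    Parameters
    ----------
    density : float
        Mass density in kg m^-3.
    dynamic_viscosity : float
        Dynamic viscosity mu in Pa s.
    """

    density: float
    dynamic_viscosity: float

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError("density must be positive")
        if self.dynamic_viscosity <= 0:
            raise ValueError("dynamic_viscosity must be positive")

    @property
    def kinematic_viscosity(self) -> float:
        """nu = mu / rho in m^2 s^-1."""
        return self.dynamic_viscosity / self.density


#: Blood treated as incompressible and Newtonian at body temperature.
BLOOD = FluidProperties(density=1060.0, dynamic_viscosity=3.5e-3)


@dataclass(frozen=True)
class VesselModel:
    """A rigid straight tube standing in for the ascending aorta.

    The default radius corresponds to a 25.15 mm mid-ascending-aortic
    diameter.  ``axis`` is the flow direction (default +y); ``center`` is
    the tube midpoint.
    """

    radius: float = 0.012575
    axis: tuple[float, float, float] = (0.0, 1.0, 0.0)
    length: float = 0.05
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.length <= 0:
            raise ValueError("length must be positive")
        a = np.asarray(self.axis, dtype=float)
        if abs(np.linalg.norm(a) - 1.0) > 1e-12:
            raise ValueError("axis must be a unit vector")

    @property
    def axis_array(self) -> np.ndarray:
        return np.asarray(self.axis, dtype=float)

    @property
    def center_array(self) -> np.ndarray:
        return np.asarray(self.center, dtype=float)


@dataclass(frozen=True)
class FlowWaveform:
    """A periodic volumetric inflow waveform sampled over one cycle.

    ``sample_times`` lie in [0, period) and the waveform is treated as
    periodic: values at arbitrary t are interpreted at t mod period.
    """

    period: float
    sample_times: np.ndarray
    flow_values: np.ndarray
    peak_flow: float
    systolic_fraction: float
    end_diastolic_flow: float

    def __post_init__(self) -> None:
        t = np.asarray(self.sample_times, dtype=float)
        q = np.asarray(self.flow_values, dtype=float)
        if self.period <= 0:
            raise ValueError("period must be positive")
        if t.ndim != 1 or t.size != q.size:
            raise ValueError("sample_times and flow_values must be 1-D and equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("sample_times must be strictly increasing")
        if t[0] < 0 or t[-1] >= self.period:
            raise ValueError("sample_times must lie in [0, period)")
        object.__setattr__(self, "sample_times", t)
        object.__setattr__(self, "flow_values", q)

    def __call__(self, t: float | np.ndarray) -> np.ndarray:
        """Periodic linear interpolation of the sampled waveform."""
        tw = np.mod(np.asarray(t, dtype=float), self.period)
        tp = np.concatenate([self.sample_times, [self.sample_times[0] + self.period]])
        qp = np.concatenate([self.flow_values, [self.flow_values[0]]])
        return np.interp(tw, tp, qp)


@dataclass(frozen=True)
class HarmonicDecomposition:
    """Truncated Fourier series of a flow waveform.

    Q(t) = Re{ sum_k Q_k exp(i k omega t) }, k = 0..K, with Q_0 real (the
    time-average flow) and ``complex_amplitudes[k]`` = Q_k in m^3 s^-1.
    """

    fundamental_angular_frequency: float
    complex_amplitudes: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        amps = np.asarray(self.complex_amplitudes, dtype=complex)
        if amps.ndim != 1 or amps.size < 1:
            raise ValueError("complex_amplitudes must be a non-empty 1-D array")
        if self.fundamental_angular_frequency <= 0:
            raise ValueError("fundamental angular frequency must be positive")
        object.__setattr__(self, "complex_amplitudes", amps)

    @property
    def period(self) -> float:
        return 2.0 * np.pi / self.fundamental_angular_frequency

    @property
    def n_harmonics(self) -> int:
        """Number of oscillatory harmonics (excludes the steady term)."""
        return self.complex_amplitudes.size - 1

    def reconstruct(self, t: float | np.ndarray) -> np.ndarray:
        """Evaluate the truncated series Q(t) at times ``t``."""
        t = np.asarray(t, dtype=float)
        k = np.arange(self.complex_amplitudes.size)
        phases = np.exp(1j * np.multiply.outer(t, k) * self.fundamental_angular_frequency)
        return np.real(phases @ self.complex_amplitudes)


def make_waveform(
    peak_flow: float = 2.45e-4,
    period: float = 0.9,
    systolic_fraction: float = 0.35,
    end_diastolic_flow: float = 1e-5,
    n_samples: int = 128,
) -> FlowWaveform:
    """Construct a smooth periodic inflow waveform with a single systolic peak.

    The shape is a raised half-sine-squared bump over the systolic window
    [0, systolic_fraction * period] sitting on a constant diastolic baseline:
    Q rises from ``end_diastolic_flow`` to ``peak_flow`` and back, then stays
    at the baseline through diastole.  Both bump halves have zero slope at
    their ends, so the waveform is C^1 and periodic.  The bump is centred on
    the sample time closest to mid-systole so that ``max(flow_values)``
    equals ``peak_flow`` exactly on the stored grid.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    if n_samples < 8:
        raise ValueError("n_samples must be at least 8")
    if not 0 < systolic_fraction < 1:
        raise ValueError("systolic_fraction must lie in (0, 1)")
    if not peak_flow > end_diastolic_flow >= 0:
        raise ValueError("require peak_flow > end_diastolic_flow >= 0")

    t = np.arange(n_samples) * period / n_samples
    t_sys = systolic_fraction * period
    # snap the peak instant onto the sample grid (keeps the stored maximum
    # exactly equal to peak_flow regardless of n_samples)
    dt = period / n_samples
    t_peak = np.clip(round(0.5 * t_sys / dt) * dt, dt, t_sys - dt)

    q = np.full(n_samples, end_diastolic_flow, dtype=float)
    amp = peak_flow - end_diastolic_flow
    rising = t <= t_peak
    falling = (t > t_peak) & (t < t_sys)
    q[rising] += amp * np.sin(0.5 * np.pi * t[rising] / t_peak) ** 2
    q[falling] += amp * np.sin(0.5 * np.pi * (t_sys - t[falling]) / (t_sys - t_peak)) ** 2
    return FlowWaveform(
        period=period,
        sample_times=t,
        flow_values=q,
        peak_flow=peak_flow,
        systolic_fraction=systolic_fraction,
        end_diastolic_flow=end_diastolic_flow,
    )


def decompose(waveform: FlowWaveform, n_harmonics: int = 8) -> HarmonicDecomposition:
    """Fourier-decompose a waveform into K oscillatory harmonics plus the mean.

    Non-uniformly sampled waveforms are resampled onto a uniform grid by
    periodic linear interpolation before the DFT.
    """
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")
    t = waveform.sample_times
    q = waveform.flow_values
    n = t.size
    uniform = np.allclose(np.diff(t), waveform.period / n, rtol=0, atol=1e-12 * waveform.period)
    if not uniform:
        tu = np.arange(n) * waveform.period / n
        q = waveform(tu)
    if n_harmonics > (n - 1) // 2:
        raise ValueError(
            f"n_harmonics={n_harmonics} exceeds the Nyquist limit {(n - 1) // 2} "
            f"of {n} samples per cycle"
        )
    coeffs = np.fft.rfft(q) / n
    amps = np.empty(n_harmonics + 1, dtype=complex)
    amps[0] = coeffs[0].real
    amps[1:] = 2.0 * coeffs[1 : n_harmonics + 1]
    return HarmonicDecomposition(
        fundamental_angular_frequency=2.0 * np.pi / waveform.period,
        complex_amplitudes=amps,
    )


def womersley_number(radius: float, angular_frequency: float, kinematic_viscosity: float) -> float:
    """alpha = R sqrt(omega / nu), the ratio of tube radius to the oscillatory
    boundary-layer thickness."""
    if radius < 0 or angular_frequency < 0:
        raise ValueError("radius and angular_frequency must be non-negative")
    if kinematic_viscosity <= 0:
        raise ValueError("kinematic_viscosity must be positive")
    return radius * np.sqrt(angular_frequency / kinematic_viscosity)


_I32 = np.power(1j, 1.5)  # i^(3/2) = exp(3i pi / 4)


def _harmonic_terms(decomp, vessel, fluid):
    """Per-harmonic (Lambda_k, normalisation D_k) for k >= 1."""
    omega = decomp.fundamental_angular_frequency
    nu = fluid.kinematic_viscosity
    k = np.arange(1, decomp.complex_amplitudes.size)
    alpha = womersley_number(vessel.radius, omega, nu) * np.sqrt(k)
    lam = _I32 * alpha
    denom = 1.0 - 2.0 * jv(1, lam) / (lam * jv(0, lam))
    return lam, denom


def velocity_profile(
    decomp: HarmonicDecomposition,
    vessel: VesselModel,
    fluid: FluidProperties,
    r: float | np.ndarray,
    t: float | np.ndarray,
) -> np.ndarray:
    """Axial velocity u(r, t) in m s^-1 of the flow-driven Womersley solution.

    The steady harmonic contributes a Poiseuille profile
    2 Q_0 / (pi R^2) (1 - (r/R)^2); each oscillatory harmonic k contributes

        Re{ (Q_k / (pi R^2)) [1 - J0(L r/R)/J0(L)] / [1 - 2 J1(L)/(L J0(L))]
            e^{i k omega t} },   L = i^(3/2) alpha_k,

    which integrates over the cross-section to exactly Re{Q_k e^{i k omega t}}.

    ``r`` and ``t`` broadcast against each other; the result is real.
    """
    r = np.asarray(r, dtype=float)
    t = np.asarray(t, dtype=float)
    R = vessel.radius
    if np.any(r < 0) or np.any(r > R * (1 + 1e-12)):
        raise ValueError("r must lie within [0, R]")
    rho = np.clip(r / R, 0.0, 1.0)
    area = np.pi * R**2
    amps = decomp.complex_amplitudes
    u = (2.0 * amps[0].real / area) * (1.0 - rho**2) * np.ones_like(t)
    if amps.size > 1:
        lam, denom = _harmonic_terms(decomp, vessel, fluid)
        omega = decomp.fundamental_angular_frequency
        for k in range(1, amps.size):
            shape = (1.0 - jv(0, lam[k - 1] * rho) / jv(0, lam[k - 1])) / denom[k - 1]
            u = u + np.real((amps[k] / area) * shape * np.exp(1j * k * omega * t))
    return u


def analytic_wss(
    decomp: HarmonicDecomposition,
    vessel: VesselModel,
    fluid: FluidProperties,
    t: float | np.ndarray,
) -> np.ndarray:
    """Wall shear stress tau(t) = -mu du/dr |_{r=R} in Pa.

    Uses dJ0(L r/R)/dr = -(L/R) J1(L r/R); the steady part is the Poiseuille
    value 4 mu Q_0 / (pi R^3).  Positive values point with the flow.
    """
    t = np.asarray(t, dtype=float)
    R = vessel.radius
    area = np.pi * R**2
    amps = decomp.complex_amplitudes
    mu = fluid.dynamic_viscosity
    dudr = (-4.0 * amps[0].real / (area * R)) * np.ones_like(t)
    if amps.size > 1:
        lam, denom = _harmonic_terms(decomp, vessel, fluid)
        omega = decomp.fundamental_angular_frequency
        for k in range(1, amps.size):
            grad_shape = (lam[k - 1] / R) * jv(1, lam[k - 1]) / jv(0, lam[k - 1]) / denom[k - 1]
            dudr = dudr + np.real((amps[k] / area) * grad_shape * np.exp(1j * k * omega * t))
    return -mu * dudr


class WomersleyField:
    """Continuous 3-component velocity sampler for a Womersley tube flow.

    Evaluates ``axis * u(r, t)`` at arbitrary 3-D points, zero outside the
    lumen.  For bulk sampling (the virtual scanner feeds ~10^5 points per
    frame) the radial profile at each requested time is tabulated once on a
    dense radius grid and then linearly interpolated; the tabulation reuses
    precomputed complex mode shapes, so per-frame cost is a phase sum plus
    one 1-D interpolation.  ``radial_samples=None`` disables the cache and
    evaluates Bessel functions directly at every point.
    """

    def __init__(
        self,
        decomp: HarmonicDecomposition,
        vessel: VesselModel,
        fluid: FluidProperties,
        radial_samples: int | None = 4096,
    ):
        self.decomp = decomp
        self.vessel = vessel
        self.fluid = fluid
        self.radial_samples = radial_samples
        self._r_grid = None
        self._modes = None
        if radial_samples is not None:
            if radial_samples < 16:
                raise ValueError("radial_samples must be >= 16 (or None)")
            R = vessel.radius
            self._r_grid = np.linspace(0.0, R, radial_samples)
            rho = self._r_grid / R
            area = np.pi * R**2
            amps = decomp.complex_amplitudes
            modes = np.zeros((amps.size, radial_samples), dtype=complex)
            modes[0] = (2.0 * amps[0].real / area) * (1.0 - rho**2)
            if amps.size > 1:
                lam, denom = _harmonic_terms(decomp, vessel, fluid)
                for k in range(1, amps.size):
                    shape = (1.0 - jv(0, lam[k - 1] * rho) / jv(0, lam[k - 1])) / denom[k - 1]
                    modes[k] = (amps[k] / area) * shape
            self._modes = modes

    def profile(self, r: np.ndarray, t: float) -> np.ndarray:
        """Axial velocity at radii ``r`` and a single time ``t``."""
        if self._modes is None:
            return velocity_profile(self.decomp, self.vessel, self.fluid, r, t)
        omega = self.decomp.fundamental_angular_frequency
        k = np.arange(self._modes.shape[0])
        phases = np.exp(1j * k * omega * t)
        u_grid = np.real(phases @ self._modes)
        return np.interp(np.asarray(r, dtype=float), self._r_grid, u_grid)

    def __call__(self, points: np.ndarray, t: float) -> np.ndarray:
        """Velocity vectors (N, 3) at Cartesian ``points`` (N, 3), time ``t``."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        rel = points - self.vessel.center_array
        axial = rel @ self.vessel.axis_array
        radial_vec = rel - np.outer(axial, self.vessel.axis_array)
        r = np.linalg.norm(radial_vec, axis=1)
        inside = (r <= self.vessel.radius) & (np.abs(axial) <= self.vessel.length / 2)
        u = np.zeros(points.shape[0])
        if np.any(inside):
            u[inside] = self.profile(r[inside], t)
        return np.outer(u, self.vessel.axis_array)

    def wall_shear_stress(self, t: float | np.ndarray) -> np.ndarray:
        return analytic_wss(self.decomp, self.vessel, self.fluid, t)

    def flow_rate(self, t: float | np.ndarray) -> np.ndarray:
        return self.decomp.reconstruct(t)


def save_waveform_csv(waveform: FlowWaveform, path) -> None:
    """Write a two-column CSV (time_s, flow_m3s)."""
    data = np.column_stack([waveform.sample_times, waveform.flow_values])
    header = "time_s,flow_m3s"
    np.savetxt(path, data, delimiter=",", header=header, comments="", fmt="%.17g")


def load_waveform_csv(path, period: float | None = None) -> FlowWaveform:
    """Read a two-column CSV (time_s, flow_m3s).

    If ``period`` is omitted it is inferred by extrapolating the mean sample
    spacing one step past the last sample.
    """
    if isinstance(path, (str, bytes)) or hasattr(path, "__fspath__"):
        raw = np.loadtxt(path, delimiter=",", skiprows=1)
    else:  # file-like
        raw = np.loadtxt(io.StringIO(path.read()), delimiter=",", skiprows=1)
    t, q = raw[:, 0], raw[:, 1]
    if period is None:
        period = t[-1] + np.mean(np.diff(t))
    return FlowWaveform(
        period=float(period),
        sample_times=t,
        flow_values=q,
        peak_flow=float(q.max()),
        systolic_fraction=float("nan"),
        end_diastolic_flow=float(q.min()),
    )
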