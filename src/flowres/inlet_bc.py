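"""Inlet-plane velocity extraction, surface fitting, and flow rate.

The inlet boundary condition of the model side of the study is built by
extracting through-plane velocities at every lumen voxel of the inlet
slice, fitting a bivariate polynomial surface per time frame, and
interpolating the per-frame fits linearly in time.  Coarse scans leave few
sample points on the plane, which bounds the polynomial degree and drives
the interpolation error that the resolution comparison measures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import EmptyRegionError, InsufficientSamplesError
from .geometry import LumenMask, PlaneSpec
from .virtual_scanner import Voxel4DFlow

__all__ = [
    "InletSampleSet",
    "InletFit",
    "extract_inlet_samples",
    "fit_inlet_surface",
    "evaluate_fit",
    "flow_rate",
    "flow_rate_from_fit",
    "save_fit_text",
    "load_fit_text",
    "save_flow_csv",
]

log = logging.getLogger(__name__)


@dataclass
class InletSampleSet:
    """Through-plane velocities at lumen voxel centres on the inlet plane.

    x, z are the in-plane voxel-centre coordinates (m), shared by all
    frames; velocity has shape (n_points, n_frames) in m s^-1.
    """

    x: np.ndarray
    z: np.ndarray
    velocity: np.ndarray
    frame_times: np.ndarray
    voxel_size: float  # mm
    period: float

    @property
    def n_points(self) -> int:
        return self.x.size

    @property
    def n_frames(self) -> int:
        return self.frame_times.size

    @property
    def voxel_size_m(self) -> float:
        return self.voxel_size * 1e-3


def monomial_exponents(degree: int) -> list[tuple[int, int]]:
    """Exponent pairs (a, b) with a + b <= degree, lexicographic order."""
    return [(a, b) for a in range(degree + 1) for b in range(degree + 1 - a)]


def _design_matrix(x, z, degree):
    terms = monomial_exponents(degree)
    return np.column_stack([x**a * z**b for a, b in terms])


@dataclass
class InletFit:
    """Per-frame polynomial surface fits with a no-slip lumen clamp.

    coefficients has shape (n_frames, n_terms) over the monomial basis
    x'^a z'^b (a + b <= degree, lexicographic) in centred/scaled coordinates
    x' = (x - center_x)/scale, z' = (z - center_z)/scale.  Evaluation
    outside ``lumen_radius`` of the centre returns 0; times interpolate
    linearly (and cyclically) between frames.
    """

    degree: int
    coefficients: np.ndarray
    frame_times: np.ndarray
    period: float
    center: tuple[float, float]
    scale: float
    lumen_radius: float

    def evaluate(self, x, z, t):
        return evaluate_fit(self, x, z, t)


def extract_inlet_samples(
    vox: Voxel4DFlow, mask: LumenMask, plane: PlaneSpec
) -> InletSampleSet:
    """One record per lumen voxel of the plane's slice per frame.

    The through-plane component is the velocity projection on the vessel
    (y) axis.
    """
    sl = mask.slice_mask(plane)  # raises EmptyRegionError when empty
    j = mask.slice_index(plane)
    ii, kk = np.nonzero(sl)
    x = vox.voxel_centers_1d(0)[ii]
    z = vox.voxel_centers_1d(2)[kk]
    v_axial = vox.velocity[ii, j, kk, :, 1]  # (n_points, n_frames)
    return InletSampleSet(
        x=x,
        z=z,
        velocity=v_axial,
        frame_times=vox.frame_times,
        voxel_size=vox.voxel_size,
        period=vox.period,
    )


def fit_inlet_surface(samples: InletSampleSet, degree: int = 4) -> InletFit:
    """Ordinary least squares of each frame's samples onto x^a z^b, a+b <= degree.

    Coordinates are centred on the sample centroid and scaled by the sample
    radius for conditioning.  Degenerate (rank-deficient) systems take the
    minimum-norm solution and are logged.  Raises
    :class:`InsufficientSamplesError` when a frame has fewer points than
    basis terms — the failure mode of very coarse scans.
    """
    n_terms = (degree + 1) * (degree + 2) // 2
    if samples.n_points < n_terms:
        raise InsufficientSamplesError(
            f"{samples.n_points} sample points cannot constrain the "
            f"{n_terms} terms of a degree-{degree} surface"
        )
    cx, cz = float(samples.x.mean()), float(samples.z.mean())
    radius = float(np.hypot(samples.x - cx, samples.z - cz).max())
    scale = radius if radius > 0 else 1.0
    A = _design_matrix((samples.x - cx) / scale, (samples.z - cz) / scale, degree)
    coeffs, _, rank, _ = np.linalg.lstsq(A, samples.velocity, rcond=None)
    if rank < n_terms:
        log.warning(
            "rank-deficient inlet fit (rank %d < %d terms); minimum-norm solution used",
            rank,
            n_terms,
        )
    lumen_radius = radius + samples.voxel_size_m / 2
    return InletFit(
        degree=degree,
        coefficients=coeffs.T.copy(),  # (n_frames, n_terms)
        frame_times=samples.frame_times.copy(),
        period=samples.period,
        center=(cx, cz),
        scale=scale,
        lumen_radius=lumen_radius,
    )


def evaluate_fit(fit: InletFit, x, z, t: float) -> np.ndarray:
    """Surface value at in-plane points and time t (wrapped into the cycle).

    Linear interpolation between the two bracketing frames' polynomial
    values; hard no-slip clamp (0) outside the lumen radius.
    """
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    tw = float(np.mod(t, fit.period))
    times = fit.frame_times
    n = times.size
    j1 = int(np.searchsorted(times, tw, side="right"))
    j0 = j1 - 1
    if j0 < 0:  # before the first frame centre: wrap to the last frame
        t0, t1 = times[-1] - fit.period, times[0]
        j0, j1 = n - 1, 0
    elif j1 == n:  # after the last frame centre
        t0, t1 = times[-1], times[0] + fit.period
        j0, j1 = n - 1, 0
    else:
        t0, t1 = times[j0], times[j1]
    w = 0.0 if t1 == t0 else (tw - t0) / (t1 - t0)
    coeffs = (1.0 - w) * fit.coefficients[j0] + w * fit.coefficients[j1]
    cx, cz = fit.center
    A = _design_matrix((x - cx) / fit.scale, (z - cz) / fit.scale, fit.degree)
    values = A @ coeffs
    outside = np.hypot(x - cx, z - cz) > fit.lumen_radius
    return np.where(outside, 0.0, values)


def flow_rate(samples: InletSampleSet) -> np.ndarray:
    """Per-frame volumetric flow rate by voxel-sum Riemann integration.

    Q(frame) = sum over slice voxels of (through-plane velocity x voxel
    face area), in m^3 s^-1 — the most literal voxel-data estimate, and the
    default.  See :func:`flow_rate_from_fit` for the surface-fit variant.
    """
    if samples.n_points == 0:
        raise EmptyRegionError("no samples to integrate")
    return samples.velocity.sum(axis=0) * samples.voxel_size_m**2


def flow_rate_from_fit(fit: InletFit, resolution: int = 200) -> np.ndarray:
    """Per-frame flow rate by integrating the fitted surface over its lumen disc.

    Provided as an alternative to the voxel-sum estimate; the two differ by
    the fit's interpolation error and by the disc-versus-voxelised domain.
    """
    cx, cz = fit.center
    r = fit.lumen_radius
    s = np.linspace(-r, r, resolution)
    dx = s[1] - s[0]
    gx, gz = np.meshgrid(cx + s, cz + s, indexing="ij")
    out = np.empty(fit.frame_times.size)
    for j, t in enumerate(fit.frame_times):
        vals = evaluate_fit(fit, gx.ravel(), gz.ravel(), float(t))
        out[j] = vals.sum() * dx * dx
    return out


def save_fit_text(fit: InletFit, path) -> None:
    """Structured-text export: degree, domain, frame times, coefficients
    (lexicographic monomial order, 17 significant digits)."""
    with open(path, "w") as f:
        f.write(f"degree {fit.degree}\n")
        f.write(f"period_s {fit.period:.17g}\n")
        f.write(f"center_m {fit.center[0]:.17g} {fit.center[1]:.17g}\n")
        f.write(f"scale_m {fit.scale:.17g}\n")
        f.write(f"lumen_radius_m {fit.lumen_radius:.17g}\n")
        f.write("monomials " + " ".join(f"x^{a}z^{b}" for a, b in monomial_exponents(fit.degree)) + "\n")
        for t, row in zip(fit.frame_times, fit.coefficients):
            f.write(f"t {t:.17g} " + " ".join(f"{c:.17g}" for c in row) + "\n")


def load_fit_text(path) -> InletFit:
    with open(path) as f:
        lines = [ln.split() for ln in f if ln.strip()]
    fields = {ln[0]: ln[1:] for ln in lines if ln[0] != "t"}
    rows = [ln[1:] for ln in lines if ln[0] == "t"]
    times = np.array([float(r[0]) for r in rows])
    coeffs = np.array([[float(c) for c in r[1:]] for r in rows])
    return InletFit(
        degree=int(fields["degree"][0]),
        coefficients=coeffs,
        frame_times=times,
        period=float(fields["period_s"][0]),
        center=(float(fields["center_m"][0]), float(fields["center_m"][1])),
        scale=float(fields["scale_m"][0]),
        lumen_radius=float(fields["lumen_radius_m"][0]),
    )


def save_flow_csv(frame_times: np.ndarray, flow: np.ndarray, path) -> None:
    """Write Q(t) as CSV (frame_time_s, flow_m3s)."""
    data = np.column_stack([frame_times, flow])
    np.savetxt(path, data, delimiter=",", header="frame_time_s,flow_m3s", comments="", fmt="%.17g")
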