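"""Phase windows and plane-level metrics: velocity extrema and sector WSS.

Systolic metrics average the peak-flow frame and its two neighbours;
diastolic metrics average every low-flow frame.  Wall shear stress is
estimated at eight equally spaced wall locations of an analysis plane from
the near-wall through-plane velocity gradient — the same estimator is
applied to the continuous reference field (densely sampled) and to voxel
data (sampled at the voxel pitch), so that the comparison isolates the
effect of resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .errors import DegenerateRayError, EmptyRegionError
from .flow_model import FluidProperties, VesselModel
from .geometry import LumenMask, PlaneSpec
from .virtual_scanner import Voxel4DFlow

__all__ = [
    "SECTOR_LABELS",
    "sector_directions",
    "PhaseWindows",
    "PlaneMetrics",
    "WSSProfile",
    "phase_windows",
    "plane_metrics",
    "plane_metrics_analytic",
    "wss_sectors",
    "save_wss_csv",
    "save_metrics_csv",
    "plot_wss_polar",
]

log = logging.getLogger(__name__)

#: Sector labels every 45 degrees: right (+x), right-anterior, anterior (-z),
#: left-anterior, left, left-posterior, posterior, right-posterior.
SECTOR_LABELS = ("R", "RA", "A", "LA", "L", "LP", "P", "RP")


def sector_directions() -> np.ndarray:
    """Unit in-plane direction per sector, shape (8, 3).

    R points along +x and A along -z (radiological anterior); the plane
    normal is the vessel (y) axis.
    """
    theta = np.deg2rad(np.arange(8) * 45.0)
    return np.column_stack([np.cos(theta), np.zeros(8), -np.sin(theta)])


@dataclass(frozen=True)
class PhaseWindows:
    """Frame-index windows for the two cardiac phases (disjoint)."""

    systolic_frames: tuple[int, ...]
    diastolic_frames: tuple[int, ...]

    def __post_init__(self) -> None:
        if set(self.systolic_frames) & set(self.diastolic_frames):
            raise ValueError("systolic and diastolic windows must be disjoint")


@dataclass(frozen=True)
class PlaneMetrics:
    """Phase-averaged velocity extrema over an analysis plane."""

    max_velocity: float
    mean_velocity: float
    phase: str

    def __post_init__(self) -> None:
        if not 0 <= self.mean_velocity <= self.max_velocity + 1e-15:
            raise ValueError("require 0 <= mean_velocity <= max_velocity")


@dataclass(frozen=True)
class WSSProfile:
    """Wall shear stress magnitude (Pa) per sector label."""

    sectors: Mapping[str, float]
    phase: str

    def __post_init__(self) -> None:
        if set(self.sectors) != set(SECTOR_LABELS):
            raise ValueError("sectors must carry exactly the 8 standard labels")
        if any(v < 0 for v in self.sectors.values()):
            raise ValueError("WSS magnitudes must be non-negative")

    def values(self) -> np.ndarray:
        return np.array([self.sectors[lbl] for lbl in SECTOR_LABELS])


def phase_windows(flow: Sequence[float], diastole_fraction: float = 0.2) -> PhaseWindows:
    """Split the cycle into systolic and diastolic frame windows.

    The systolic window is the peak-flow frame and the frames immediately
    before and after (cyclically wrapped).  The diastolic window runs from
    the first post-peak frame whose flow drops below
    ``diastole_fraction * peak`` through the end of the cycle, minus any
    systolic frames.  Ties on the maximum break to the earliest frame.
    """
    q = np.asarray(flow, dtype=float)
    n = q.size
    if n < 5:
        raise ValueError("need at least 5 frames to window the cycle")
    peak = int(np.argmax(q))
    if np.sum(q == q[peak]) > 1:
        log.warning("multiple equal flow maxima; using the earliest frame %d", peak)
    systolic = tuple(sorted({(peak - 1) % n, peak, (peak + 1) % n}))
    cutoff = diastole_fraction * q[peak]
    start = None
    for j in range(peak + 1, n):
        if q[j] < cutoff:
            start = j
            break
    diastolic = () if start is None else tuple(
        j for j in range(start, n) if j not in systolic
    )
    return PhaseWindows(systolic_frames=systolic, diastolic_frames=diastolic)


def plane_metrics(
    vox: Voxel4DFlow,
    mask: LumenMask,
    plane: PlaneSpec,
    window: Sequence[int],
    phase: str = "",
) -> PlaneMetrics:
    """Max and mean phase-averaged speed over the plane's lumen voxels.

    Per-voxel speeds are averaged across the window frames first
    (magnitude-then-average), then reduced over the slice.
    """
    window = tuple(window)
    if not window:
        raise ValueError("window must be non-empty")
    sl = mask.slice_mask(plane)
    j = mask.slice_index(plane)
    ii, kk = np.nonzero(sl)
    speeds = np.linalg.norm(vox.velocity[ii, j, kk][:, window, :], axis=-1)
    averaged = speeds.mean(axis=1)
    return PlaneMetrics(
        max_velocity=float(averaged.max()),
        mean_velocity=float(averaged.mean()),
        phase=phase,
    )


def plane_metrics_analytic(
    field,
    times: Sequence[float],
    phase: str = "",
    n_radial: int = 1024,
) -> PlaneMetrics:
    """Reference plane metrics evaluated directly on a tube-flow field.

    Mirrors :func:`plane_metrics`: per-radius speeds are time-averaged over
    the window first, then the maximum and the area-weighted mean are taken
    over the cross-section disc.
    """
    R = field.vessel.radius
    r = np.linspace(0.0, R, n_radial)
    speeds = np.abs(np.stack([field.profile(r, float(t)) for t in times]))
    averaged = speeds.mean(axis=0)
    mean = 2.0 * np.trapezoid(averaged * r, r) / R**2
    return PlaneMetrics(max_velocity=float(averaged.max()), mean_velocity=float(mean), phase=phase)


def _ray_wss(radii: np.ndarray, velocities: np.ndarray, mu: float) -> float:
    """mu * |slope| of the straight line through (radius, velocity) samples."""
    slope = np.polyfit(radii, velocities, 1)[0]
    return mu * abs(slope)


def wss_sectors(
    source,
    vessel: VesselModel,
    plane: PlaneSpec,
    window,
    fluid: FluidProperties,
    fit_points: int = 3,
    spacing: float | None = None,
    phase: str = "",
) -> WSSProfile:
    """Eight-sector WSS from the near-wall through-plane velocity gradient.

    For each of 8 rays at 45 degree spacing, the through-plane velocity is
    sampled at ``fit_points`` wall-inward positions (R - j*spacing,
    j = 1..fit_points), a straight line is fitted, and
    WSS = mu * |slope at wall|, averaged over the window.

    ``source`` may be a continuous field callable ``f(points, t) -> (N, 3)``
    (then ``window`` is a sequence of times and ``spacing`` defaults to
    R/200) or a :class:`Voxel4DFlow` (then ``window`` is a sequence of frame
    indices and ``spacing`` defaults to the voxel size, with trilinear
    sampling).  The wall position is taken from the vessel model.
    """
    if fit_points < 2:
        raise ValueError("fit_points must be >= 2")
    R = vessel.radius
    center = vessel.center_array.copy()
    center[1] = plane.axis_coordinate
    dirs = sector_directions()

    if isinstance(source, Voxel4DFlow):
        spacing = source.voxel_size_m if spacing is None else spacing
        radii = R - spacing * np.arange(1, fit_points + 1)
        if np.any(radii <= 0):
            raise DegenerateRayError("sampling spacing too coarse for the vessel radius")
        pts = center[None, None, :] + dirs[:, None, :] * radii[None, :, None]
        frac = (pts - source.origin) / source.voxel_size_m - 0.5
        coords = frac.reshape(-1, 3).T
        mag = ndimage.map_coordinates(source.magnitude, coords, order=1, mode="nearest")
        lumen_per_ray = (mag.reshape(8, fit_points) > 0).sum(axis=1)
        if np.any(lumen_per_ray < fit_points):
            bad = SECTOR_LABELS[int(np.argmin(lumen_per_ray))]
            raise DegenerateRayError(
                f"ray {bad} has {lumen_per_ray.min()} lumen samples < fit_points={fit_points}"
            )
        window = tuple(window)
        wss = np.zeros(8)
        for f in window:
            v_axial = ndimage.map_coordinates(
                source.velocity[:, :, :, f, 1], coords, order=1, mode="nearest"
            ).reshape(8, fit_points)
            wss += [
                _ray_wss(radii, v_axial[i], fluid.dynamic_viscosity) for i in range(8)
            ]
        wss /= len(window)
    else:
        spacing = R / 200.0 if spacing is None else spacing
        radii = R - spacing * np.arange(1, fit_points + 1)
        if np.any(radii <= 0):
            raise DegenerateRayError("sampling spacing too coarse for the vessel radius")
        pts = (center[None, None, :] + dirs[:, None, :] * radii[None, :, None]).reshape(-1, 3)
        times = tuple(window)
        wss = np.zeros(8)
        for t in times:
            v = np.asarray(source(pts, float(t)))
            v_axial = (v @ vessel.axis_array).reshape(8, fit_points)
            wss += [
                _ray_wss(radii, v_axial[i], fluid.dynamic_viscosity) for i in range(8)
            ]
        wss /= len(times)

    return WSSProfile(sectors=dict(zip(SECTOR_LABELS, wss)), phase=phase)


def save_wss_csv(profiles: Sequence[WSSProfile], path) -> None:
    """Write sector WSS rows as CSV (phase, sector, wss_Pa)."""
    with open(path, "w") as f:
        f.write("phase,sector,wss_Pa\n")
        for p in profiles:
            for lbl in SECTOR_LABELS:
                f.write(f"{p.phase},{lbl},{p.sectors[lbl]:.17g}\n")


def save_metrics_csv(metrics: Sequence[PlaneMetrics], path) -> None:
    """Write plane metrics as CSV (phase, max_ms, mean_ms)."""
    with open(path, "w") as f:
        f.write("phase,max_ms,mean_ms\n")
        for m in metrics:
            f.write(f"{m.phase},{m.max_velocity:.17g},{m.mean_velocity:.17g}\n")


def plot_wss_polar(profiles: Mapping[str, WSSProfile], path=None, title: str = ""):
    """Polar plot of sector WSS, one trace per labelled profile."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    theta = np.deg2rad(np.arange(9) * 45.0)
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"})
    for name, prof in profiles.items():
        vals = prof.values()
        ax.plot(theta, np.append(vals, vals[0]), marker="o", label=name)
    ax.set_xticks(theta[:-1])
    ax.set_xticklabels(SECTOR_LABELS)
    ax.set_title(title or "Sector wall shear stress (Pa)")
    ax.legend(loc="upper right", bbox_to_anchor=(1.3, 1.1), fontsize="small")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        return None
    return fig
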