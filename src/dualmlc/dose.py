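"""Simplified kernel dose engine and profile tools.

Turns fluence maps into relative planar/point doses at depth: the fluence
is blurred by the projected primary source (anisotropic Gaussian),
magnified to the measurement plane, and scaled by an analytic
depth-dose factor and a mild field-size output factor.  The engine's job
is *relative* dosimetry — comparing model to virtual measurement with a
consistent forward model — not absolute dose calculation.

Also provides the FFF field-edge detector: for an unflattened beam the
field edge is the inflection point of the penumbra, located at the
extremum of the profile's first derivative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

from .fluence import FluenceMap, GridSpec, accumulate_dynamic_fluence, grid_for_aperture
from .mlc_model import Machine, MLCParameters, Plan, equivalent_square

__all__ = [
    "BeamGeometry",
    "Axis",
    "Profile1D",
    "pdd",
    "output_factor",
    "source_blur",
    "dose_plane",
    "point_dose",
    "point_doses",
    "field_edge_inflection",
    "extract_profile",
    "EdgeAmbiguityError",
]

PDD_REFERENCE_DEPTH = 10.0
PDD_AT_REFERENCE = 0.63


class Axis(str, Enum):
    X = "X"
    Y = "Y"
    DIAGONAL = "diagonal"


@dataclass(frozen=True)
class BeamGeometry:
    """Measurement geometry: source-surface distance and depth, cm."""

    ssd: float
    depth: float

    def __post_init__(self) -> None:
        if self.ssd <= 0:
            raise ValueError("ssd must be positive")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")

    def magnification(self, machine: Machine) -> float:
        return (self.ssd + self.depth) / machine.sad


@dataclass
class Profile1D:
    """1D dose scan; positions strictly increasing."""

    positions: np.ndarray
    values: np.ndarray
    axis: Axis = Axis.X

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.shape != self.values.shape:
            raise ValueError("positions and values must have equal length")
        if self.positions.size >= 2 and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        self.axis = Axis(self.axis)


def pdd(depth: float, machine: Machine) -> float:
    """Analytic percentage-depth-dose factor, PDD(d_max) = 1.

    Linear build-up from the surface to d_max, exponential attenuation
    beyond, tuned so PDD(10 cm) = 0.63 for a reference field.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    dm = machine.d_max
    if depth <= dm:
        return depth / dm if dm > 0 else 1.0
    mu = -math.log(PDD_AT_REFERENCE) / (PDD_REFERENCE_DEPTH - dm)
    return math.exp(-mu * (depth - dm))


def output_factor(eq_square: float) -> float:
    """Relative output vs equivalent-square field size, normalized at 10 cm.

    A mild monotone saturation curve; configuration, not science — the
    virtual measurements and the model share it, so it cancels in all
    relative comparisons.
    """
    if eq_square <= 0:
        raise ValueError("equivalent square must be positive")
    raw = 1.0 - 0.12 * math.exp(-eq_square / 2.5)
    ref = 1.0 - 0.12 * math.exp(-10.0 / 2.5)
    return raw / ref


def _blur_sigmas(machine: Machine, plane_distance: float) -> tuple[float, float]:
    """Source penumbra sigmas (x, y) projected to a plane at
    ``plane_distance`` cm from the source, for a collimator at the
    mid-layer distance."""
    d_mlc = 0.5 * (machine.layer_distance_proximal + machine.layer_distance_distal)
    scale = (plane_distance - d_mlc) / d_mlc
    return machine.source_sigma_x * scale, machine.source_sigma_y * scale


def source_blur(f: FluenceMap, machine: Machine,
                plane_distance: float | None = None) -> FluenceMap:
    """Anisotropic Gaussian source blur of a fluence map.

    The source sigmas are projected through the mid-layer collimator
    distance to the given plane (default: the isocenter plane).  The
    convolution conserves the map integral in the interior.
    """
    if plane_distance is None:
        plane_distance = machine.sad
    sx, sy = _blur_sigmas(machine, plane_distance)
    h = f.spacing
    if h <= 0:
        raise ValueError("map must have at least 2 grid points per axis")
    if min(sx, sy) < h:
        import warnings
        warnings.warn(
            f"grid spacing {h:g} cm exceeds blur sigma {min(sx, sy):g} cm; "
            "penumbra under-resolved", stacklevel=2)
    blurred = ndimage.gaussian_filter(
        f.values, sigma=(sy / h, sx / h), mode="nearest", truncate=5.0)
    return FluenceMap(f.x.copy(), f.y.copy(), blurred)


def dose_plane(f: FluenceMap, geom: BeamGeometry, machine: Machine,
               eq_square: float | None = None) -> FluenceMap:
    """Relative dose in the measurement plane.

    dose = PDD(depth) * OF(eq_square) * source-blurred fluence, with the
    grid magnified from the isocenter plane by (ssd + depth)/sad.
    """
    mag = geom.magnification(machine)
    plane_distance = geom.ssd + geom.depth
    blurred = source_blur(
        FluenceMap(f.x * mag, f.y * mag, f.values), machine, plane_distance)
    factor = pdd(geom.depth, machine)
    if eq_square is not None:
        factor *= output_factor(eq_square)
    return FluenceMap(blurred.x, blurred.y, blurred.values * factor)


def _plan_pairs(plan: Plan):
    for cp in plan.control_points:
        yield from cp.apertures


def plan_dose_plane(plan: Plan, geom: BeamGeometry, machine: Machine,
                    params: MLCParameters, grid: GridSpec | None = None,
                    spacing: float = 0.1,
                    max_substep_travel: float = 0.1) -> FluenceMap:
    """Convenience: accumulated plan fluence pushed through the engine."""
    if grid is None:
        grid = grid_for_aperture(list(_plan_pairs(plan)), machine,
                                 spacing=spacing)
    f = accumulate_dynamic_fluence(plan, params, machine, grid,
                                   max_substep_travel=max_substep_travel)
    return dose_plane(f, geom, machine)


def _interpolator(d: FluenceMap) -> RegularGridInterpolator:
    return RegularGridInterpolator((d.y, d.x), d.values, method="linear",
                                   bounds_error=True)


def point_dose(dose: FluenceMap, point: tuple[float, float],
               averaging: tuple[str, float] | None = None) -> float:
    """Dose at (x, y) by bilinear interpolation of a dose plane.

    ``averaging`` optionally applies a detector kernel:
    ``("line_y", L)`` averages along a line of length L cm in Y (a chamber
    with its long axis in-plane); ``("gauss", sigma)`` an isotropic
    Gaussian of the given sigma.
    """
    itp = _interpolator(dose)
    x0, y0 = point
    try:
        if averaging is None:
            return float(itp((y0, x0)))
        kind, size = averaging
        if kind == "line_y":
            n = max(9, int(round(size / (dose.spacing / 2))) | 1)
            ys = y0 + np.linspace(-size / 2, size / 2, n)
            return float(np.mean(itp(np.column_stack([ys, np.full(n, x0)]))))
        if kind == "gauss":
            n = 9
            g = np.linspace(-2.5 * size, 2.5 * size, n)
            w = np.exp(-0.5 * (g / size) ** 2)
            xx, yy = np.meshgrid(x0 + g, y0 + g)
            ww = np.outer(w, w)
            vals = itp(np.column_stack([yy.ravel(), xx.ravel()]))
            return float(np.sum(vals * ww.ravel()) / np.sum(ww))
        raise ValueError(f"unknown averaging kernel {kind!r}")
    except ValueError as e:
        if "out of bounds" in str(e).lower():
            raise ValueError(f"point {point} outside the dose grid") from e
        raise


def point_doses(dose: FluenceMap, points: np.ndarray) -> np.ndarray:
    """Bilinear dose at many (x, y) points (no detector averaging)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    itp = _interpolator(dose)
    try:
        return np.asarray(itp(np.column_stack([pts[:, 1], pts[:, 0]])))
    except ValueError as e:
        if "out of bounds" in str(e).lower():
            raise ValueError("points outside the dose grid") from e
        raise


class EdgeAmbiguityError(ValueError):
    """No single well-defined derivative extremum in the search window."""


def field_edge_inflection(p: Profile1D,
                          window: tuple[float, float] | None = None) -> float:
    """FFF field-edge position: extremum of the profile's first derivative.

    Uses centered differences refined by quadratic interpolation of the
    derivative peak.  Raises :class:`EdgeAmbiguityError` when the
    derivative has no distinct extremum (e.g. a linear ramp) or several
    separated equal extrema.
    """
    x = p.positions
    v = p.values
    if x.size < 5:
        raise ValueError("profile too short for edge detection")
    d = (v[2:] - v[:-2]) / (x[2:] - x[:-2])
    xd = x[1:-1]
    if window is not None:
        m = (xd >= window[0]) & (xd <= window[1])
        if m.sum() < 3:
            raise ValueError("window contains fewer than 3 interior points")
        d, xd = d[m], xd[m]
    mag = np.abs(d)
    peak = mag.max()
    if peak <= 0 or (peak - mag.min()) <= 1e-12 * max(peak, 1.0):
        raise EdgeAmbiguityError("derivative has no distinct extremum")
    near = np.nonzero(mag >= peak * (1 - 1e-9))[0]
    if near.size > 1 and (np.diff(near) > 1).any():
        raise EdgeAmbiguityError("multiple separated derivative extrema")
    i = int(near[0])
    if i == 0 or i == mag.size - 1:
        return float(xd[i])
    y0, y1, y2 = mag[i - 1], mag[i], mag[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(xd[i])
    delta = 0.5 * (y0 - y2) / denom
    step = xd[i + 1] - xd[i]
    return float(xd[i] + delta * step)


def extract_profile(dose: FluenceMap, axis: Axis | str,
                    coord: float = 0.0) -> Profile1D:
    """Cut a 1D profile out of a dose plane at the given orthogonal
    coordinate (nearest grid line)."""
    axis = Axis(axis)
    if axis is Axis.X:
        return Profile1D(dose.x.copy(), dose.profile_x(coord), Axis.X)
    if axis is Axis.Y:
        return Profile1D(dose.y.copy(), dose.profile_y(coord), Axis.Y)
    raise ValueError("diagonal extraction not supported")
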