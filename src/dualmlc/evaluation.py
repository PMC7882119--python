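"""Dose-comparison and QA statistics.

Gamma index with global or local dose normalization, per-point local dose
errors, and confidence limits in the style of credentialing tests
(mean +/- 1.96 SD for errors, mean - 1.96 SD for passing rates).

The gamma search is exact: the reference is linearly resampled at one
tenth of the distance-to-agreement and, for each evaluated point, the
search radius is the point's own dose-difference gamma times the DTA —
any reference point farther away cannot lower the minimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .fluence import FluenceMap

__all__ = [
    "GammaCriteria",
    "GammaResult",
    "gamma",
    "gamma_points",
    "local_error_stats",
    "LocalErrorStats",
    "ConfidenceLimit",
    "confidence_limit",
    "confidence_limit_from_stats",
    "parse_criteria",
]


@dataclass(frozen=True)
class GammaCriteria:
    """Dose tolerance (%), distance to agreement (mm), normalization mode
    and low-dose threshold (% of reference maximum)."""

    dose_tolerance: float = 3.0
    dta_mm: float = 2.0
    normalization: Literal["global", "local"] = "global"
    threshold: float = 10.0

    def __post_init__(self) -> None:
        if self.dose_tolerance <= 0 or self.dta_mm <= 0:
            raise ValueError("dose tolerance and DTA must be positive")
        if not (0 < self.threshold < 100):
            raise ValueError("threshold must be in (0, 100)")
        if self.normalization not in ("global", "local"):
            raise ValueError("normalization must be 'global' or 'local'")

    @property
    def label(self) -> str:
        tag = "G" if self.normalization == "global" else "L"
        return f"{self.dose_tolerance:g}%{tag}/{self.dta_mm:g}mm"


def parse_criteria(text: str, threshold: float = 10.0) -> GammaCriteria:
    """Parse shorthand like '3G2' or '2L2' (tolerance, mode, DTA mm)."""
    t = text.strip().upper()
    for mode, name in (("G", "global"), ("L", "local")):
        if mode in t:
            tol, dta = t.split(mode)
            return GammaCriteria(float(tol), float(dta), name, threshold)
    raise ValueError(f"cannot parse gamma criteria {text!r}")


@dataclass
class GammaResult:
    gamma: np.ndarray          # per evaluated point (above threshold)
    local_errors: np.ndarray   # 100*(eval-ref)/ref at the same points
    passing_rate: float        # % of gamma <= 1
    n: int
    criteria: GammaCriteria
    evaluated_mask: np.ndarray = field(default=None)  # type: ignore[assignment]


def _fine_reference(ref: FluenceMap, dta_cm: float):
    """Reference resampled at <= dta/10 on its own extent."""
    step = dta_cm / 10.0
    itp = RegularGridInterpolator((ref.y, ref.x), ref.values,
                                  method="linear", bounds_error=False,
                                  fill_value=None)
    fx = np.arange(ref.x[0], ref.x[-1] + step / 2, step)
    fy = np.arange(ref.y[0], ref.y[-1] + step / 2, step)
    gx, gy = np.meshgrid(fx, fy)
    vals = itp(np.column_stack([gy.ravel(), gx.ravel()])).reshape(gy.shape)
    return fx, fy, vals


def gamma_points(points: np.ndarray, doses: np.ndarray, ref: FluenceMap,
                 crit: GammaCriteria) -> GammaResult:
    """Gamma of dose values at arbitrary (x, y) points against a
    reference map.

    Points where the reference (at the point) is below the threshold
    fraction of the reference maximum are excluded from the statistics.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    doses = np.asarray(doses, dtype=float)
    if points.shape[0] != doses.size:
        raise ValueError("points and doses must have the same length")
    dta = crit.dta_mm / 10.0  # cm
    ref_max = float(ref.values.max())
    if ref_max <= 0:
        raise ValueError("reference has no positive dose")
    itp = RegularGridInterpolator((ref.y, ref.x), ref.values,
                                  method="linear", bounds_error=False,
                                  fill_value=None)
    ref_at = itp(np.column_stack([points[:, 1], points[:, 0]]))
    mask = ref_at >= crit.threshold / 100.0 * ref_max
    if not mask.any():
        raise ValueError("no points above the dose threshold")

    fx, fy, fvals = _fine_reference(ref, dta)
    tol_global = crit.dose_tolerance / 100.0 * ref_max
    tol_pct = crit.dose_tolerance / 100.0

    def _g2_of(de: float, vals: np.ndarray, d2: np.ndarray) -> np.ndarray:
        dd = de - vals
        if crit.normalization == "global":
            dose_term = (dd / tol_global) ** 2
        else:
            tol = tol_pct * vals
            with np.errstate(divide="ignore", invalid="ignore"):
                dose_term = np.where(tol > 0, (dd / tol) ** 2, np.inf)
        return dose_term + d2 / (dta * dta)

    out = np.empty(int(mask.sum()))
    errs = np.empty_like(out)
    for k, idx in enumerate(np.nonzero(mask)[0]):
        x0, y0 = points[idx]
        de = float(doses[idx])
        r0 = float(ref_at[idx])
        errs[k] = 100.0 * (de - r0) / r0 if r0 != 0 else np.inf
        # gamma at the nearest resampled node is an upper bound; any
        # candidate farther than (bound * dta) cannot lower the minimum
        ix = int(np.clip(np.searchsorted(fx, x0), 0, fx.size - 1))
        if ix > 0 and abs(fx[ix - 1] - x0) < abs(fx[ix] - x0):
            ix -= 1
        iy = int(np.clip(np.searchsorted(fy, y0), 0, fy.size - 1))
        if iy > 0 and abs(fy[iy - 1] - y0) < abs(fy[iy] - y0):
            iy -= 1
        d2n = (fx[ix] - x0) ** 2 + (fy[iy] - y0) ** 2
        g2n = float(_g2_of(de, fvals[iy, ix], np.array(d2n)))
        radius = math.sqrt(g2n) * dta * (1 + 1e-12) + 1e-12
        ix0 = int(np.searchsorted(fx, x0 - radius, "left"))
        ix1 = int(np.searchsorted(fx, x0 + radius, "right"))
        iy0 = int(np.searchsorted(fy, y0 - radius, "left"))
        iy1 = int(np.searchsorted(fy, y0 + radius, "right"))
        dx = fx[ix0:ix1] - x0
        dy = fy[iy0:iy1] - y0
        d2 = dy[:, None] ** 2 + dx[None, :] ** 2
        g2 = _g2_of(de, fvals[iy0:iy1, ix0:ix1], d2)
        g2 = np.where(d2 <= radius * radius, g2, np.inf)
        out[k] = math.sqrt(min(float(np.min(g2)), g2n))
    passing = 100.0 * float(np.mean(out <= 1.0))
    return GammaResult(out, errs, passing, out.size, crit, mask)


def gamma(eval_dose: FluenceMap, ref_dose: FluenceMap,
          crit: GammaCriteria) -> GammaResult:
    """Gamma of an evaluated dose map against a reference map."""
    gx, gy = np.meshgrid(eval_dose.x, eval_dose.y)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    return gamma_points(pts, eval_dose.values.ravel(), ref_dose, crit)


@dataclass
class LocalErrorStats:
    mean: float
    median: float
    sd: float
    n: int
    errors: np.ndarray
    hist_edges: np.ndarray
    hist_counts: np.ndarray


def local_error_stats(eval_doses: np.ndarray, ref_doses: np.ndarray,
                      threshold: float = 10.0,
                      bin_width: float = 1.0) -> LocalErrorStats:
    """Per-point local percent dose errors 100*(eval-ref)/ref over points
    receiving at least ``threshold`` % of the reference maximum."""
    e = np.asarray(eval_doses, dtype=float)
    r = np.asarray(ref_doses, dtype=float)
    if e.shape != r.shape:
        raise ValueError("eval and ref must have the same shape")
    rmax = r.max()
    if rmax <= 0:
        raise ValueError("reference has no positive dose")
    m = r >= threshold / 100.0 * rmax
    if not m.any():
        raise ValueError("no points above the dose threshold")
    errs = 100.0 * (e[m] - r[m]) / r[m]
    lo = math.floor(errs.min() / bin_width) * bin_width
    hi = math.ceil(errs.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, _ = np.histogram(errs, bins=edges)
    return LocalErrorStats(
        mean=float(errs.mean()),
        median=float(np.median(errs)),
        sd=float(errs.std(ddof=1)) if errs.size > 1 else 0.0,
        n=int(errs.size),
        errors=errs,
        hist_edges=edges,
        hist_counts=counts,
    )


def _round_toward_zero(v: float, decimals: int = 1) -> float:
    f = 10.0 ** decimals
    return math.trunc(v * f) / f


@dataclass
class ConfidenceLimit:
    mean: float
    sd: float
    raw: tuple[float, float] | float
    paper_style: tuple[float, float] | float
    direction: str


def confidence_limit(values: Sequence[float],
                     direction: Literal["two_sided_error",
                                        "lower_passing"] = "two_sided_error",
                     ) -> ConfidenceLimit:
    """95% confidence limit of commissioning-test results.

    ``two_sided_error``: mean +/- 1.96 * sample SD.  ``lower_passing``:
    mean - 1.96 * SD, capped at 100 (a passing-rate floor).  The
    paper-style value truncates toward zero magnitude at one decimal, the
    convention used when such limits are quoted (e.g. +/-2.156 -> 2.1).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    return confidence_limit_from_stats(float(v.mean()), float(v.std(ddof=1)),
                                       direction)


def confidence_limit_from_stats(mean: float, sd: float,
                                direction: Literal[
                                    "two_sided_error",
                                    "lower_passing"] = "two_sided_error",
                                ) -> ConfidenceLimit:
    """Confidence limit directly from a reported mean and sample SD."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    m = mean
    if direction == "two_sided_error":
        raw = (m - 1.96 * sd, m + 1.96 * sd)
        style = (_round_toward_zero(raw[0]), _round_toward_zero(raw[1]))
    elif direction == "lower_passing":
        raw = min(m - 1.96 * sd, 100.0)
        style = _round_toward_zero(raw)
    else:
        raise ValueError("direction must be 'two_sided_error' or 'lower_passing'")
    return ConfidenceLimit(m, sd, raw, style, direction)
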