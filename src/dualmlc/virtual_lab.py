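"""Virtual measurement lab: a hidden ground-truth machine plus detector
and noise models, generating every measurement session the commissioning
pipeline consumes.

The ground truth plays the role of the physical linac: sessions are
computed by the same forward chain (fluence -> source blur -> depth dose)
under the *true* leaf-end parameters, convolved with a detector response
and multiplied by lognormal reading noise.  Sessions are pure functions of
(ground truth, arguments): identical seeds give identical readings.

Detector response models (physical sizes; simple kernels):

* Farmer chamber — 2.3 cm line average along its axis (in-plane, Y),
* CC13 chamber  — 0.6 cm Gaussian,
* Edge diode    — 0.08 cm Gaussian along the scan direction.

All sweeping-gap sessions use the classic geometry: 10 cm depth at 90 cm
SSD, which places the measurement plane at the isocenter distance, so
plane coordinates coincide with nominal leaf coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .dose import (Axis, BeamGeometry, Profile1D, dose_plane, point_dose,
                   point_doses)
from .fluence import (
    FluenceMap,
    GridSpec,
    accumulate_dynamic_fluence,
    grid_for_aperture,
)
from .mlc_model import (
    ControlPoint,
    Layer,
    LeafPair,
    Machine,
    MLCParameters,
    Plan,
    row_span,
    validate_plan,
)

__all__ = [
    "GroundTruth",
    "MeasurementRecord",
    "MeasurementSet",
    "AbuttingJunction",
    "BarSession",
    "EdgeField",
    "PlanMeasurement",
    "PlanSuite",
    "SessionBundle",
    "DEFAULT_GAPS_MM",
    "DEFAULT_POSITIONS_CM",
    "rows_covering",
    "band_aperture",
    "sweep_plan",
    "sweep_reading",
    "leakage_reading",
    "reference_reading",
    "allowed_gaps",
    "gen_sweep_session",
    "abutting_profiles",
    "gen_abutting_session",
    "bar_sum_profile",
    "gen_bar_session",
    "gen_edge_session",
    "gen_plan_suite",
    "gen_bundle",
]

DEFAULT_GAPS_MM = (2.0, 4.0, 6.0, 10.0, 14.0, 16.0, 20.0)
DEFAULT_POSITIONS_CM = (0.0, -3.0, 3.0, 5.0, 10.0, 12.0, 13.0)
SWEEP_GEOMETRY = BeamGeometry(ssd=90.0, depth=10.0)
FARMER_LINE_CM = 2.3
EDGE_SIGMA_CM = 0.08
SWEEP_LENGTH_CM = 8.0
SWEEP_END_MARGIN_CM = 0.3
PARK_X_CM = -13.5


@dataclass(frozen=True)
class GroundTruth:
    """Hidden true machine state driving all virtual measurements."""

    true_params: MLCParameters = MLCParameters(
        offset=0.007, gain=0.0, curvature=0.0, tip_width=0.0,
        layer_transmission=0.0047, tng_width=0.05, dynamic_min_gap=0.06)
    machine: Machine = Machine()
    noise_sd: float = 0.005
    seed: int = 0

    def rng(self, *stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed & 0x7FFFFFFF, *stream])

    def noise(self, rng: np.random.Generator, shape=None) -> np.ndarray | float:
        """Multiplicative lognormal noise factor(s) of sd ``noise_sd``."""
        if self.noise_sd <= 0:
            return 1.0 if shape is None else np.ones(shape)
        z = rng.standard_normal(shape)
        return np.exp(self.noise_sd * z)


@dataclass(frozen=True)
class MeasurementRecord:
    kind: str                 # "sweep" | "leakage" | "reference"
    reading: float
    gap_mm: float | None
    position_cm: float
    depth_cm: float
    ssd_cm: float
    detector: str

    @property
    def leakage(self) -> bool:
        return self.kind == "leakage"


@dataclass
class MeasurementSet:
    records: list[MeasurementRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [(r.kind, r.gap_mm, r.position_cm, r.depth_cm, r.ssd_cm)
                for r in self.records]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate measurement setups")
        for r in self.records:
            if r.reading <= 0:
                raise ValueError("readings must be positive")

    def sweeps_at(self, position: float) -> list[MeasurementRecord]:
        return [r for r in self.records
                if r.kind == "sweep" and math.isclose(r.position_cm, position)]

    def leakage_at(self, position: float) -> MeasurementRecord:
        for r in self.records:
            if r.kind == "leakage" and math.isclose(r.position_cm, position):
                return r
        raise KeyError(f"no leakage record at {position} cm")

    def reference(self) -> MeasurementRecord:
        for r in self.records:
            if r.kind == "reference":
                return r
        raise KeyError("no reference record")

    @property
    def positions(self) -> list[float]:
        return sorted({r.position_cm for r in self.records if r.kind == "sweep"})


# ---------------------------------------------------------------------------
# aperture builders

def rows_covering(y_lo: float, y_hi: float, layer: Layer,
                  machine: Machine) -> list[int]:
    """Row indices of a layer whose span intersects (y_lo, y_hi)."""
    w = machine.physical_leaf_width
    n = int(round(machine.max_field / w)) + 2
    out = []
    for i in range(0, n + 1):
        lo, hi = row_span(i, layer, machine)
        if hi > y_lo + 1e-9 and lo < y_hi - 1e-9:
            out.append(i)
    return out


def band_aperture(x_left: float, x_right: float, y_lo: float, y_hi: float,
                  machine: Machine,
                  layers: Sequence[Layer] = (Layer.PROXIMAL, Layer.DISTAL),
                  ) -> tuple[LeafPair, ...]:
    """Rectangular aperture [x_left, x_right] x [y_lo, y_hi] on both layers."""
    pairs = []
    for layer in layers:
        for i in rows_covering(y_lo, y_hi, layer, machine):
            pairs.append(LeafPair(x_left, x_right, i, layer))
    return tuple(pairs)


def closed_aperture(y_lo: float, y_hi: float, machine: Machine,
                    park_x: float = PARK_X_CM) -> tuple[LeafPair, ...]:
    return band_aperture(park_x, park_x, y_lo, y_hi, machine)


def static_plan(pairs: Sequence[LeafPair], total_mu: float = 100.0,
                name: str = "") -> Plan:
    return Plan((ControlPoint(tuple(pairs), 1.0),), total_mu=total_mu, name=name)


def sweep_plan(gap_cm: float, position: float, machine: Machine,
               field_half_y: float = 2.0) -> tuple[Plan, float]:
    """Two-control-point sweeping-gap delivery.

    The gap travels a fixed ``SWEEP_LENGTH_CM`` window positioned so the
    leading leaf stays within travel range; returns (plan, sweep length).
    """
    c_max = min(position + SWEEP_LENGTH_CM / 2.0, 14.0 - gap_cm / 2.0)
    c_min = c_max - SWEEP_LENGTH_CM
    if c_min < -14.0 + gap_cm / 2.0:
        c_min = -14.0 + gap_cm / 2.0
        c_max = c_min + SWEEP_LENGTH_CM
    if (c_max - position < gap_cm / 2.0 + SWEEP_END_MARGIN_CM
            or position - c_min < gap_cm / 2.0 + SWEEP_END_MARGIN_CM):
        raise ValueError(
            f"gap {gap_cm:g} cm cannot fully traverse a chamber at "
            f"{position:g} cm within leaf travel range")
    aps = []
    for c, w in ((c_min, 0.0), (c_max, 1.0)):
        pairs = band_aperture(c - gap_cm / 2.0, c + gap_cm / 2.0,
                              -field_half_y, field_half_y, machine)
        aps.append(ControlPoint(pairs, w))
    return Plan(tuple(aps), name=f"sweep_g{gap_cm:g}_p{position:g}"), c_max - c_min


def allowed_gaps(position: float, gaps_mm: Sequence[float],
                 min_gap_cm: float) -> list[float]:
    """Gaps (mm) deliverable at an off-axis position: the gap must fully
    traverse the chamber inside the +/-14 cm travel range."""
    out = []
    for g in gaps_mm:
        g_cm = g / 10.0
        if g_cm < min_gap_cm:
            raise ValueError(
                f"gap {g:g} mm below the dynamic minimum gap "
                f"{min_gap_cm * 10:g} mm: undeliverable")
        if abs(position) + g_cm / 2.0 + SWEEP_END_MARGIN_CM + g_cm / 2.0 <= 14.0:
            out.append(g)
    return out


# ---------------------------------------------------------------------------
# noise-free forward readings (shared by the generator and the model side
# of the commissioning fits)

def _sweep_grid(position: float, spacing: float = 0.1) -> GridSpec:
    snap = lambda v: round(v / spacing) * spacing
    return GridSpec(snap(position - 3.0), snap(position + 3.0),
                    -3.0, 3.0, spacing)


def sweep_reading(machine: Machine, params: MLCParameters, gap_cm: float,
                  position: float, spacing: float = 0.1,
                  substep: float = 0.1) -> float:
    """Noise-free Farmer-chamber reading of one sweeping-gap delivery."""
    plan, _ = sweep_plan(gap_cm, position, machine)
    grid = _sweep_grid(position, spacing)
    f = accumulate_dynamic_fluence(plan, params, machine, grid,
                                   max_substep_travel=substep)
    d = dose_plane(f, SWEEP_GEOMETRY, machine)
    return point_dose(d, (position, 0.0), averaging=("line_y", FARMER_LINE_CM))


def leakage_reading(machine: Machine, params: MLCParameters,
                    position: float, spacing: float = 0.1) -> float:
    """Noise-free closed-field (leaves parked off-axis) reading."""
    plan = static_plan(closed_aperture(-2.0, 2.0, machine))
    grid = _sweep_grid(position, spacing)
    f = accumulate_dynamic_fluence(plan, params, machine, grid)
    d = dose_plane(f, SWEEP_GEOMETRY, machine)
    return point_dose(d, (position, 0.0), averaging=("line_y", FARMER_LINE_CM))


def reference_reading(machine: Machine, params: MLCParameters,
                      spacing: float = 0.1) -> float:
    """Noise-free 10x10 cm^2 static-field reading at the central axis."""
    plan = static_plan(band_aperture(-5.0, 5.0, -5.0, 5.0, machine))
    grid = GridSpec(-7.0, 7.0, -7.0, 7.0, spacing)
    f = accumulate_dynamic_fluence(plan, params, machine, grid)
    d = dose_plane(f, SWEEP_GEOMETRY, machine)
    return point_dose(d, (0.0, 0.0), averaging=("line_y", FARMER_LINE_CM))


# ---------------------------------------------------------------------------
# sessions

def gen_sweep_session(gt: GroundTruth,
                      gaps_mm: Sequence[float] = DEFAULT_GAPS_MM,
                      positions: Sequence[float] = DEFAULT_POSITIONS_CM,
                      spacing: float = 0.1) -> MeasurementSet:
    """Sweeping-gap ion-chamber session at 10 cm depth / 90 cm SSD.

    One closed-field leakage record per position and one static 10x10
    cross-calibration reference are included.  Gap/position combinations
    the leaf travel range cannot deliver are omitted.
    """
    rng = gt.rng(1)
    records = []
    for p in positions:
        for g in allowed_gaps(p, gaps_mm, gt.true_params.dynamic_min_gap):
            r = sweep_reading(gt.machine, gt.true_params, g / 10.0, p, spacing)
            records.append(MeasurementRecord(
                "sweep", r * float(gt.noise(rng)), g, p, 10.0, 90.0, "farmer"))
        leak = leakage_reading(gt.machine, gt.true_params, p, spacing)
        records.append(MeasurementRecord(
            "leakage", leak * float(gt.noise(rng)), None, p, 10.0, 90.0,
            "farmer"))
    ref = reference_reading(gt.machine, gt.true_params, spacing)
    records.append(MeasurementRecord(
        "reference", ref * float(gt.noise(rng)), None, 0.0, 10.0, 90.0,
        "farmer"))
    return MeasurementSet(records)


@dataclass
class AbuttingJunction:
    junction_cm: float
    profile_a: Profile1D
    profile_b: Profile1D
    profile_sum: Profile1D


def _diode_profile(dose: FluenceMap, axis: Axis, coord: float,
                   lo: float, hi: float) -> Profile1D:
    """Scan along an axis with the Edge-diode Gaussian response."""
    if axis is Axis.X:
        pos, vals = dose.x, dose.profile_x(coord)
    else:
        pos, vals = dose.y, dose.profile_y(coord)
    h = pos[1] - pos[0]
    vals = ndimage.gaussian_filter1d(vals, EDGE_SIGMA_CM / h, mode="nearest")
    m = (pos >= lo - 1e-9) & (pos <= hi + 1e-9)
    return Profile1D(pos[m], vals[m], axis)


def abutting_profiles(machine: Machine, params: MLCParameters,
                      junction: float, spacing: float = 0.05,
                      ) -> tuple[Profile1D, Profile1D]:
    """Noise-free normalized X-scans of two abutting 2x4 cm^2 fields."""
    geom = SWEEP_GEOMETRY
    lo, hi = junction - 3.0, junction + 3.0
    out = []
    for x0, x1 in ((junction - 2.0, junction), (junction, junction + 2.0)):
        pairs = band_aperture(x0, x1, -2.0, 2.0, machine)
        plan = static_plan(pairs)
        snap = lambda v: round(v / spacing) * spacing
        grid = GridSpec(snap(lo - 1.5), snap(hi + 1.5), -3.0, 3.0, spacing)
        f = accumulate_dynamic_fluence(plan, params, machine, grid)
        d = dose_plane(f, geom, machine)
        prof = _diode_profile(d, Axis.X, 0.0, lo, hi)
        center = 0.5 * (x0 + x1)
        norm = prof.values[int(np.argmin(np.abs(prof.positions - center)))]
        out.append(Profile1D(prof.positions, prof.values / norm, Axis.X))
    return out[0], out[1]


def gen_abutting_session(gt: GroundTruth,
                         junctions: Sequence[float] = (0.0, -10.0, 10.0),
                         n_runs: int = 3,
                         spacing: float = 0.05) -> list[AbuttingJunction]:
    """Abutting 2x4 cm^2 field scans; ``n_runs`` noisy runs are averaged."""
    if any(abs(j) > 10.0 + 1e-9 for j in junctions):
        raise ValueError("junctions must lie within +/-10 cm")
    rng = gt.rng(2)
    out = []
    for j in junctions:
        pa, pb = abutting_profiles(gt.machine, gt.true_params, j, spacing)
        va = np.mean([pa.values * gt.noise(rng, pa.values.shape)
                      for _ in range(n_runs)], axis=0)
        vb = np.mean([pb.values * gt.noise(rng, pb.values.shape)
                      for _ in range(n_runs)], axis=0)
        a = Profile1D(pa.positions.copy(), va, Axis.X)
        b = Profile1D(pb.positions.copy(), vb, Axis.X)
        s = Profile1D(pa.positions.copy(), va + vb, Axis.X)
        out.append(AbuttingJunction(j, a, b, s))
    return out


@dataclass
class BarSession:
    layer: Layer
    profile_a: Profile1D
    profile_b: Profile1D
    profile_sum: Profile1D


def _bar_pairs(machine: Machine, layer: Layer, open_even: bool,
               y_half: float = 4.0, x_half: float = 3.0,
               ) -> tuple[LeafPair, ...]:
    """Bar pattern on one layer (alternate rows open/closed); the other
    layer fully retracted over the band."""
    other = Layer.DISTAL if layer is Layer.PROXIMAL else Layer.PROXIMAL
    pairs = []
    for i in rows_covering(-y_half, y_half, layer, machine):
        if (i % 2 == 0) == open_even:
            pairs.append(LeafPair(-x_half, x_half, i, layer))
        else:
            pairs.append(LeafPair(PARK_X_CM, PARK_X_CM, i, layer))
    for i in rows_covering(-y_half - 1.0, y_half + 1.0, other, machine):
        pairs.append(LeafPair(-x_half - 0.5, x_half + 0.5, i, other))
    return tuple(pairs)


def bar_sum_profile(machine: Machine, params: MLCParameters, layer: Layer,
                    spacing: float = 0.05, y_half: float = 4.0,
                    ) -> tuple[Profile1D, Profile1D, Profile1D]:
    """Noise-free complementary-bar Y-scans and their sum."""
    geom = SWEEP_GEOMETRY
    lo, hi = -y_half + 1.0, y_half - 1.0
    profs = []
    for open_even in (True, False):
        pairs = _bar_pairs(machine, layer, open_even, y_half)
        plan = static_plan(pairs)
        grid = GridSpec(-4.5, 4.5, -y_half - 1.5, y_half + 1.5, spacing)
        f = accumulate_dynamic_fluence(plan, params, machine, grid)
        d = dose_plane(f, geom, machine)
        profs.append(_diode_profile(d, Axis.Y, 0.0, lo, hi))
    a, b = profs
    s = Profile1D(a.positions.copy(), a.values + b.values, Axis.Y)
    return a, b, s


def gen_bar_session(gt: GroundTruth, layer: Layer | str = Layer.PROXIMAL,
                    spacing: float = 0.05) -> BarSession:
    """Complementary bar patterns scanned in Y, exposing T&G strips."""
    layer = Layer(layer)
    rng = gt.rng(3 if layer is Layer.PROXIMAL else 4)
    a, b, _ = bar_sum_profile(gt.machine, gt.true_params, layer, spacing)
    va = a.values * gt.noise(rng, a.values.shape)
    vb = b.values * gt.noise(rng, b.values.shape)
    return BarSession(
        layer,
        Profile1D(a.positions.copy(), va, Axis.Y),
        Profile1D(b.positions.copy(), vb, Axis.Y),
        Profile1D(a.positions.copy(), va + vb, Axis.Y),
    )


@dataclass
class EdgeField:
    center_cm: float
    width_cm: float
    profile: Profile1D


def gen_edge_session(gt: GroundTruth,
                     centers: Sequence[float] = (-10.0, -6.0, -3.0, 0.0,
                                                 3.0, 6.0, 10.0),
                     width: float = 2.0,
                     spacing: float = 0.05) -> list[EdgeField]:
    """Narrow-slit X-scans at several off-axis centers.

    The field-edge midpoints extracted from these profiles measure the
    leaf-pair midpoint shift versus nominal position (the gain isolator).
    """
    rng = gt.rng(5)
    out = []
    for c in centers:
        pairs = band_aperture(c - width / 2.0, c + width / 2.0,
                              -2.0, 2.0, gt.machine)
        plan = static_plan(pairs)
        snap = lambda v: round(v / spacing) * spacing
        grid = GridSpec(snap(c - width / 2 - 2.0), snap(c + width / 2 + 2.0),
                        -3.0, 3.0, spacing)
        f = accumulate_dynamic_fluence(plan, gt.true_params, gt.machine, grid)
        d = dose_plane(f, SWEEP_GEOMETRY, gt.machine)
        prof = _diode_profile(d, Axis.X, 0.0,
                              c - width / 2 - 1.0, c + width / 2 + 1.0)
        noisy = prof.values * gt.noise(rng, prof.values.shape)
        out.append(EdgeField(c, width, Profile1D(prof.positions, noisy, Axis.X)))
    return out


# ---------------------------------------------------------------------------
# modulated plan suite

@dataclass
class PlanMeasurement:
    plan: Plan
    technique: str
    chamber_points: tuple[tuple[float, float], tuple[float, float]]
    chamber_doses: tuple[float, float]       # "measured" (noisy), cGy-like
    array_points: np.ndarray                  # (N, 2) plane coordinates
    array_doses: np.ndarray                   # (N,) "measured" (noisy)
    modulation_mu_per_cgy: float
    dose_ratio: float                         # noise-free low/high


@dataclass
class PlanSuite:
    items: list[PlanMeasurement]
    technique: str
    seed: int


PLAN_GRID = GridSpec(-11.5, 11.5, -6.5, 6.5, 0.1)
CHAMBER_GRID = GridSpec(-8.0, 8.0, -6.5, 6.5, 0.1)
ARRAY_RADIUS_CM = 10.5
PLAN_GEOMETRY = BeamGeometry(ssd=90.0, depth=10.0)


def _vmat_plan(rng: np.random.Generator, machine: Machine, width: float,
               name: str) -> Plan:
    n_cp = 60
    prox = rows_covering(-5.0, 5.0, Layer.PROXIMAL, machine)
    dist = rows_covering(-5.0, 5.0, Layer.DISTAL, machine)
    rows = [(i, Layer.PROXIMAL) for i in prox] + [(i, Layer.DISTAL) for i in dist]
    amp = 2.0
    phases = rng.uniform(0, 2 * np.pi, len(rows))
    freqs = rng.integers(1, 3, len(rows))
    wjit = rng.uniform(0.85, 1.15, len(rows))
    cps = []
    for k in range(n_cp):
        t = k / (n_cp - 1)
        pairs = []
        for (i, layer), ph, fr, wj in zip(rows, phases, freqs, wjit):
            c = amp * math.sin(2 * math.pi * fr * t + ph)
            w = max(0.5, width * wj)
            pairs.append(LeafPair(max(-6.0, c - w / 2), min(6.0, c + w / 2),
                                  i, layer))
        cps.append(ControlPoint(tuple(pairs),
                                0.0 if k == 0 else 1.0 / (n_cp - 1),
                                gantry_angle=k * 354.0 / (n_cp - 1)))
    return Plan(tuple(cps), total_mu=600.0, name=name)


def _mu_profile(rng: np.random.Generator, n_seg: int) -> np.ndarray:
    """Normalized per-segment MU weights with a smooth random modulation
    (a sliding window's fluence follows the MU density along the sweep)."""
    k = np.arange(n_seg)
    ph1, ph2 = rng.uniform(0, 2 * np.pi, 2)
    w = 1.0 + 0.6 * np.sin(2 * np.pi * k / n_seg + ph1) \
        + 0.25 * np.sin(4 * np.pi * k / n_seg + ph2)
    w = np.clip(w, 0.4, None)
    return w / w.sum()


def _sw_vmat_plan(rng: np.random.Generator, machine: Machine, width: float,
                  name: str) -> Plan:
    n_cp = 60
    prox = rows_covering(-5.0, 5.0, Layer.PROXIMAL, machine)
    dist = rows_covering(-5.0, 5.0, Layer.DISTAL, machine)
    rows = [(i, Layer.PROXIMAL) for i in prox] + [(i, Layer.DISTAL) for i in dist]
    widths = np.maximum(0.5, width * rng.uniform(0.8, 1.2, len(rows)))
    mu = _mu_profile(rng, n_cp - 1)
    cps = []
    for k in range(n_cp):
        t = k / (n_cp - 1)
        c = -5.0 + 10.0 * t
        pairs = [LeafPair(c - w / 2, c + w / 2, i, layer)
                 for (i, layer), w in zip(rows, widths)]
        cps.append(ControlPoint(tuple(pairs),
                                0.0 if k == 0 else float(mu[k - 1]),
                                gantry_angle=k * 354.0 / (n_cp - 1)))
    return Plan(tuple(cps), total_mu=600.0, name=name)


def _dmlc_plan(rng: np.random.Generator, machine: Machine, width: float,
               name: str) -> Plan:
    n_angles, n_sub = 9, 8
    prox = rows_covering(-5.0, 5.0, Layer.PROXIMAL, machine)
    dist = rows_covering(-5.0, 5.0, Layer.DISTAL, machine)
    rows = [(i, Layer.PROXIMAL) for i in prox] + [(i, Layer.DISTAL) for i in dist]
    cps = []
    for a in range(n_angles):
        angle = a * 40.0
        widths = np.maximum(0.5, width * rng.uniform(0.8, 1.2, len(rows)))
        mu = _mu_profile(rng, n_sub - 1) / n_angles
        for k in range(n_sub):
            t = k / (n_sub - 1)
            c = -4.0 + 8.0 * t
            pairs = [LeafPair(c - w / 2, c + w / 2, i, layer)
                     for (i, layer), w in zip(rows, widths)]
            first_of_seg = (k == 0)
            cps.append(ControlPoint(
                tuple(pairs),
                0.0 if first_of_seg else float(mu[k - 1]),
                gantry_angle=angle))
    return Plan(tuple(cps), total_mu=600.0, name=name)


_BUILDERS = {"vmat": _vmat_plan, "sw_vmat": _sw_vmat_plan, "dmlc": _dmlc_plan}


def plan_dose(plan: Plan, machine: Machine, params: MLCParameters,
              grid: GridSpec = PLAN_GRID,
              max_substep_travel: float = 0.2) -> FluenceMap:
    """Relative plan dose plane (cGy per total_mu-scaled units)."""
    f = accumulate_dynamic_fluence(plan, params, machine, grid,
                                   max_substep_travel=max_substep_travel)
    d = dose_plane(f, PLAN_GEOMETRY, machine)
    return FluenceMap(d.x, d.y, d.values * plan.total_mu)


def _array_points(rng: np.random.Generator) -> np.ndarray:
    """Cylindrical diode-array sample positions projected on the dose
    plane: detectors at 10.5 cm radius, helically distributed."""
    n_phi = int(rng.integers(30, 43))
    ys = np.arange(-5.5, 5.5 + 1e-9, 0.5)
    pts = []
    for j, y in enumerate(ys):
        phis = 2 * np.pi * (np.arange(n_phi) + 0.5 * (j % 2)) / n_phi
        for ph in phis:
            pts.append((ARRAY_RADIUS_CM * math.sin(ph), y))
    return np.asarray(pts)


def gen_plan_suite(gt: GroundTruth, n_plans: int = 5,
                   technique: str = "vmat",
                   modulation: float = 6.0,
                   seed: int | None = None) -> PlanSuite:
    """Seeded suite of modulated plans with chamber and array measurements.

    Per plan: two chamber points (high dose at the isocenter, low dose at
    a noise-free ratio of 0.4-0.8 to the high point), noisy "measured"
    doses, and cylindrical-array samples at 10.5 cm radius.
    """
    if technique not in _BUILDERS:
        raise ValueError(f"unknown technique {technique!r}")
    if not (1.5 <= modulation <= 10.0):
        raise ValueError("modulation target must be within [1.5, 10] MU/cGy")
    seed = gt.seed if seed is None else seed
    # heuristic window width for the modulation target: iso duty cycle of
    # roughly 1/(modulation * PDD(10))
    width = float(np.clip(10.0 / (0.63 * modulation), 0.8, 5.0))
    items = []
    for k in range(n_plans):
        rng = np.random.default_rng([seed & 0x7FFFFFFF, 10 + k])
        for attempt in range(12):
            plan = _BUILDERS[technique](rng, gt.machine, width,
                                        name=f"{technique}_{k:02d}")
            rep = validate_plan(plan, gt.machine, gt.true_params)
            if not rep.valid:
                continue
            dmap = plan_dose(plan, gt.machine, gt.true_params)
            high = point_dose(dmap, (0.0, 0.0))
            if high <= 0:
                continue
            mod = plan.total_mu / high
            if not (1.5 <= mod <= 10.0):
                continue
            low_pt = None
            cand = [(x, y) for x in (-6.0, -4.0, -2.0, 2.0, 4.0, 6.0)
                    for y in (-4.0, -2.0, 0.0, 2.0, 4.0)]
            for ci in rng.permutation(len(cand)):
                x, y = cand[ci]
                d = point_dose(dmap, (x, y))
                if 0.4 * high <= d <= 0.8 * high:
                    low_pt, low = (x, y), d
                    break
            if low_pt is None:
                continue
            pts = _array_points(rng)
            arr = point_doses(dmap, pts)
            noise2 = gt.noise(rng, 2)
            arr_noise = gt.noise(rng, arr.shape)
            items.append(PlanMeasurement(
                plan=plan, technique=technique,
                chamber_points=((0.0, 0.0), low_pt),
                chamber_doses=(high * float(noise2[0]),
                               low * float(noise2[1])),
                array_points=pts,
                array_doses=arr * arr_noise,
                modulation_mu_per_cgy=mod,
                dose_ratio=low / high,
            ))
            break
        else:
            raise RuntimeError(
                f"could not build a valid {technique} plan (k={k}) under "
                f"kinematic limits at modulation {modulation}")
    return PlanSuite(items, technique, seed)


@dataclass
class SessionBundle:
    """Everything the commissioning pipeline consumes."""

    sweeps: MeasurementSet
    abutting: list[AbuttingJunction]
    bars: BarSession
    edges: list[EdgeField]
    plan_suites: list[PlanSuite]


def gen_bundle(gt: GroundTruth, n_plans_per_technique: int = 5,
               techniques: Sequence[str] = ("vmat", "sw_vmat", "dmlc"),
               sweep_positions: Sequence[float] = DEFAULT_POSITIONS_CM,
               ) -> SessionBundle:
    """Full virtual commissioning dataset from one ground truth."""
    return SessionBundle(
        sweeps=gen_sweep_session(gt, positions=sweep_positions),
        abutting=gen_abutting_session(gt),
        bars=gen_bar_session(gt, Layer.PROXIMAL),
        edges=gen_edge_session(gt),
        plan_suites=[gen_plan_suite(gt, n_plans_per_technique, t,
                                    seed=gt.seed + 100 + i)
                     for i, t in enumerate(techniques)],
    )
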