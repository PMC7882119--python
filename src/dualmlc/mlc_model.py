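"""Machine description and leaf-end position algebra for a dual-layer MLC.

The leaf-end model maps a nominal leaf position ``x_nom`` (cm in the
isocenter plane, IEC 61217, positive to the right of the central axis in
beam's-eye view for both banks) to the effective tip position used for
fluence calculation::

    X_left  = x_nom - offset + gain * x_nom - curvature * x_nom**2
    X_right = x_nom + offset + gain * x_nom + curvature * x_nom**2

Two derived quantities isolate the parameters: for an opposed pair planned
at the same ``x_nom``, the *dosimetric offset*
``dX_D = (X_right - X_left)/2 = offset + curvature * x_nom**2`` moves the
dosimetric field edge relative to the nominal one (offset and curvature
only), while the *midpoint shift*
``dX_MP = (X_left + X_right)/2 - x_nom = gain * x_nom`` moves the pair
midpoint (gain only).  This separation is what lets the commissioning
pipeline estimate each parameter from an isolating experiment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from enum import Enum
from typing import Iterable, Sequence

__all__ = [
    "Bank",
    "Layer",
    "MLCParameters",
    "Machine",
    "LeafPair",
    "ControlPoint",
    "Plan",
    "ApertureViolation",
    "ValidityReport",
    "leaf_tip_position",
    "dosimetric_offset",
    "midpoint_shift",
    "equivalent_square",
    "validate_aperture",
    "validate_plan",
    "row_span",
]

X_NOM_LIMIT = 14.0  # cm, half of the 28 cm maximum field


class Bank(str, Enum):
    LEFT = "left"
    RIGHT = "right"


class Layer(str, Enum):
    PROXIMAL = "proximal"
    DISTAL = "distal"


@dataclass(frozen=True)
class MLCParameters:
    """Fitted leaf-end model parameters.

    Parameters
    ----------
    offset : float
        Leaf-end offset, cm. Positive widens every gap dosimetrically.
    gain : float
        Dimensionless proportional position error; shifts pair midpoints.
    curvature : float
        Quadratic off-axis term, cm^-1 (coefficient of x_nom**2 in cm).
    tip_width : float
        Width of the raised-transmission tip zone, cm (half leaf height).
    layer_transmission : float
        Single-layer transmission fraction, in (0, 1).
    tng_width : float
        Tongue-and-groove strip width along leaf sides, cm.
    dynamic_min_gap : float
        Minimum allowed gap for moving leaf pairs, cm.
    """

    offset: float = 0.0
    gain: float = 0.0
    curvature: float = 0.0
    tip_width: float = 0.0
    layer_transmission: float = 0.0047
    tng_width: float = 0.05
    dynamic_min_gap: float = 0.06

    def __post_init__(self) -> None:
        if self.tip_width < 0:
            raise ValueError("tip_width must be >= 0")
        if self.tng_width < 0:
            raise ValueError("tng_width must be >= 0")
        if not (0.0 < self.layer_transmission < 1.0):
            raise ValueError("layer_transmission must be in (0, 1)")
        if self.dynamic_min_gap < 0:
            raise ValueError("dynamic_min_gap must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "MLCParameters":
        return cls(**d)


@dataclass(frozen=True)
class Machine:
    """Fixed geometry and beam constants of the ring-gantry linac.

    Distances in cm from the source unless noted.  The two leaf layers sit
    at the bottom-of-leaf distances; leaves are 1 cm wide physically, and
    the distal layer is staggered half a leaf width in Y so the effective
    resolution at isocenter is 0.5 cm.
    """

    sad: float = 100.0
    layer_distance_proximal: float = 38.9
    layer_distance_distal: float = 47.9
    max_field: float = 28.0
    effective_leaf_width: float = 0.5
    physical_leaf_width: float = 1.0
    d_max: float = 1.3
    source_sigma_x: float = 0.075
    source_sigma_y: float = 0.090
    max_leaf_speed: float = 5.0     # cm/s
    max_gantry_speed: float = 12.0  # deg/s
    min_mu_per_deg: float = 0.1
    max_mu_rate: float = 800.0 / 60.0  # MU/s (nominal 800 MU/min at d_max)

    def __post_init__(self) -> None:
        if not (0 < self.layer_distance_proximal < self.layer_distance_distal < self.sad):
            raise ValueError("layer distances must satisfy 0 < proximal < distal < sad")
        for name in ("sad", "max_field", "effective_leaf_width",
                     "physical_leaf_width", "d_max", "source_sigma_x",
                     "source_sigma_y", "max_leaf_speed", "max_gantry_speed",
                     "max_mu_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Machine":
        return cls(**d)


@dataclass(frozen=True)
class LeafPair:
    """One opposed leaf pair: open interval [x_nom_left, x_nom_right].

    ``y_index`` counts leaf rows within the layer; the physical Y span at
    isocenter is given by :func:`row_span`.
    """

    x_nom_left: float
    x_nom_right: float
    y_index: int
    layer: Layer

    def __post_init__(self) -> None:
        if self.x_nom_left > self.x_nom_right + 1e-12:
            raise ValueError("x_nom_left must be <= x_nom_right")
        lim = X_NOM_LIMIT + 1e-9
        if abs(self.x_nom_left) > lim or abs(self.x_nom_right) > lim:
            raise ValueError(
                f"nominal leaf positions must lie within +/-{X_NOM_LIMIT} cm"
            )

    @property
    def gap(self) -> float:
        return self.x_nom_right - self.x_nom_left


def row_span(y_index: int, layer: Layer | str, machine: Machine) -> tuple[float, float]:
    """Y extent (cm at isocenter) of a leaf row.

    Proximal rows tile [-14, 14] on integer-multiples of the physical leaf
    width; distal rows are staggered by half a leaf width, which is what
    produces the 0.5 cm effective resolution of the stacked pair.
    """
    w = machine.physical_leaf_width
    half = machine.max_field / 2.0
    if Layer(layer) is Layer.PROXIMAL:
        lo = -half + y_index * w
    else:
        lo = -half - w / 2.0 + y_index * w
    return lo, lo + w


@dataclass(frozen=True)
class ControlPoint:
    """A single MU-weighted machine state: apertures for both layers."""

    apertures: tuple[LeafPair, ...]
    mu_weight: float
    gantry_angle: float = 0.0

    def __post_init__(self) -> None:
        if self.mu_weight < 0:
            raise ValueError("mu_weight must be >= 0")
        seen = set()
        for lp in self.apertures:
            key = (lp.layer, lp.y_index)
            if key in seen:
                raise ValueError(f"duplicate leaf pair for {key}")
            seen.add(key)

    def layer_pairs(self, layer: Layer | str) -> tuple[LeafPair, ...]:
        layer = Layer(layer)
        return tuple(lp for lp in self.apertures if lp.layer is layer)


@dataclass(frozen=True)
class Plan:
    """Ordered control-point sequence; mu_weights sum to 1."""

    control_points: tuple[ControlPoint, ...]
    total_mu: float = 100.0
    name: str = ""

    def __post_init__(self) -> None:
        if not self.control_points:
            raise ValueError("plan needs at least one control point")
        s = sum(cp.mu_weight for cp in self.control_points)
        if not math.isclose(s, 1.0, rel_tol=0, abs_tol=1e-6):
            raise ValueError(f"mu_weights must sum to 1 (got {s})")
        if self.total_mu <= 0:
            raise ValueError("total_mu must be positive")


@dataclass(frozen=True)
class ApertureViolation:
    kind: str            # "field_size" | "min_gap" | "leaf_speed" | "mu_per_deg"
    message: str
    control_point: int
    y_index: int | None = None
    layer: str | None = None


@dataclass
class ValidityReport:
    violations: list[ApertureViolation] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not self.violations


def _check_bounds(x_nom: float) -> None:
    if abs(x_nom) > X_NOM_LIMIT + 1e-9:
        raise ValueError(
            f"x_nom={x_nom:g} cm outside the +/-{X_NOM_LIMIT} cm leaf travel range"
        )


def leaf_tip_position(x_nom: float, bank: Bank | str, params: MLCParameters) -> float:
    """Effective tip position (cm) for one bank under the leaf-end model."""
    _check_bounds(x_nom)
    bank = Bank(bank)
    d = params.offset + params.curvature * x_nom * x_nom
    if bank is Bank.LEFT:
        return x_nom + params.gain * x_nom - d
    return x_nom + params.gain * x_nom + d


def dosimetric_offset(x_nom: float, params: MLCParameters) -> float:
    """dX_D = (X_right - X_left)/2 for a pair planned at x_nom.

    Equals ``offset + curvature * x_nom**2``; independent of gain.
    """
    _check_bounds(x_nom)
    return params.offset + params.curvature * x_nom * x_nom


def midpoint_shift(x_nom: float, params: MLCParameters) -> float:
    """dX_MP = (X_left + X_right)/2 - x_nom.

    Equals ``gain * x_nom``; independent of offset and curvature.
    """
    _check_bounds(x_nom)
    return params.gain * x_nom


def equivalent_square(a: float, b: float) -> float:
    """Equivalent-square side of an a x b rectangular field: 2ab/(a+b)."""
    if a <= 0 or b <= 0:
        raise ValueError("field sides must be positive")
    return 2.0 * a * b / (a + b)


def _moving_pairs(plan: Plan) -> set[tuple[Layer, int]]:
    """Keys of leaf pairs whose nominal positions change anywhere in the plan."""
    first: dict[tuple[Layer, int], tuple[float, float]] = {}
    moving: set[tuple[Layer, int]] = set()
    for cp in plan.control_points:
        for lp in cp.apertures:
            key = (lp.layer, lp.y_index)
            pos = (lp.x_nom_left, lp.x_nom_right)
            if key in first:
                if (abs(first[key][0] - pos[0]) > 1e-9
                        or abs(first[key][1] - pos[1]) > 1e-9):
                    moving.add(key)
            else:
                first[key] = pos
    return moving


def validate_aperture(plan: Plan, machine: Machine, params: MLCParameters) -> ValidityReport:
    """Kinematic and geometric validity of a plan's aperture sequence.

    Checks, per the machine's delivery constraints: field extent within the
    maximum field, dynamic leaf pairs keeping at least the dynamic minimum
    gap, leaf speed within the maximum given the segment time allowed by
    gantry speed and MU rate, and MU/deg above the deliverable floor for
    arc segments.
    """
    report = ValidityReport()
    half = machine.max_field / 2.0
    moving = _moving_pairs(plan)
    dynamic = len(plan.control_points) > 1

    for i, cp in enumerate(plan.control_points):
        for lp in cp.apertures:
            if abs(lp.x_nom_left) > half + 1e-9 or abs(lp.x_nom_right) > half + 1e-9:
                report.violations.append(ApertureViolation(
                    "field_size",
                    f"leaf positions ({lp.x_nom_left:g}, {lp.x_nom_right:g}) "
                    f"exceed +/-{half:g} cm",
                    i, lp.y_index, lp.layer.value,
                ))
            lo, hi = row_span(lp.y_index, lp.layer, machine)
            if lo < -half - 1e-9 or hi > half + 1e-9:
                report.violations.append(ApertureViolation(
                    "field_size",
                    f"row span ({lo:g}, {hi:g}) exceeds +/-{half:g} cm",
                    i, lp.y_index, lp.layer.value,
                ))
            key = (lp.layer, lp.y_index)
            if dynamic and key in moving and 0 < lp.gap < params.dynamic_min_gap - 1e-9:
                report.violations.append(ApertureViolation(
                    "min_gap",
                    f"moving pair gap {lp.gap:g} cm < dynamic minimum "
                    f"{params.dynamic_min_gap:g} cm",
                    i, lp.y_index, lp.layer.value,
                ))

    # segment kinematics between consecutive control points
    for i in range(1, len(plan.control_points)):
        prev, cur = plan.control_points[i - 1], plan.control_points[i]
        d_mu = cur.mu_weight * plan.total_mu
        d_gantry = abs(cur.gantry_angle - prev.gantry_angle)
        t_avail = max(d_gantry / machine.max_gantry_speed,
                      d_mu / machine.max_mu_rate)
        prev_pos = {(lp.layer, lp.y_index): lp for lp in prev.apertures}
        max_travel = 0.0
        worst: LeafPair | None = None
        for lp in cur.apertures:
            p = prev_pos.get((lp.layer, lp.y_index))
            if p is None:
                continue
            travel = max(abs(lp.x_nom_left - p.x_nom_left),
                         abs(lp.x_nom_right - p.x_nom_right))
            if travel > max_travel:
                max_travel, worst = travel, lp
        if max_travel > 0 and max_travel > machine.max_leaf_speed * t_avail * (1 + 1e-9):
            report.violations.append(ApertureViolation(
                "leaf_speed",
                f"leaf travel {max_travel:g} cm in {t_avail:g} s requires "
                f"{max_travel / t_avail if t_avail > 0 else math.inf:.2f} cm/s "
                f"> {machine.max_leaf_speed:g} cm/s",
                i,
                worst.y_index if worst else None,
                worst.layer.value if worst else None,
            ))
        # the MU/deg floor applies to arc segments that deliver dose;
        # beam-off gantry repositioning is exempt
        if d_gantry > 1e-9 and d_mu > 0:
            mu_per_deg = d_mu / d_gantry
            if mu_per_deg < machine.min_mu_per_deg * (1 - 1e-9):
                report.violations.append(ApertureViolation(
                    "mu_per_deg",
                    f"{mu_per_deg:.4f} MU/deg < minimum "
                    f"{machine.min_mu_per_deg:g} MU/deg",
                    i,
                ))
    return report


# alias matching the plan-level contract
validate_plan = validate_aperture
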