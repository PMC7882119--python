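"""File formats: JSON for machines, parameters and plans; CSV (with
'#'-prefixed metadata header lines) for measurements, profiles and maps.

All lengths are cm except sweeping-gap widths, which are recorded in mm
as is conventional for that measurement; units are named in headers.
Round-trips are lossless to 1e-9 relative precision.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from .dose import Axis, Profile1D
from .fluence import FluenceMap
from .mlc_model import (
    ControlPoint,
    Layer,
    LeafPair,
    Machine,
    MLCParameters,
    Plan,
)
from .virtual_lab import (
    AbuttingJunction,
    BarSession,
    EdgeField,
    MeasurementRecord,
    MeasurementSet,
    PlanMeasurement,
    PlanSuite,
    SessionBundle,
)

__all__ = [
    "RunConfig",
    "write_machine",
    "read_machine",
    "write_plan",
    "read_plan",
    "write_measurements",
    "read_measurements",
    "write_profile",
    "read_profile",
    "write_map",
    "read_map",
    "write_map_csv",
    "read_map_csv",
    "write_histogram",
    "plan_to_dicom_rtplan",
    "save_bundle",
    "load_bundle",
]


class RunConfig(BaseModel):
    """Serializable run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    noise_sd: float = 0.005
    grid_spacing: float = 0.1
    n_plans_per_technique: int = 5
    techniques: tuple[str, ...] = ("vmat", "sw_vmat", "dmlc")
    gamma_criteria: tuple[str, ...] = ("3G2", "2L2")
    gamma_threshold: float = 10.0
    rms_offset_candidates: tuple[float, ...] = (
        -0.03, -0.02, -0.01, 0.0, 0.01, 0.02, 0.03)
    tng_candidates: tuple[float, ...] = (0.0, 0.02, 0.04, 0.05, 0.06,
                                         0.08, 0.1)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2))


# ---------------------------------------------------------------------------
# machine / parameters / plan JSON

def write_machine(path: str | Path, machine: Machine,
                  params: MLCParameters) -> None:
    Path(path).write_text(json.dumps(
        {"machine": machine.to_dict(), "mlc_parameters": params.to_dict()},
        indent=2))


def read_machine(path: str | Path) -> tuple[Machine, MLCParameters]:
    d = json.loads(Path(path).read_text())
    try:
        return (Machine.from_dict(d["machine"]),
                MLCParameters.from_dict(d["mlc_parameters"]))
    except (KeyError, TypeError) as e:
        raise ValueError(f"malformed machine file {path}: {e}") from e


def _plan_to_dict(plan: Plan) -> dict:
    return {
        "name": plan.name,
        "total_mu": plan.total_mu,
        "control_points": [
            {
                "mu_weight": cp.mu_weight,
                "gantry_angle": cp.gantry_angle,
                "apertures": [
                    {"layer": lp.layer.value, "y_index": lp.y_index,
                     "x_left": lp.x_nom_left, "x_right": lp.x_nom_right}
                    for lp in cp.apertures
                ],
            }
            for cp in plan.control_points
        ],
    }


def _plan_from_dict(d: dict) -> Plan:
    cps = []
    for c in d["control_points"]:
        pairs = tuple(
            LeafPair(a["x_left"], a["x_right"], a["y_index"],
                     Layer(a["layer"]))
            for a in c["apertures"])
        cps.append(ControlPoint(pairs, c["mu_weight"], c["gantry_angle"]))
    return Plan(tuple(cps), total_mu=d["total_mu"], name=d.get("name", ""))


def write_plan(path: str | Path, plan: Plan) -> None:
    Path(path).write_text(json.dumps(_plan_to_dict(plan), indent=1))


def read_plan(path: str | Path) -> Plan:
    try:
        return _plan_from_dict(json.loads(Path(path).read_text()))
    except (KeyError, TypeError) as e:
        raise ValueError(f"malformed plan file {path}: {e}") from e


# ---------------------------------------------------------------------------
# CSV helpers

def _write_csv(path: Path, df: pd.DataFrame, meta: dict[str, Any]) -> None:
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False, float_format="%.10g")


def _read_csv(path: Path) -> tuple[pd.DataFrame, dict[str, str]]:
    import io as _io
    meta = {}
    lines = Path(path).read_text().splitlines(keepends=True)
    n_head = 0
    for line in lines:
        if not line.startswith("#"):
            break
        k, _, v = line[1:].partition(":")
        meta[k.strip()] = v.strip()
        n_head += 1
    df = pd.read_csv(_io.StringIO("".join(lines[n_head:])))
    return df, meta


def write_measurements(path: str | Path, mset: MeasurementSet) -> None:
    df = pd.DataFrame([{
        "kind": r.kind,
        "gap_mm": r.gap_mm if r.gap_mm is not None else np.nan,
        "position_cm": r.position_cm,
        "depth_cm": r.depth_cm,
        "ssd_cm": r.ssd_cm,
        "detector": r.detector,
        "reading": r.reading,
    } for r in mset.records])
    _write_csv(Path(path), df, {"format": "dualmlc-measurements-v1",
                                "units": "gap mm, lengths cm"})


def read_measurements(path: str | Path) -> MeasurementSet:
    df, meta = _read_csv(Path(path))
    required = {"kind", "gap_mm", "position_cm", "depth_cm", "ssd_cm",
                "detector", "reading"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"malformed measurement file {path}: missing columns "
            f"{sorted(required - set(df.columns))}")
    records = [
        MeasurementRecord(
            kind=row.kind,
            reading=float(row.reading),
            gap_mm=None if pd.isna(row.gap_mm) else float(row.gap_mm),
            position_cm=float(row.position_cm),
            depth_cm=float(row.depth_cm),
            ssd_cm=float(row.ssd_cm),
            detector=row.detector,
        )
        for row in df.itertuples()
    ]
    return MeasurementSet(records)


def write_profile(path: str | Path, p: Profile1D, **meta: Any) -> None:
    df = pd.DataFrame({"position_cm": p.positions, "value": p.values})
    _write_csv(Path(path), df, {"format": "dualmlc-profile-v1",
                                "axis": p.axis.value, **meta})


def read_profile(path: str | Path) -> Profile1D:
    df, meta = _read_csv(Path(path))
    if "position_cm" not in df.columns or "value" not in df.columns:
        raise ValueError(f"malformed profile file {path}")
    return Profile1D(df["position_cm"].to_numpy(),
                     df["value"].to_numpy(),
                     Axis(meta.get("axis", "X")))


def write_map(path: str | Path, m: FluenceMap, **meta: Any) -> None:
    """Grid text format: two '#' header lines carry the axes."""
    with open(Path(path), "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        fh.write("# x_cm: " + " ".join(f"{v:.10g}" for v in m.x) + "\n")
        fh.write("# y_cm: " + " ".join(f"{v:.10g}" for v in m.y) + "\n")
        np.savetxt(fh, m.values, fmt="%.10g", delimiter=",")


def write_map_csv(path: str | Path, m: FluenceMap, **meta: Any) -> None:
    """Long-format map export: one (x_cm, y_cm, value) row per pixel."""
    gx, gy = np.meshgrid(m.x, m.y)
    df = pd.DataFrame({"x_cm": gx.ravel(), "y_cm": gy.ravel(),
                       "value": m.values.ravel()})
    _write_csv(Path(path), df, {"format": "dualmlc-map-csv-v1", **meta})


def read_map_csv(path: str | Path) -> FluenceMap:
    df, _ = _read_csv(Path(path))
    if not {"x_cm", "y_cm", "value"}.issubset(df.columns):
        raise ValueError(f"malformed map CSV {path}")
    x = np.unique(df["x_cm"].to_numpy())
    y = np.unique(df["y_cm"].to_numpy())
    piv = df.pivot(index="y_cm", columns="x_cm", values="value")
    return FluenceMap(x, y, piv.to_numpy())


def write_histogram(path: str | Path, edges: np.ndarray,
                    counts: np.ndarray, **meta: Any) -> None:
    """Dose-error histogram export (bin edges in %, counts)."""
    df = pd.DataFrame({"bin_low_percent": edges[:-1],
                       "bin_high_percent": edges[1:],
                       "count": counts})
    _write_csv(Path(path), df, {"format": "dualmlc-histogram-v1", **meta})


def plan_to_dicom_rtplan(plan: Plan):  # pragma: no cover - extension point
    """Documented extension point: export a plan as a DICOM RT Plan.

    Not implemented — the pipeline's native format is the JSON plan file
    (see :func:`write_plan`); a converter would map control points to
    BeamSequence/ControlPointSequence items with per-layer leaf
    boundaries.
    """
    raise NotImplementedError(
        "DICOM RT Plan conversion is a documented extension point")


def read_map(path: str | Path) -> FluenceMap:
    x = y = None
    skip = 0
    with open(Path(path)) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            if line.startswith("# x_cm:"):
                x = np.array([float(v) for v in line.split(":", 1)[1].split()])
            elif line.startswith("# y_cm:"):
                y = np.array([float(v) for v in line.split(":", 1)[1].split()])
    if x is None or y is None:
        raise ValueError(f"malformed map file {path}: missing axis headers")
    vals = np.loadtxt(Path(path), delimiter=",", skiprows=skip, ndmin=2)
    return FluenceMap(x, y, vals)


# ---------------------------------------------------------------------------
# session bundle

def save_bundle(outdir: str | Path, bundle: SessionBundle,
                seed: int, noise_sd: float) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_measurements(out / "sweeps.csv", bundle.sweeps)

    rows = []
    for j in bundle.abutting:
        for comp, prof in (("a", j.profile_a), ("b", j.profile_b),
                           ("sum", j.profile_sum)):
            for x, v in zip(prof.positions, prof.values):
                rows.append({"junction_cm": j.junction_cm, "component": comp,
                             "position_cm": x, "value": v})
    _write_csv(out / "abutting.csv", pd.DataFrame(rows),
               {"format": "dualmlc-abutting-v1"})

    rows = []
    for comp, prof in (("a", bundle.bars.profile_a),
                       ("b", bundle.bars.profile_b),
                       ("sum", bundle.bars.profile_sum)):
        for x, v in zip(prof.positions, prof.values):
            rows.append({"component": comp, "position_cm": x, "value": v})
    _write_csv(out / "bars.csv", pd.DataFrame(rows),
               {"format": "dualmlc-bars-v1",
                "layer": bundle.bars.layer.value})

    rows = []
    for e in bundle.edges:
        for x, v in zip(e.profile.positions, e.profile.values):
            rows.append({"center_cm": e.center_cm, "width_cm": e.width_cm,
                         "position_cm": x, "value": v})
    _write_csv(out / "edges.csv", pd.DataFrame(rows),
               {"format": "dualmlc-edges-v1"})

    plan_dir = out / "plans"
    plan_dir.mkdir(exist_ok=True)
    rows = []
    inventory = []
    for suite in bundle.plan_suites:
        for it in suite.items:
            write_plan(plan_dir / f"{it.plan.name}.json", it.plan)
            inventory.append(it.plan.name)
            for tag, pt, dose in (
                    ("high", it.chamber_points[0], it.chamber_doses[0]),
                    ("low", it.chamber_points[1], it.chamber_doses[1])):
                rows.append({"plan": it.plan.name, "technique": it.technique,
                             "point": tag, "x_cm": pt[0], "y_cm": pt[1],
                             "dose": dose,
                             "modulation_mu_per_cgy": it.modulation_mu_per_cgy,
                             "dose_ratio": it.dose_ratio,
                             "suite_seed": suite.seed})
            for i, (pt, dose) in enumerate(zip(it.array_points,
                                               it.array_doses)):
                rows.append({"plan": it.plan.name, "technique": it.technique,
                             "point": f"array_{i}", "x_cm": pt[0],
                             "y_cm": pt[1], "dose": dose,
                             "modulation_mu_per_cgy": it.modulation_mu_per_cgy,
                             "dose_ratio": it.dose_ratio,
                             "suite_seed": suite.seed})
    _write_csv(out / "plan_measurements.csv", pd.DataFrame(rows),
               {"format": "dualmlc-plan-measurements-v1"})

    digest = hashlib.sha256(
        json.dumps({"seed": seed, "inventory": inventory},
                   sort_keys=True).encode()).hexdigest()
    (out / "manifest.json").write_text(json.dumps({
        "seed": seed,
        "noise_sd": noise_sd,
        "ground_truth_hash": digest,
        "sessions": ["sweeps", "abutting", "bars", "edges", "plans"],
        "n_plans": len(inventory),
    }, indent=2))


def load_bundle(indir: str | Path) -> SessionBundle:
    src = Path(indir)
    sweeps = read_measurements(src / "sweeps.csv")

    df, _ = _read_csv(src / "abutting.csv")
    abutting = []
    for j, grp in df.groupby("junction_cm", sort=True):
        profs = {}
        for comp, g in grp.groupby("component"):
            g = g.sort_values("position_cm")
            profs[comp] = Profile1D(g["position_cm"].to_numpy(),
                                    g["value"].to_numpy(), Axis.X)
        abutting.append(AbuttingJunction(float(j), profs["a"], profs["b"],
                                         profs["sum"]))

    df, meta = _read_csv(src / "bars.csv")
    profs = {}
    for comp, g in df.groupby("component"):
        g = g.sort_values("position_cm")
        profs[comp] = Profile1D(g["position_cm"].to_numpy(),
                                g["value"].to_numpy(), Axis.Y)
    bars = BarSession(Layer(meta.get("layer", "proximal")),
                      profs["a"], profs["b"], profs["sum"])

    df, _ = _read_csv(src / "edges.csv")
    edges = []
    for (c, w), g in df.groupby(["center_cm", "width_cm"], sort=True):
        g = g.sort_values("position_cm")
        edges.append(EdgeField(float(c), float(w),
                               Profile1D(g["position_cm"].to_numpy(),
                                         g["value"].to_numpy(), Axis.X)))

    df, _ = _read_csv(src / "plan_measurements.csv")
    suites: dict[str, list[PlanMeasurement]] = {}
    seeds: dict[str, int] = {}
    for plan_name, g in df.groupby("plan", sort=True):
        plan = read_plan(src / "plans" / f"{plan_name}.json")
        tech = g["technique"].iloc[0]
        high = g[g["point"] == "high"].iloc[0]
        low = g[g["point"] == "low"].iloc[0]
        arr = g[g["point"].str.startswith("array_")].copy()
        arr["idx"] = arr["point"].str.slice(6).astype(int)
        arr = arr.sort_values("idx")
        item = PlanMeasurement(
            plan=plan, technique=tech,
            chamber_points=((float(high.x_cm), float(high.y_cm)),
                            (float(low.x_cm), float(low.y_cm))),
            chamber_doses=(float(high.dose), float(low.dose)),
            array_points=arr[["x_cm", "y_cm"]].to_numpy(),
            array_doses=arr["dose"].to_numpy(),
            modulation_mu_per_cgy=float(high.modulation_mu_per_cgy),
            dose_ratio=float(high.dose_ratio),
        )
        suites.setdefault(tech, []).append(item)
        seeds[tech] = int(high.suite_seed)
    plan_suites = [PlanSuite(items, tech, seeds[tech])
                   for tech, items in sorted(suites.items())]
    return SessionBundle(sweeps=sweeps, abutting=abutting, bars=bars,
                         edges=edges, plan_suites=plan_suites)
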