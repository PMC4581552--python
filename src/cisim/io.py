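"""Plain-text file formats for profiles, contours, plans, traces and
summaries.

All geometry files are in millimetres.  CSV files carry the numeric tables;
a JSON sidecar (same stem, ``.json``) carries labels, units and the
configuration needed to reconstruct in-memory objects exactly.  Coordinate
convention, recorded in every header: cochleostomy at the origin, insertion
direction toward -x.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cochlea import CochleaContour2D
from .electrode import (
    N_CONTACTS,
    CurlingProfile,
    ElectrodeConfig,
    profile_from_config,
)
from .errors import InvalidInputError
from .strategies import InsertionPlan, InsertionPose, SimulationTrace
from .trauma import TraumaGrade

__all__ = [
    "write_profile",
    "read_profile",
    "write_contour",
    "read_contour",
    "write_plan",
    "read_plan",
    "write_trace",
    "read_trace",
    "write_outline",
]

_HEADER_COMMON = {
    "units": "mm",
    "frame": "cochleostomy at origin, insertion toward -x",
}


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def _fmt(x: float) -> str:
    return format(float(x), ".9g")


# ---------------------------------------------------------------------------
# curling profiles
# ---------------------------------------------------------------------------

def write_profile(profile: CurlingProfile, path) -> Path:
    """One row per (extraction step, landmark): tip and contacts c01..c22."""
    path = Path(path)
    ids = [f"c{i:02d}" for i in range(1, N_CONTACTS + 1)]
    with open(path, "w") as fh:
        fh.write("s_mm,landmark_id,x_mm,y_mm\n")
        for st in profile.states:
            s = _fmt(st.stylet_extraction_s)
            fh.write(f"{s},tip,{_fmt(st.tip_point[0])},{_fmt(st.tip_point[1])}\n")
            for lid, p in zip(ids, st.contact_positions):
                fh.write(f"{s},{lid},{_fmt(p[0])},{_fmt(p[1])}\n")
    header = {
        **_HEADER_COMMON,
        "label": profile.label,
        "s_max": profile.s_max,
        "L": profile.config.total_length,
        "config": dataclasses.asdict(profile.config),
        "meta": _jsonify(profile.meta),
    }
    _sidecar(path).write_text(json.dumps(_jsonify(header), indent=1, sort_keys=True))
    return path


def read_profile(path) -> CurlingProfile:
    """Read and validate a curling-profile file; the shape states are
    rebuilt from the sidecar configuration (landmarks are cross-checked)."""
    path = Path(path)
    df = pd.read_csv(path)
    need = {"s_mm", "landmark_id", "x_mm", "y_mm"}
    if not need.issubset(df.columns):
        raise InvalidInputError(f"profile CSV must have columns {sorted(need)}")
    counts = df.groupby("s_mm")["landmark_id"].count()
    if not (counts == N_CONTACTS + 1).all():
        raise InvalidInputError("each extraction step needs 23 landmarks (tip + 22)")
    s_vals = np.array(sorted(counts.index))
    if not np.all(np.diff(s_vals) > 0):
        raise InvalidInputError("extraction steps must be strictly increasing")
    header = json.loads(_sidecar(path).read_text())
    cfg = ElectrodeConfig(
        **{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in header["config"].items()
        }
    )
    profile = profile_from_config(cfg, label=header["label"], meta=header.get("meta", {}))
    if len(profile.states) != len(s_vals) or not np.allclose(
        profile.s_values, s_vals, atol=1e-9
    ):
        raise InvalidInputError("profile CSV steps do not match the sidecar config")
    tips = df[df.landmark_id == "tip"].sort_values("s_mm")[["x_mm", "y_mm"]].to_numpy()
    if not np.allclose(tips, profile.tip_trajectory, atol=1e-6):
        raise InvalidInputError("tip landmarks inconsistent with the sidecar config")
    return profile


# ---------------------------------------------------------------------------
# cochlear contours
# ---------------------------------------------------------------------------

def write_contour(contour: CochleaContour2D, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("contour,order_index,x_mm,y_mm\n")
        for name, pts in (("inner", contour.inner_contour), ("outer", contour.outer_contour)):
            for i, p in enumerate(pts):
                fh.write(f"{name},{i},{_fmt(p[0])},{_fmt(p[1])}\n")
    header = {
        **_HEADER_COMMON,
        "cochleostomy": _jsonify(contour.cochleostomy_point),
        "entry_direction": _jsonify(contour.entry_direction),
        "A_mm": contour.distance_A,
        "size_class": contour.size_class,
        "narrow_lumen_warning": contour.narrow_lumen_warning,
        "meta": _jsonify(contour.meta),
    }
    _sidecar(path).write_text(json.dumps(_jsonify(header), indent=1, sort_keys=True))
    return path


def read_contour(path) -> CochleaContour2D:
    path = Path(path)
    df = pd.read_csv(path)
    need = {"contour", "order_index", "x_mm", "y_mm"}
    if not need.issubset(df.columns):
        raise InvalidInputError(f"contour CSV must have columns {sorted(need)}")
    header = json.loads(_sidecar(path).read_text())
    parts = {}
    for name in ("inner", "outer"):
        sub = df[df.contour == name].sort_values("order_index")
        if len(sub) < 3:
            raise InvalidInputError(f"{name} contour missing or too short")
        parts[name] = sub[["x_mm", "y_mm"]].to_numpy()
    return CochleaContour2D(
        inner_contour=parts["inner"],
        outer_contour=parts["outer"],
        cochleostomy_point=np.asarray(header["cochleostomy"], dtype=float),
        entry_direction=np.asarray(header["entry_direction"], dtype=float),
        distance_A=header.get("A_mm"),
        size_class=header.get("size_class", "custom"),
        narrow_lumen_warning=header.get("narrow_lumen_warning", False),
        meta=header.get("meta", {}),
    )


# ---------------------------------------------------------------------------
# insertion plans
# ---------------------------------------------------------------------------

def write_plan(plan: InsertionPlan, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("s_mm,dx_mm,dy_mm,dphi_deg\n")
        for s, p in plan.steps:
            fh.write(f"{_fmt(s)},{_fmt(p.dx)},{_fmt(p.dy)},{_fmt(p.dphi)}\n")
    header = {
        **_HEADER_COMMON,
        "strategy": plan.strategy,
        "constraints": _jsonify(plan.constraints_record),
    }
    _sidecar(path).write_text(json.dumps(_jsonify(header), indent=1, sort_keys=True))
    return path


def read_plan(path) -> InsertionPlan:
    path = Path(path)
    df = pd.read_csv(path)
    need = {"s_mm", "dx_mm", "dy_mm", "dphi_deg"}
    if not need.issubset(df.columns):
        raise InvalidInputError(f"plan CSV must have columns {sorted(need)}")
    header = json.loads(_sidecar(path).read_text())
    steps = [
        (float(r.s_mm), InsertionPose(float(r.dx_mm), float(r.dy_mm), float(r.dphi_deg)))
        for r in df.itertuples()
    ]
    return InsertionPlan(
        strategy=header["strategy"],
        steps=steps,
        constraints_record=header.get("constraints", {}),
    )


# ---------------------------------------------------------------------------
# simulation traces
# ---------------------------------------------------------------------------

_ROMAN = {g.value: g.roman for g in TraumaGrade}

_TRACE_COLUMNS = [
    "s_mm",
    "dx_mm",
    "dy_mm",
    "dphi_deg",
    "grade",
    "tip_overlap_fraction",
    "tip_outside_whole",
    "body_penetration_fraction",
    "contact_regions",
    "restraint_flag",
    "far_outside_flag",
    "total_overlap_area_mm2",
    "max_penetration_depth_mm",
    "first_contact_depth_mm",
    "tip_incidence_deg",
    "canal_violation",
]


def write_trace(trace: SimulationTrace, path) -> Path:
    """Per-step overlap features and grade (grades serialized 0..4; the
    Roman labels are recorded in the summary sidecar)."""
    path = Path(path)
    rows = []
    for st in trace.steps:
        r = st.report
        rows.append(
            {
                "s_mm": st.s,
                "dx_mm": st.pose.dx,
                "dy_mm": st.pose.dy,
                "dphi_deg": st.pose.dphi,
                "grade": int(st.grade),
                "tip_overlap_fraction": r.tip_overlap_fraction,
                "tip_outside_whole": r.tip_outside_whole,
                "body_penetration_fraction": r.body_penetration_fraction,
                "contact_regions": r.contact_regions,
                "restraint_flag": r.restraint_flag,
                "far_outside_flag": r.far_outside_flag,
                "total_overlap_area_mm2": r.total_overlap_area,
                "max_penetration_depth_mm": r.max_penetration_depth,
                "first_contact_depth_mm": r.first_contact_depth,
                "tip_incidence_deg": r.tip_incidence_deg,
                "canal_violation": st.canal_violation,
            }
        )
    pd.DataFrame(rows, columns=_TRACE_COLUMNS).to_csv(path, index=False)
    hist = trace.histogram
    summary = {
        **_HEADER_COMMON,
        "strategy": trace.strategy,
        "profile": trace.profile_label,
        "cochlea": trace.cochlea_label,
        "n_steps": len(trace.steps),
        "grade_labels": _ROMAN,
        "histogram": {_ROMAN[i]: float(hist[i]) for i in range(5)},
        "mean_grade": trace.mean_grade,
        "total_overlap_cost": trace.total_cost,
    }
    _sidecar(path).write_text(json.dumps(_jsonify(summary), indent=1, sort_keys=True))
    return path


def read_trace(path) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    df = pd.read_csv(path)
    missing = set(_TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidInputError(f"trace CSV missing columns {sorted(missing)}")
    summary = json.loads(_sidecar(path).read_text())
    return df, summary


def write_outline(outline, path) -> Path:
    """Closed areal outline polygon as CSV (x_mm, y_mm) plus a GeoJSON-style
    sidecar."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("x_mm,y_mm\n")
        for p in outline.ring:
            fh.write(f"{_fmt(p[0])},{_fmt(p[1])}\n")
    geo = {
        "type": "Feature",
        "geometry": {
            "type": "Polygon",
            "coordinates": [_jsonify(np.vstack([outline.ring, outline.ring[:1]]))],
        },
        "properties": {**_HEADER_COMMON, "trimmed": outline.trimmed},
    }
    _sidecar(path).write_text(json.dumps(geo, indent=1))
    return path
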