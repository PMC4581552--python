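"""Insertion plans and the step-by-step insertion simulator.

A plan assigns to every stylet-extraction step ``s`` a rigid pose of the
electrode relative to the cochlea: feed ``dx`` along the insertion axis
(positive = deeper, applied as a translation along -x), lateral offset
``dy``, and a rotation ``dphi`` about the cochleostomy point.  Three
scenarios are modelled:

* ``autoAOS`` — automated advance-off-stylet through a minimally invasive
  drill canal: ``dy`` and ``dphi`` frozen after initial positioning, feed
  coupled 1:1 to stylet extraction;
* ``manAOS`` — the manual technique, in which the surgeon intuitively
  compensates the imperfect start configuration; the compensation is a
  rotation about the cochleostomy, emulated by a greedy per-step overlap
  minimization over ``dphi`` under a rotation-rate cap;
* ``optIns`` — the individually optimized plan produced by
  :mod:`cisim.optimize`.

The simulator places the areal outline at every step, computes the overlap
report, assigns a trauma-risk grade, and aggregates the grade histogram
normalized by the number of investigated steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cochlea import CochleaContour2D
from .electrode import CurlingProfile, ElectrodeOutline, build_outline
from .errors import InvalidPlanError
from .geometry import rot2d
from .trauma import (
    GradingConfig,
    StepCostField,
    TraumaGrade,
    compute_overlap,
    exact_step_cost,
    grade,
    grade_distribution,
)

__all__ = [
    "InsertionPose",
    "InsertionPlan",
    "TraceStep",
    "SimulationTrace",
    "ManAOSConfig",
    "place_electrode",
    "plan_autoAOS",
    "plan_manAOS",
    "simulate",
    "state_outlines",
    "DEFAULT_CANAL_DIAMETER",
]

DEFAULT_CANAL_DIAMETER = 2.0  # mm drill-canal bore used for guide lines


@dataclass(frozen=True)
class InsertionPose:
    """Rigid placement parameters: feed, lateral offset, rotation."""

    dx: float = 0.0  # mm along -x; positive = deeper insertion
    dy: float = 0.0  # mm lateral
    dphi: float = 0.0  # degrees about the cochleostomy point

    def as_array(self) -> np.ndarray:
        return np.array([self.dx, self.dy, self.dphi])


@dataclass
class InsertionPlan:
    """Pose per extraction step under one strategy's constraints."""

    strategy: str  # manAOS | autoAOS | optIns
    steps: list[tuple[float, InsertionPose]]
    constraints_record: dict = field(default_factory=dict)

    def __post_init__(self):
        s = self.s_values
        if not np.all(np.diff(s) > 0):
            raise InvalidPlanError("plan extraction values must be strictly increasing")
        dx = np.array([p.dx for _, p in self.steps])
        if np.any(np.diff(dx) < -1e-9):
            raise InvalidPlanError("implant feed dx must be non-decreasing")
        if self.strategy == "autoAOS" and len(self.steps) > 1:
            dy = {round(p.dy, 12) for _, p in self.steps}
            dphi = {round(p.dphi, 12) for _, p in self.steps}
            if len(dy) > 1 or len(dphi) > 1:
                raise InvalidPlanError("autoAOS requires constant dy and dphi")

    @property
    def s_values(self) -> np.ndarray:
        return np.array([s for s, _ in self.steps])

    @property
    def poses(self) -> np.ndarray:
        return np.array([[p.dx, p.dy, p.dphi] for _, p in self.steps])

    @property
    def dx_final(self) -> float:
        return float(self.steps[-1][1].dx)


def place_electrode(
    outline_or_state,
    pose: InsertionPose,
    cochleostomy=(0.0, 0.0),
) -> ElectrodeOutline:
    """Rigidly place an electrode outline: rotate by ``dphi`` about the
    cochleostomy, then translate by ``(-dx, +dy)``.

    Accepts a prebuilt :class:`ElectrodeOutline` or a :class:`ShapeState`
    (an outline is built first).  Area and arc length are preserved.
    """
    outline = (
        outline_or_state
        if isinstance(outline_or_state, ElectrodeOutline)
        else build_outline(outline_or_state)
    )
    pivot = np.asarray(cochleostomy, dtype=float)
    R = rot2d(np.deg2rad(pose.dphi))
    t = np.array([-pose.dx, pose.dy])

    def move(pts):
        return (np.asarray(pts) - pivot) @ R.T + pivot + t

    return ElectrodeOutline(
        ring=move(outline.ring),
        tip_ring=move(outline.tip_ring),
        path=move(outline.path),
        path_u=outline.path_u.copy(),
        normals=np.asarray(outline.normals) @ R.T,
        widths=outline.widths.copy(),
        total_length=outline.total_length,
        trimmed=outline.trimmed,
    )


def state_outlines(profile: CurlingProfile) -> dict[float, ElectrodeOutline]:
    """Canonical-frame outline per stored state, keyed by extraction s."""
    return {float(st.stylet_extraction_s): build_outline(st) for st in profile.states}


def _canal_lines(initial_pose: InsertionPose, diameter: float) -> list:
    """Two parallel guide lines marking the drill canal / guiding tube."""
    y0 = initial_pose.dy
    r = diameter / 2.0
    return [
        [[-2.0, y0 - r], [30.0, y0 - r]],
        [[-2.0, y0 + r], [30.0, y0 + r]],
    ]


def plan_autoAOS(
    profile: CurlingProfile,
    contour: CochleaContour2D,
    initial_pose: InsertionPose | None = None,
) -> InsertionPlan:
    """Automated advance-off-stylet: feed coupled 1:1 to extraction, lateral
    offset and rotation frozen at the initial positioning (default: centred
    in the drill canal, no rotation)."""
    p0 = initial_pose or InsertionPose()
    steps = [
        (float(s), InsertionPose(dx=p0.dx + float(s), dy=p0.dy, dphi=p0.dphi))
        for s in profile.s_values
    ]
    return InsertionPlan(
        strategy="autoAOS",
        steps=steps,
        constraints_record={
            "dy_frozen": p0.dy,
            "dphi_frozen": p0.dphi,
            "dx_coupling": "1:1",
            "dx_final": p0.dx + float(profile.s_max),
            "canal_diameter": DEFAULT_CANAL_DIAMETER,
            "canal_lines": _canal_lines(p0, DEFAULT_CANAL_DIAMETER),
        },
    )


@dataclass(frozen=True)
class ManAOSConfig:
    """Greedy rotational-compensation settings for the manual technique."""

    rate_cap_deg: float = 5.0  # per-step rotation change, avoids abrupt moves
    n_candidates: int = 21
    initial_pose: InsertionPose = InsertionPose()


def plan_manAOS(
    profile: CurlingProfile,
    contour: CochleaContour2D,
    config: ManAOSConfig | None = None,
    cost_field: StepCostField | None = None,
    outlines: dict[float, ElectrodeOutline] | None = None,
) -> InsertionPlan:
    """Manual advance-off-stylet with intuitive rotational compensation.

    Feed and lateral offset follow the automated plan; the rotation is
    chosen greedily per step to minimize that step's overlap cost, capped at
    ``rate_cap_deg`` per step.  The neutral automated orientation is always
    among the candidates (the surgeon can relax the compensation entirely),
    so every step scores at least as well as the automated technique.
    """
    cfg = config or ManAOSConfig()
    p0 = cfg.initial_pose
    field_ = cost_field or StepCostField(contour)
    outls = outlines or state_outlines(profile)
    s_values = profile.s_values

    dphi = p0.dphi
    chosen: list[float] = []
    for s in s_values:
        outline = outls[float(s)]
        pts, w, du = field_.section_points(outline)
        # candidate superset: the rate-capped window around the previous
        # compensation, plus the neutral automated orientation (relaxing the
        # compensation entirely is always possible), so every step scores at
        # least as well as the automated technique
        cands = np.unique(
            np.concatenate(
                [
                    dphi + np.linspace(-cfg.rate_cap_deg, cfg.rate_cap_deg, cfg.n_candidates),
                    [p0.dphi],
                ]
            )
        )
        dx = p0.dx + float(s)
        poses = np.column_stack(
            [np.full(len(cands), dx), np.full(len(cands), p0.dy), cands]
        )
        costs = field_.cost_of_poses(pts, w, du, poses)
        # tie-break toward the smallest compensation (closest to neutral)
        best = costs.min()
        ties = np.flatnonzero(costs <= best + 1e-12)
        k = ties[np.lexsort((np.abs(cands[ties] - dphi), np.abs(cands[ties] - p0.dphi)))[0]]
        dphi = float(cands[k])
        chosen.append(dphi)
    steps = [
        (float(s), InsertionPose(dx=p0.dx + float(s), dy=p0.dy, dphi=phi))
        for s, phi in zip(s_values, chosen)
    ]
    return InsertionPlan(
        strategy="manAOS",
        steps=steps,
        constraints_record={
            "dy_frozen": p0.dy,
            "dx_coupling": "1:1",
            "dphi_rate_cap_deg": cfg.rate_cap_deg,
            "dx_final": p0.dx + float(profile.s_max),
        },
    )


@dataclass
class TraceStep:
    s: float
    pose: InsertionPose
    report: object  # OverlapReport
    grade: TraumaGrade
    step_cost: float
    canal_violation: bool = False


@dataclass
class SimulationTrace:
    """Per-step placement, overlap report and grade for one simulated
    insertion, plus the normalized grade histogram."""

    strategy: str
    profile_label: str
    cochlea_label: str
    steps: list[TraceStep]

    @property
    def grades(self) -> list[TraumaGrade]:
        return [st.grade for st in self.steps]

    @property
    def histogram(self) -> np.ndarray:
        return grade_distribution(self.grades)

    @property
    def total_cost(self) -> float:
        return float(sum(st.step_cost for st in self.steps))

    @property
    def mean_grade(self) -> float:
        return float(np.mean([int(g) for g in self.grades]))


def _canal_check(
    outline: ElectrodeOutline, s: float, pose: InsertionPose, diameter: float
) -> bool:
    """True if the unreleased (still stylet-borne) portion leaves the canal."""
    mask = (outline.path_u >= s) & (outline.path[:, 0] > 0.0)
    if not np.any(mask):
        return False
    y = outline.path[mask, 1]
    return bool(np.any(np.abs(y - pose.dy) > diameter / 2.0))


def simulate(
    plan: InsertionPlan,
    profile: CurlingProfile,
    contour: CochleaContour2D,
    grading_config: GradingConfig | None = None,
    outlines: dict[float, ElectrodeOutline] | None = None,
) -> SimulationTrace:
    """Run one insertion: place the outline at every plan step, compute the
    overlap report and trauma-risk grade, and aggregate the histogram."""
    sv = profile.s_values
    outls = outlines if outlines is not None else {}
    steps: list[TraceStep] = []
    canal_d = plan.constraints_record.get("canal_diameter", DEFAULT_CANAL_DIAMETER)
    for s, pose in plan.steps:
        if s < sv[0] - 1e-9 or s > sv[-1] + 1e-9:
            raise InvalidPlanError(
                f"plan step s={s} outside the profile range [{sv[0]}, {sv[-1]}]"
            )
        outline = outls.get(float(s))
        if outline is None:
            outline = build_outline(profile.state_at(s))
            outls[float(s)] = outline
        placed = place_electrode(outline, pose, contour.cochleostomy_point)
        report = compute_overlap(placed, contour, grading_config)
        g = grade(report, grading_config)
        steps.append(
            TraceStep(
                s=float(s),
                pose=pose,
                report=report,
                grade=g,
                step_cost=exact_step_cost(report),
                canal_violation=(
                    _canal_check(placed, float(s), pose, canal_d)
                    if plan.strategy == "autoAOS"
                    else False
                ),
            )
        )
    return SimulationTrace(
        strategy=plan.strategy,
        profile_label=profile.label,
        cochlea_label=contour.size_class,
        steps=steps,
    )
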