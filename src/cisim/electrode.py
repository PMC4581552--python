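"""Shape model of a preformed, stylet-straightened electrode array.

The array is an inextensible planar curve of fixed total length.  Its
manufactured ("relaxed") shape is a logarithmic spiral continued by a straight
basal run; with the stylet fully inside it is held in a slightly curved
("banana") start configuration, modelled as a circular arc.  Pulling the
stylet out by ``s`` millimetres releases the distal ``s`` mm of arc, which
snaps to the manufactured shape immediately and completely, while the portion
still on the stylet keeps the start configuration.  The two pieces join with
position and tangent continuity at the release point.

Conventions: units are mm, the working plane is x-y, the tip points toward -x
in the canonical (gripper) frame, and the curve is stored tip-first, i.e.
``path_u[0] = 0`` is the tip and ``path_u[-1] = L`` the gripped base.  The
white marker (7.6 mm of arc behind the tip on the modelled array) sits at the
origin of the canonical frame in the start configuration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.optimize import least_squares

from ._spiral import LogSpiral
from .errors import FitFailureError, InvalidConfigError, InvalidInputError
from .geometry import (
    circular_arc_from_frame,
    frame_on_circular_arc,
    polyline_arclength,
    rot2d,
)

__all__ = [
    "ElectrodeConfig",
    "ManufacturedShape",
    "ShapeState",
    "CurlingProfile",
    "StraightSegment",
    "ShapeModel",
    "ElectrodeOutline",
    "ARCHETYPES",
    "synthesize_curling_profile",
    "profile_from_config",
    "fit_shape_model",
    "build_outline",
    "curling_profile_curve",
    "max_tip_deflection",
]

N_CONTACTS = 22
MARKER_ARCLEN = 7.6  # mm of arc between tip and white marker


# ---------------------------------------------------------------------------
# configuration and manufactured shape
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ElectrodeConfig:
    """Geometry of one modelled array and of its extraction experiment.

    ``spiral_tip_radius`` / ``spiral_b`` define the manufactured spiral (the
    radius at the tip and the growth rate), ``spiral_span`` how much of the
    path, measured from the tip, is spiral before the straight basal run.
    ``start_sagitta`` is the bow height of the banana-shaped start
    configuration over the full length.  ``s_max`` is the largest stylet
    extraction recorded in the profile; extraction is sampled every
    ``step`` mm (the digitization protocol used 0.1-0.25 mm increments).
    """

    total_length: float = 24.0
    insertable_length: float = 15.6
    marker_arclen: float = MARKER_ARCLEN
    spiral_tip_radius: float = 2.4
    spiral_b: float = 0.10
    spiral_span: float = 14.5
    start_sagitta: float = 1.8
    s_max: float = 15.3
    step: float = 0.15
    contact_span: tuple[float, float] = (0.7, 14.3)
    path_du: float = 0.04
    label: str = "RE"

    @property
    def start_curvature(self) -> float:
        # circular-arc bow: sagitta h over length L gives kappa ~ 8 h / L^2
        return 8.0 * self.start_sagitta / self.total_length**2

    @property
    def full_insertion_feed(self) -> float:
        """Feed (mm) at which the basal marker ribs reach the cochleostomy:
        the clinical full insertion depth, measured from the advance-off-
        stylet datum (white marker at the cochleostomy)."""
        return self.insertable_length - self.marker_arclen

    @property
    def contact_arclens(self) -> np.ndarray:
        """Arc positions (from tip) of contacts c01 (basal) .. c22 (apical)."""
        lo, hi = self.contact_span
        return np.linspace(hi, lo, N_CONTACTS)

    def validate(self) -> None:
        if self.s_max > self.total_length:
            raise InvalidConfigError(
                f"s_max={self.s_max} exceeds total path length {self.total_length}"
            )
        if not 0.0 < self.step:
            raise InvalidConfigError("step must be positive")
        if self.spiral_span > self.total_length:
            raise InvalidConfigError("spiral_span exceeds total length")


class ManufacturedShape:
    """Closed-form relaxed shape: log spiral at the tip, straight basal run.

    Parameterized by arc length ``u`` from the tip.  The spiral is evaluated
    in its own canonical frame; callers rigidly move the returned points.
    The spiral sense is chosen so that, walking from base to tip, the curve
    turns left (positive signed curvature), matching the cochlea convention.
    """

    def __init__(self, tip_radius: float, b: float, span: float, total_length: float):
        self.spiral = LogSpiral(a=tip_radius, b=b, sense=-1)
        self.span = float(span)
        self.total_length = float(total_length)
        # frame at the basal end of the spiral portion, for the straight run
        th = self.spiral.theta_at_arclength(self.span)
        self._th_span = float(th)
        self._span_point = self.spiral.point(th)
        # tangent for travel tip->base is direction of increasing theta
        self._base_dir = self.spiral.tangent(th, direction=1)

    def theta_at(self, u):
        return self.spiral.theta_at_arclength(np.minimum(u, self.span))

    def point(self, u):
        u = np.asarray(u, dtype=float)
        th = self.spiral.theta_at_arclength(np.clip(u, 0.0, self.span))
        pts = self.spiral.point(th)
        over = u > self.span
        if np.any(over):
            pts = np.where(
                over[..., None],
                self._span_point + (u[..., None] - self.span) * self._base_dir,
                pts,
            )
        return pts

    def heading(self, u: float) -> float:
        """Tangent angle at ``u`` for travel toward the tip (decreasing u)."""
        if u > self.span:
            t = -self._base_dir
        else:
            th = float(self.spiral.theta_at_arclength(u))
            t = self.spiral.tangent(th, direction=-1)
        return float(np.arctan2(t[1], t[0]))

    def curvature(self, u):
        u = np.asarray(u, dtype=float)
        th = self.spiral.theta_at_arclength(np.clip(u, 0.0, self.span))
        k = self.spiral.curvature(th)
        return np.where(u > self.span, 0.0, k)


# ---------------------------------------------------------------------------
# shape states and curling profiles
# ---------------------------------------------------------------------------

@dataclass
class ShapeState:
    """Central-path shape at one stylet extraction ``s``."""

    stylet_extraction_s: float
    central_path: np.ndarray  # (N, 2), tip first
    path_u: np.ndarray  # (N,), arc length from tip at each vertex
    contact_positions: np.ndarray  # (22, 2), c01 (basal) .. c22 (apical)
    contact_arclens: np.ndarray  # (22,)
    tip_point: np.ndarray  # (2,)
    marker_arclen: float = MARKER_ARCLEN
    meta: dict = field(default_factory=dict)

    @property
    def total_arclength(self) -> float:
        return float(polyline_arclength(self.central_path)[-1])

    def point_at(self, u):
        """Interpolated path point(s) at arc position(s) ``u`` from the tip."""
        u = np.asarray(u, dtype=float)
        x = np.interp(u, self.path_u, self.central_path[:, 0])
        y = np.interp(u, self.path_u, self.central_path[:, 1])
        return np.stack([x, y], axis=-1)


@dataclass
class CurlingProfile:
    """Ordered shape states over stylet extraction; the array's kinematic
    fingerprint.  ``tip_trajectory`` projected to the x-y plane is the
    sigmoidal curling profile used to compare arrays."""

    states: list[ShapeState]
    s_max: float
    label: str
    config: ElectrodeConfig
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        s = self.s_values
        if len(s) and not np.all(np.diff(s) > 0):
            raise InvalidInputError("extraction values must be strictly increasing")

    @property
    def s_values(self) -> np.ndarray:
        return np.array([st.stylet_extraction_s for st in self.states])

    @property
    def tip_trajectory(self) -> np.ndarray:
        return np.array([st.tip_point for st in self.states])

    def state_at(self, s: float, tol: float = 1e-9) -> ShapeState:
        """State at extraction ``s``; linear per-vertex interpolation between
        the two bracketing stored states (step sizes <= 0.25 mm make this
        sub-resolution)."""
        sv = self.s_values
        if s < sv[0] - tol or s > sv[-1] + tol:
            raise InvalidInputError(
                f"extraction s={s} outside profile range [{sv[0]}, {sv[-1]}]"
            )
        i = int(np.searchsorted(sv, s))
        if i < len(sv) and abs(sv[i] - s) <= tol:
            return self.states[i]
        if i > 0 and abs(sv[i - 1] - s) <= tol:
            return self.states[i - 1]
        lo, hi = self.states[i - 1], self.states[i]
        w = (s - sv[i - 1]) / (sv[i] - sv[i - 1])
        # resample both onto a common arc-length grid before blending
        u = np.union1d(lo.path_u, hi.path_u)
        p = (1 - w) * lo.point_at(u) + w * hi.point_at(u)
        contacts = (1 - w) * lo.contact_positions + w * hi.contact_positions
        tip = (1 - w) * lo.tip_point + w * hi.tip_point
        return ShapeState(
            stylet_extraction_s=float(s),
            central_path=p,
            path_u=u,
            contact_positions=contacts,
            contact_arclens=lo.contact_arclens.copy(),
            tip_point=tip,
            marker_arclen=lo.marker_arclen,
            meta={"interpolated": True},
        )


# archetype presets spanning the observed range of curling behaviour:
# (start-configuration sagitta mm, manufactured tip radius mm)
ARCHETYPES = {
    "pronounced": {"start_sagitta": 3.0, "spiral_tip_radius": 2.20},
    "moderate": {"start_sagitta": 1.8, "spiral_tip_radius": 2.40},
    "flat": {"start_sagitta": 0.6, "spiral_tip_radius": 2.60},
}


def _base_frame(cfg: ElectrodeConfig) -> tuple[np.ndarray, float]:
    """Gripper-frame pose of the base vertex, fixed across all states.

    Chosen so that in the start configuration the white marker sits at the
    origin and the chord from marker to tip runs along -x; the banana bow
    then bulges toward +y, the same side as the canonical lumen's basal
    bulge (both curves turn left).
    """
    v_marker = cfg.total_length - cfg.marker_arclen  # arc from base to marker
    kappa0 = cfg.start_curvature
    # chord direction marker -> tip in a marker-tangent-aligned frame
    tip = circular_arc_from_frame((0.0, 0.0), np.pi, kappa0, np.array([cfg.marker_arclen]))[0]
    delta = np.pi - np.arctan2(tip[1], tip[0])  # rotate chord onto -x
    base_pt, base_psi = frame_on_circular_arc((0.0, 0.0), np.pi, kappa0, -v_marker)
    return rot2d(delta) @ base_pt, base_psi + delta


def _state_at(cfg: ElectrodeConfig, shape: ManufacturedShape, s: float) -> ShapeState:
    L = cfg.total_length
    kappa0 = cfg.start_curvature
    base_pt, base_psi = _base_frame(cfg)

    # vertex grid in u (arc from tip), with an exact vertex at the release point
    n = max(int(round(L / cfg.path_du)) + 1, 100)
    u = np.linspace(0.0, L, n)
    if 0.0 < s < L:
        u = np.union1d(u, [s])

    # junction frame on the unreleased arc at u = s (v = L - s)
    junc_pt, junc_psi = frame_on_circular_arc(base_pt, base_psi, kappa0, L - s)
    # rigid motion taking the manufactured shape's frame at u=s onto the junction
    m_pt = shape.point(np.array([s]))[0]
    m_psi = shape.heading(s)
    ang = junc_psi - m_psi
    R = rot2d(ang)

    def released_points(uq: np.ndarray) -> np.ndarray:
        return (shape.point(uq) - m_pt) @ R.T + junc_pt

    def path_points(uq: np.ndarray) -> np.ndarray:
        uq = np.asarray(uq, dtype=float)
        pts = np.empty((len(uq), 2))
        rel = uq <= s + 1e-12
        if np.any(~rel):
            pts[~rel] = circular_arc_from_frame(base_pt, base_psi, kappa0, L - uq[~rel])
        if np.any(rel):
            pts[rel] = released_points(uq[rel])
        return pts

    path = path_points(u)
    contacts = path_points(cfg.contact_arclens)
    tip = path_points(np.array([0.0]))[0]
    return ShapeState(
        stylet_extraction_s=float(s),
        central_path=path,
        path_u=u,
        contact_positions=contacts,
        contact_arclens=cfg.contact_arclens,
        tip_point=tip,
        marker_arclen=cfg.marker_arclen,
        meta={"release_rotation": float(ang), "release_junction": junc_pt.copy()},
    )


def synthesize_curling_profile(
    archetype: str,
    variability_seed: int | None = None,
    config: ElectrodeConfig | None = None,
) -> CurlingProfile:
    """Generate a full curling profile for one archetype.

    ``variability_seed`` perturbs the start sagitta (+-5 %) and the
    manufactured tip radius (+-2 %), emulating unit-to-unit variability
    between physically distinct arrays of the same qualitative class.
    """
    if archetype not in ARCHETYPES:
        raise InvalidInputError(
            f"unknown archetype {archetype!r}; expected one of {sorted(ARCHETYPES)}"
        )
    cfg = config or ElectrodeConfig()
    updates = dict(ARCHETYPES[archetype])
    if config is None or (
        config.start_sagitta == ElectrodeConfig.start_sagitta
        and config.spiral_tip_radius == ElectrodeConfig.spiral_tip_radius
    ):
        cfg = dataclasses.replace(cfg, **updates)
    if variability_seed is not None:
        rng = np.random.default_rng(variability_seed)
        cfg = dataclasses.replace(
            cfg,
            start_sagitta=cfg.start_sagitta * (1 + 0.05 * (2 * rng.random() - 1)),
            spiral_tip_radius=cfg.spiral_tip_radius * (1 + 0.02 * (2 * rng.random() - 1)),
        )
    cfg.validate()
    label = cfg.label if cfg.label != "RE" else f"RE-{archetype}"
    return profile_from_config(
        cfg, label=label, meta={"archetype": archetype, "variability_seed": variability_seed}
    )


def profile_from_config(
    cfg: ElectrodeConfig, label: str | None = None, meta: dict | None = None
) -> CurlingProfile:
    """Deterministically build the full state series from a (possibly
    individually perturbed) electrode configuration."""
    cfg.validate()
    shape = ManufacturedShape(
        cfg.spiral_tip_radius, cfg.spiral_b, cfg.spiral_span, cfg.total_length
    )
    n_steps = int(round(cfg.s_max / cfg.step))
    s_values = np.linspace(0.0, cfg.s_max, n_steps + 1)
    states = [_state_at(cfg, shape, s) for s in s_values]
    return CurlingProfile(
        states=states,
        s_max=cfg.s_max,
        label=label or cfg.label,
        config=cfg,
        meta=meta or {},
    )


def released_spiral_in_state_frame(state: ShapeState, profile: CurlingProfile) -> LogSpiral:
    """The manufactured spiral, rigidly moved into the frame of ``state``.

    Closed-form reference curve on which all released contacts must lie.
    """
    cfg = profile.config
    base = LogSpiral(a=cfg.spiral_tip_radius, b=cfg.spiral_b, sense=-1)
    ang = state.meta["release_rotation"]
    shape = ManufacturedShape(
        cfg.spiral_tip_radius, cfg.spiral_b, cfg.spiral_span, cfg.total_length
    )
    s = state.stylet_extraction_s
    m_pt = shape.point(np.array([s]))[0]
    R = rot2d(ang)
    center = (np.asarray(base.center) - m_pt) @ R.T + state.meta["release_junction"]
    return LogSpiral(a=base.a, b=base.b, center=tuple(center), phi=base.phi + ang, sense=-1)


def curling_profile_curve(profile: CurlingProfile) -> np.ndarray:
    """Tip-point positions over extraction, projected to the x-y working plane."""
    if len(profile.states) < 3:
        raise InvalidInputError("curling profile needs at least 3 states")
    return profile.tip_trajectory.copy()


def max_tip_deflection(profile: CurlingProfile) -> float:
    """Largest tip deflection caused by the imperfect (banana-shaped) start
    configuration.

    The reference is the same array with an ideally straight start
    configuration (zero start curvature, identical manufactured shape); the
    deflection at extraction ``s`` is the distance between the two tip
    positions, and the profile's characteristic deflection is the maximum
    over ``s``.  At ``s = 0`` this is exactly the bow of the start
    configuration, the quantity used to rank curling behaviour.
    """
    cfg = dataclasses.replace(profile.config, start_sagitta=0.0)
    shape = ManufacturedShape(
        cfg.spiral_tip_radius, cfg.spiral_b, cfg.spiral_span, cfg.total_length
    )
    ref = np.array(
        [_state_at(cfg, shape, st.stylet_extraction_s).tip_point for st in profile.states]
    )
    return float(np.max(np.linalg.norm(profile.tip_trajectory - ref, axis=1)))


# ---------------------------------------------------------------------------
# areal outline
# ---------------------------------------------------------------------------

INNER_OFFSET = 0.15  # mm, constant
OUTER_OFFSET_BASE = 0.65  # mm at the gripped base
OUTER_OFFSET_TIP = 0.45  # mm at the tip
TIP_CAP_LENGTH = 0.3  # mm, conical cap beyond the central-path tip
SOFTIP_LENGTH = 0.5  # mm of path counted as the flexible tip region


@dataclass
class ElectrodeOutline:
    """Closed areal outline of one shape state (mm)."""

    ring: np.ndarray  # (M, 2) closed outline vertices (first != last)
    tip_ring: np.ndarray  # sub-polygon around the conical tip cap
    path: np.ndarray  # (K, 2) resampled central path, tip first
    path_u: np.ndarray  # (K,)
    normals: np.ndarray  # (K, 2) unit normals pointing to the inner side
    widths: np.ndarray  # (K,) local total width
    total_length: float
    inner_offset: float = INNER_OFFSET  # central path -> inner contour (mm)
    trimmed: bool = False  # loops removed because curvature beat the offset

    def local_width(self, u):
        u = np.asarray(u, dtype=float)
        return INNER_OFFSET + OUTER_OFFSET_TIP + (
            OUTER_OFFSET_BASE - OUTER_OFFSET_TIP
        ) * u / self.total_length

    @property
    def polygon(self):
        from shapely.geometry import Polygon

        return Polygon(self.ring)

    @property
    def tip_region(self):
        from shapely.geometry import Polygon

        return Polygon(self.tip_ring)


def _walk_tangents(path: np.ndarray) -> np.ndarray:
    """Unit tangents for walking base->tip on a tip-first path."""
    t = -np.gradient(path, axis=0)
    t /= np.linalg.norm(t, axis=1, keepdims=True)
    return t


def build_outline(state: ShapeState, du: float = 0.1) -> ElectrodeOutline:
    """Areal outline: inner contour at a constant 0.15 mm from the central
    path, outer contour tapering 0.65 -> 0.45 mm toward the tip, the tip
    closed by two straight lines into a conical cap."""
    from shapely.geometry import Polygon
    from shapely.validation import make_valid

    L = float(state.path_u[-1])
    k = max(int(round(L / du)) + 1, 25)
    u = np.linspace(0.0, L, k)
    path = state.point_at(u)
    t_walk = _walk_tangents(path)
    # the curl centre lies to the left of base->tip travel; that is the
    # inner (modiolus-facing) side
    n_inner = np.stack([-t_walk[:, 1], t_walk[:, 0]], axis=-1)

    w_out = OUTER_OFFSET_TIP + (OUTER_OFFSET_BASE - OUTER_OFFSET_TIP) * u / L
    inner = path + INNER_OFFSET * n_inner
    outer = path - w_out[:, None] * n_inner

    apex = path[0] + TIP_CAP_LENGTH * t_walk[0]
    # ring: apex -> inner (tip to base) -> base edge -> outer (base to tip) -> apex
    ring = np.vstack([apex, inner, outer[::-1]])
    poly = Polygon(ring)
    trimmed = False
    if not poly.is_valid:
        trimmed = True
        fixed = make_valid(poly)
        polys = (
            [g for g in fixed.geoms if g.geom_type == "Polygon"]
            if hasattr(fixed, "geoms")
            else [fixed]
        )
        poly = max(polys, key=lambda g: g.area)
        ring = np.asarray(poly.exterior.coords)[:-1]

    m = u <= SOFTIP_LENGTH
    tip_ring = np.vstack([apex, inner[m], outer[m][::-1]])

    widths = INNER_OFFSET + w_out
    return ElectrodeOutline(
        ring=ring,
        tip_ring=tip_ring,
        path=path,
        path_u=u,
        normals=n_inner,
        widths=widths,
        total_length=L,
        trimmed=trimmed,
    )


# ---------------------------------------------------------------------------
# fitting a shape model to digitized landmark points
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StraightSegment:
    start: np.ndarray  # (2,)
    direction: np.ndarray  # (2,) unit vector
    length: float

    @property
    def end(self) -> np.ndarray:
        return self.start + self.length * self.direction


@dataclass
class ShapeModel:
    """Fitted central-path model: a logarithmic spiral and up to three
    straight segments joined with positional continuity."""

    spiral: LogSpiral | None
    spiral_theta_range: tuple[float, float] | None
    straight_segments: list[StraightSegment]
    join_points: list[float]  # arc positions (from the basal end) of the joins
    rms: float
    n_points: int

    @property
    def spiral_a(self) -> float | None:
        return None if self.spiral is None else self.spiral.a

    @property
    def spiral_b(self) -> float | None:
        return None if self.spiral is None else self.spiral.b

    def central_polyline(self, n_per_piece: int = 200) -> np.ndarray:
        """Dense polyline from base to tip for plotting/round-trip checks."""
        pieces = []
        for seg in self.straight_segments:
            tt = np.linspace(0, seg.length, max(2, n_per_piece // 4))
            pieces.append(seg.start + tt[:, None] * seg.direction)
        if self.spiral is not None:
            t0, t1 = self.spiral_theta_range
            th = np.linspace(t0, t1, n_per_piece)
            pieces.append(self.spiral.point(th))
        return np.vstack(pieces)


def _fit_log_spiral(points: np.ndarray):
    """ODR fit of a logarithmic spiral; returns (spiral, theta, rms) or None."""
    p = np.asarray(points, dtype=float)
    n = len(p)
    # initial circle fit (Kasa) for the centre
    A = np.column_stack([2 * p[:, 0], 2 * p[:, 1], np.ones(n)])
    bvec = (p**2).sum(axis=1)
    try:
        sol, *_ = np.linalg.lstsq(A, bvec, rcond=None)
    except np.linalg.LinAlgError:
        return None
    cx, cy = sol[0], sol[1]
    rel = p - [cx, cy]
    r = np.linalg.norm(rel, axis=1)
    if np.any(r < 1e-12):
        return None
    th = np.unwrap(np.arctan2(rel[:, 1], rel[:, 0]))
    # linear init: ln r = ln a + b * theta
    M = np.column_stack([np.ones(n), th])
    coef, *_ = np.linalg.lstsq(M, np.log(r), rcond=None)
    ln_a0, b0 = coef
    if abs(b0) < 1e-8:
        b0 = np.sign(b0) * 1e-8 if b0 != 0 else 1e-8

    def residuals(x):
        cx, cy, ln_a, b = x[:4]
        theta = x[4:]
        rr = np.exp(ln_a + b * theta)
        mx = cx + rr * np.cos(theta)
        my = cy + rr * np.sin(theta)
        return np.concatenate([mx - p[:, 0], my - p[:, 1]])

    x0 = np.concatenate([[cx, cy, ln_a0, b0], th])
    try:
        res = least_squares(residuals, x0, method="lm", max_nfev=4000)
    except Exception:
        return None
    if not np.all(np.isfinite(res.x)):
        return None
    cx, cy, ln_a, b = res.x[:4]
    theta = res.x[4:]
    rms = float(np.sqrt(np.mean(res.fun.reshape(2, -1).T.__pow__(2).sum(axis=1))))
    spiral = LogSpiral(a=float(np.exp(ln_a)), b=float(b), center=(float(cx), float(cy)))
    return spiral, theta, rms


def _chain_segments(points: np.ndarray, start: np.ndarray | None, n_seg: int):
    """Fit ``n_seg`` connected straight segments through ordered ``points``.

    ``points`` are ordered from the piece nearest the previous model part
    outward; ``start`` anchors the first segment (None = free PCA line).
    Splits are chosen by brute force over contiguous runs (>=2 points each).
    Returns (segments ordered base->tip, residuals) or None if impossible.
    """
    n = len(points)
    if n < 2 * n_seg:
        return None
    best = None
    # interior split positions between runs
    for splits in combinations(range(2, n - 1), n_seg - 1):
        if any(b - a < 2 for a, b in zip((0,) + splits, splits + (n,))):
            continue
        bounds = (0,) + splits + (n,)
        segs: list[StraightSegment] = []
        resid: list[np.ndarray] = []
        anchor = start
        ok = True
        for a, b in zip(bounds[:-1], bounds[1:]):
            run = points[a:b]
            if anchor is None:
                # free line through the run (PCA)
                c = run.mean(axis=0)
                d = np.linalg.svd(run - c)[2][0]
                proj = (run - c) @ d
                if proj[0] > proj[-1]:
                    d, proj = -d, -proj
                seg_start = c + proj.min() * d
                length = float(proj.max() - proj.min())
                perp = (run - c) - np.outer(proj, d)
            else:
                rel = run - anchor
                # direction of the ray from the anchor minimizing orthogonal
                # distances: principal eigenvector of rel^T rel
                _, _, vt = np.linalg.svd(rel, full_matrices=False)
                d = vt[0]
                proj = rel @ d
                if proj.sum() < 0:
                    d, proj = -d, -proj
                if np.any(proj < -1e-9):
                    ok = False
                    break
                seg_start = anchor.copy()
                length = float(proj.max())
                perp = rel - np.outer(proj, d)
            segs.append(StraightSegment(start=seg_start, direction=d, length=length))
            resid.append(np.linalg.norm(perp, axis=1))
            anchor = segs[-1].end
        if not ok:
            continue
        rr = np.concatenate(resid)
        score = float(np.sqrt(np.mean(rr**2)))
        if best is None or score < best[2]:
            best = (segs, rr, score)
    if best is None:
        return None
    return best[0], best[1]


def fit_shape_model(points, config: dict | None = None) -> ShapeModel:
    """Fit a logarithmic spiral plus up to three straight segments through
    digitized landmark points ordered base -> tip.

    The segment count is selected by parsimony: counts are increased from 0
    and the smallest count whose RMS improves by less than 10 % over the next
    count is accepted.
    """
    p = np.asarray(points, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2:
        raise InvalidInputError("points must be an (N, 2) array")
    if len(p) < 5:
        raise InvalidInputError(f"need at least 5 points, got {len(p)}")
    cfg = {"max_segments": 3, "improvement": 0.10, "collinear_tol": 1e-9}
    if config:
        cfg.update(config)
    scale = float(np.ptp(p, axis=0).max())

    # degenerate collinear input: pure straight-segment representation
    line = _chain_segments(p[::-1], start=None, n_seg=1)
    if line is not None:
        segs, rr = line
        line_rms = float(np.sqrt(np.mean(rr**2)))
        if line_rms < cfg["collinear_tol"] * max(scale, 1.0):
            segs_b2t = [
                StraightSegment(s.end, -s.direction, s.length) for s in reversed(segs)
            ]
            return ShapeModel(
                spiral=None,
                spiral_theta_range=None,
                straight_segments=segs_b2t,
                join_points=[],
                rms=line_rms,
                n_points=len(p),
            )

    def candidate(n_seg: int):
        """Best spiral + n_seg-segment model; returns (rms, builder) or None."""
        best = None
        min_spiral_pts = 5
        # j = index of the first (most basal) point on the spiral
        j_range = [0] if n_seg == 0 else range(2 * n_seg, len(p) - min_spiral_pts + 1)
        for j in j_range:
            fit = _spiral_cache.get(j)
            if fit is None and j not in _spiral_cache:
                fit = _fit_log_spiral(p[j:])
                _spiral_cache[j] = fit
            if fit is None:
                continue
            spiral, theta, _ = fit
            resid_sp = np.linalg.norm(spiral.point(theta) - p[j:], axis=1)
            if n_seg == 0:
                rr = resid_sp
                segs_b2t: list[StraightSegment] = []
            else:
                basal_end = spiral.point(theta[0])
                chain = _chain_segments(p[:j][::-1], start=basal_end, n_seg=n_seg)
                if chain is None:
                    continue
                segs, rr_seg = chain
                segs_b2t = [
                    StraightSegment(s.end, -s.direction, s.length)
                    for s in reversed(segs)
                ]
                rr = np.concatenate([rr_seg, resid_sp])
            rms = float(np.sqrt(np.mean(rr**2)))
            if best is None or rms < best[0]:
                best = (rms, spiral, theta, segs_b2t)
        return best

    _spiral_cache: dict[int, object] = {}
    cands = {}
    for k in range(cfg["max_segments"] + 1):
        cands[k] = candidate(k)

    usable = {k: c for k, c in cands.items() if c is not None}
    if not usable:
        best_line = line[1] if line is not None else None
        raise FitFailureError(
            "spiral fit did not converge for any segment count",
            best_rms=float(np.sqrt(np.mean(best_line**2))) if best_line is not None else None,
        )

    chosen = max(usable)
    ks = sorted(usable)
    for idx, k in enumerate(ks):
        rms_k = usable[k][0]
        if rms_k <= cfg["collinear_tol"] * max(scale, 1.0):
            chosen = k
            break
        nxt = ks[idx + 1] if idx + 1 < len(ks) else None
        if nxt is None:
            chosen = k
            break
        rms_n = usable[nxt][0]
        if (rms_k - rms_n) < cfg["improvement"] * rms_k:
            chosen = k
            break

    rms, spiral, theta, segs = usable[chosen]
    th0, th1 = float(theta[0]), float(theta[-1])
    joins = []
    acc = 0.0
    for seg in segs:
        acc += seg.length
        joins.append(acc)
    return ShapeModel(
        spiral=spiral,
        spiral_theta_range=(th0, th1),
        straight_segments=segs,
        join_points=joins,
        rms=rms,
        n_points=len(p),
    )
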