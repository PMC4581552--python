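"""2D cochlear lumen contours and the Escudé size metric.

The cochlea is represented by two open polylines — the inner (modiolar) and
outer (lateral) walls of the spiral lumen — in a canonical working frame:
cochleostomy at the origin, insertion direction along -x, the lumen curling
toward -y.  Contours come either from a triangulated inner-ear surface mesh
(rotating cutting-plane sampling followed by an orthogonal-distance
regression plane projection) or from the parametric generator
:func:`synthesize_cochlea`, which builds the walls as two offset logarithmic
spirals calibrated to a target Escudé distance A.

Size metric: distance "A" is the greatest lateral dimension of the basal
turn, measured from the round-window end of the outer wall to the opposing
lateral wall.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

from ._spiral import LogSpiral
from .errors import (
    DegeneratePlaneError,
    InsufficientCoverageError,
    InvalidConfigError,
    InvalidInputError,
    InvalidMeshError,
)
from .geometry import polyline_arclength, resample_polyline, rot2d

__all__ = [
    "ModiolarAxis",
    "CrossSectionSample",
    "CochleaContour2D",
    "SIZE_PRESETS",
    "sample_cross_sections",
    "project_to_plane",
    "measure_distance_A",
    "measure_distance_B",
    "synthesize_cochlea",
]

# Escudé distance-A presets (mm) for the small / medium / large synthetic
# cochleae.  Configuration defaults chosen inside the reported human range.
SIZE_PRESETS = {"CS": 8.5, "CM": 9.0, "CL": 9.5}
A_PLAUSIBLE_RANGE = (7.5, 10.5)

CORRIDOR_LENGTH = 30.0  # mm of straight entry channel outside the cochleostomy
WALL_THICKNESS = 2.5  # mm of bone modelled around the lumen for overlap scoring
MAX_ELECTRODE_WIDTH = 0.8  # basal width of the modelled array (mm)
AOS_CHORD_ARC = 7.6  # arc depth used to orient the canonical frame (marker depth)


@dataclass(frozen=True)
class ModiolarAxis:
    """Rotation axis through the modiolus used for cross-section sampling."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if abs(n - 1.0) > 1e-12:
            d = d / n
        object.__setattr__(self, "direction", d)


@dataclass(frozen=True)
class CrossSectionSample:
    """Inner/outer lumen points picked on one rotated cutting half-plane."""

    plane_angle: float  # degrees about the modiolar axis (virtual, unbounded)
    inner_point: np.ndarray  # 3D mm
    outer_point: np.ndarray  # 3D mm


@dataclass
class CochleaContour2D:
    """Inner and outer lumen walls in the canonical 2D working frame."""

    inner_contour: np.ndarray  # (N, 2), basal end first
    outer_contour: np.ndarray  # (M, 2), basal end first
    cochleostomy_point: np.ndarray  # (2,)
    entry_direction: np.ndarray  # (2,) unit
    distance_A: float | None = None
    size_class: str = "custom"
    narrow_lumen_warning: bool = False
    meta: dict = field(default_factory=dict)

    # -- derived geometry (built lazily, shapely-backed) ------------------
    @cached_property
    def centerline(self) -> np.ndarray:
        n = max(len(self.inner_contour), len(self.outer_contour))
        inner = resample_polyline(self.inner_contour, n=n)
        outer = resample_polyline(self.outer_contour, n=n)
        return 0.5 * (inner + outer)

    @cached_property
    def lumen_width(self) -> np.ndarray:
        n = max(len(self.inner_contour), len(self.outer_contour))
        inner = resample_polyline(self.inner_contour, n=n)
        outer = resample_polyline(self.outer_contour, n=n)
        return np.linalg.norm(outer - inner, axis=1)

    @cached_property
    def lumen_polygon(self):
        from shapely.geometry import Polygon

        ring = np.vstack([self.outer_contour, self.inner_contour[::-1]])
        poly = Polygon(ring)
        if not poly.is_valid:
            from shapely.validation import make_valid

            poly = make_valid(poly)
            if hasattr(poly, "geoms"):
                poly = max(
                    (g for g in poly.geoms if g.geom_type == "Polygon"),
                    key=lambda g: g.area,
                )
        return poly

    @cached_property
    def mouth_width(self) -> float:
        return float(np.linalg.norm(self.outer_contour[0] - self.inner_contour[0]))

    @cached_property
    def free_space(self):
        """Open surgical access outside the cochleostomy (posterior to the
        entry plane); nothing there is scored as cochlear contact."""
        from shapely.geometry import Polygon

        L = CORRIDOR_LENGTH
        return Polygon([(0.0, -L), (L, -L), (L, L), (0.0, L)])

    @cached_property
    def mouth_region(self):
        """Immediate neighbourhood of the cochleostomy opening: the drilled
        passage between the basal ends of the two walls (no bone there)."""
        from shapely.geometry import LineString

        mouth = LineString([self.inner_contour[0], self.outer_contour[0]])
        return mouth.buffer(0.35, quad_segs=8)

    @cached_property
    def open_region(self):
        """Lumen, cochleostomy passage, and the open access space outside
        the entry plane."""
        return self.lumen_polygon.union(self.free_space).union(self.mouth_region)

    @cached_property
    def forbidden_region(self):
        """Bony shell around the lumen; electrode overlap with this region
        is what the trauma grading scores.  The half-space beyond the entry
        plane and the drilled cochleostomy passage are open and never
        forbidden."""
        shell = self.lumen_polygon.buffer(WALL_THICKNESS, quad_segs=8)
        return (
            shell.difference(self.lumen_polygon)
            .difference(self.free_space)
            .difference(self.mouth_region)
        )

    @cached_property
    def inner_line(self):
        from shapely.geometry import LineString

        return LineString(self.inner_contour)

    @cached_property
    def outer_line(self):
        from shapely.geometry import LineString

        return LineString(self.outer_contour)

    def scaled(self, factor: float) -> "CochleaContour2D":
        """Uniformly scaled copy (about the cochleostomy point)."""
        c = self.cochleostomy_point
        return CochleaContour2D(
            inner_contour=(self.inner_contour - c) * factor + c,
            outer_contour=(self.outer_contour - c) * factor + c,
            cochleostomy_point=c.copy(),
            entry_direction=self.entry_direction.copy(),
            distance_A=None if self.distance_A is None else self.distance_A * factor,
            size_class=self.size_class,
            narrow_lumen_warning=self.narrow_lumen_warning,
            meta=dict(self.meta),
        )


# ---------------------------------------------------------------------------
# mesh -> cross sections -> plane projection
# ---------------------------------------------------------------------------

def _axis_frame(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = direction / np.linalg.norm(direction)
    helper = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(d, helper)) > 0.9:
        helper = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(d, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    return e1, e2


def _segment_loops(segments: np.ndarray, tol: float = 1e-6) -> list[np.ndarray]:
    """Group an unordered segment soup into connected components of vertices."""
    key = lambda p: tuple(np.round(p / tol).astype(np.int64))
    parent: dict = {}

    def find(k):
        while parent[k] != k:
            parent[k] = parent[parent[k]]
            k = parent[k]
        return k

    pts: dict = {}
    for seg in segments:
        ka, kb = key(seg[0]), key(seg[1])
        for k, p in ((ka, seg[0]), (kb, seg[1])):
            if k not in parent:
                parent[k] = k
                pts[k] = p
        ra, rb = find(ka), find(kb)
        if ra != rb:
            parent[ra] = rb
    groups: dict = {}
    for k in parent:
        groups.setdefault(find(k), []).append(pts[k])
    return [np.asarray(v) for v in groups.values() if len(v) >= 3]


def sample_cross_sections(
    mesh,
    axis: ModiolarAxis,
    step_deg: float = 5.0,
    start_plane: float = 0.0,
) -> list[CrossSectionSample]:
    """Slice a lumen surface mesh with a half-plane rotated about the
    modiolar axis and pick, per cut, the radially innermost and outermost
    intersection points.

    Where the half-plane cuts several turns of the helical lumen, the loops
    are assigned to successive virtual angles ``angle + 360 k`` ordered from
    the basal-most (largest radius) loop outward, so the samples cover the
    whole segmented turn range.
    """
    import trimesh.intersections as ti

    e1, e2 = _axis_frame(axis.direction)
    d = axis.direction
    angles = np.arange(0.0, 360.0, step_deg)
    out: list[CrossSectionSample] = []
    any_hit = False
    for alpha in angles:
        a = np.deg2rad(alpha)
        ref = np.cos(a) * e1 + np.sin(a) * e2
        normal = np.cross(d, ref)
        segs = ti.mesh_plane(mesh, plane_normal=normal, plane_origin=axis.point)
        if len(segs) == 0:
            warnings.warn(f"empty mesh intersection at plane angle {alpha} deg")
            continue
        mids = segs.mean(axis=1)
        side = (mids - axis.point) @ ref > 0
        segs = segs[side]
        if len(segs) == 0:
            warnings.warn(f"no intersection on the half-plane at {alpha} deg")
            continue
        any_hit = True
        loops = _segment_loops(segs)
        rho_of = lambda P: (P - axis.point) @ ref
        loops.sort(key=lambda P: -float(np.mean(rho_of(P))))
        for k, P in enumerate(loops):
            rho = rho_of(P)
            out.append(
                CrossSectionSample(
                    plane_angle=start_plane + alpha + 360.0 * k,
                    inner_point=P[int(np.argmin(rho))].copy(),
                    outer_point=P[int(np.argmax(rho))].copy(),
                )
            )
    if not any_hit:
        raise InvalidMeshError("cutting plane never intersects the mesh")
    out.sort(key=lambda s: s.plane_angle)
    return out


def fit_odr_plane(points: np.ndarray):
    """Orthogonal-distance regression plane: (centroid, e1, e2, normal)."""
    p = np.asarray(points, dtype=float)
    c = p.mean(axis=0)
    u, sv, vt = np.linalg.svd(p - c, full_matrices=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise DegeneratePlaneError("points are collinear; plane is not unique")
    return c, vt[0], vt[1], vt[2]


def canonicalize_contours(
    inner: np.ndarray, outer: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Rigidly move 2D contours into the canonical working frame.

    Cochleostomy (basal centerline end) at the origin; the entry axis — the
    best-fit line through the origin over the basal 7.6 mm of the lumen
    centerline (the linear advance phase of the insertion technique) —
    along -x; and the lumen turning left when walked base to apex (reflect
    if needed), so that electrode and lumen share one curl handedness.
    """
    n = max(len(inner), len(outer))
    # resampled copies are used only to define the frame; the transform is
    # applied to the original vertices (canonicalization is idempotent)
    mid = 0.5 * (resample_polyline(inner, n=n) + resample_polyline(outer, n=n))
    start = mid[0]
    mid = mid - start
    u = polyline_arclength(mid)
    depth = min(AOS_CHORD_ARC, 0.5 * u[-1])
    basal = resample_polyline(mid, s=np.linspace(0.0, depth, 40))
    # principal direction of the basal run through the origin
    _, _, vt = np.linalg.svd(basal, full_matrices=False)
    d = vt[0]
    if np.sum(basal @ d) < 0:
        d = -d
    R = rot2d(np.pi - np.arctan2(d[1], d[0]))  # entry axis -> -x
    ci = (np.asarray(inner, dtype=float) - start) @ R.T
    co = (np.asarray(outer, dtype=float) - start) @ R.T
    mid = mid @ R.T
    t = np.diff(mid, axis=0)
    turning = np.sum(t[:-1, 0] * t[1:, 1] - t[:-1, 1] * t[1:, 0])
    if turning < 0:  # enforce left-turning spiral
        ci[:, 1] *= -1
        co[:, 1] *= -1
    return ci, co


def project_to_plane(
    samples: list[CrossSectionSample], canonicalize: bool = True
) -> CochleaContour2D:
    """Project the 3D inner/outer point cloud onto its ODR plane and order
    the projections by plane angle into the two wall polylines."""
    if len(samples) < 6:
        raise InvalidInputError(f"need at least 6 samples, got {len(samples)}")
    samples = sorted(samples, key=lambda s: s.plane_angle)
    inner3 = np.array([s.inner_point for s in samples], dtype=float)
    outer3 = np.array([s.outer_point for s in samples], dtype=float)
    allp = np.vstack([inner3, outer3])
    c, e1, e2, _ = fit_odr_plane(allp)
    to2d = lambda P: np.stack([(P - c) @ e1, (P - c) @ e2], axis=-1)
    inner2, outer2 = to2d(inner3), to2d(outer3)
    if canonicalize:
        inner2, outer2 = canonicalize_contours(inner2, outer2)
    contour = CochleaContour2D(
        inner_contour=inner2,
        outer_contour=outer2,
        cochleostomy_point=0.5 * (inner2[0] + outer2[0]),
        entry_direction=np.array([-1.0, 0.0]),
        size_class="custom",
    )
    try:
        contour.distance_A = measure_distance_A(contour)
    except InsufficientCoverageError:
        contour.distance_A = None
    return contour


# ---------------------------------------------------------------------------
# distance A (Escudé)
# ---------------------------------------------------------------------------

def _total_turning(points: np.ndarray) -> float:
    """Absolute accumulated heading change along a polyline (radians)."""
    t = np.diff(points, axis=0)
    ang = np.arctan2(t[:, 1], t[:, 0])
    return float(np.abs(np.sum(np.abs(np.diff(np.unwrap(ang))))))


def measure_distance_A(contour: CochleaContour2D) -> float:
    """Greatest lateral dimension of the basal turn: the longest chord from
    the round-window end of the outer wall to the opposing lateral wall."""
    outer = np.asarray(contour.outer_contour, dtype=float)
    if len(outer) < 8:
        raise InsufficientCoverageError("outer contour has too few vertices")
    t = np.diff(outer, axis=0)
    ang = np.unwrap(np.arctan2(t[:, 1], t[:, 0]))
    turning = np.concatenate([[0.0], np.abs(np.cumsum(np.diff(ang)))])
    if turning[-1] < 2 * np.pi - 1e-6:
        raise InsufficientCoverageError(
            f"contour covers {np.degrees(turning[-1]):.0f} deg < one full basal turn"
        )
    rw = outer[0]
    basal = outer[: int(np.searchsorted(turning, 2 * np.pi)) + 2]
    return float(np.max(np.linalg.norm(basal - rw, axis=1)))


def measure_distance_B(contour: CochleaContour2D) -> float:
    """Basal-turn dimension perpendicular to the A line (optional extra;
    recorded but unused downstream — cochleae are classified by A only)."""
    outer = np.asarray(contour.outer_contour, dtype=float)
    a_len = measure_distance_A(contour)  # also validates coverage
    rw = outer[0]
    dists = np.linalg.norm(outer - rw, axis=1)
    d = (outer[int(np.argmax(dists))] - rw) / a_len
    n = np.array([-d[1], d[0]])
    proj = (outer - rw) @ n
    return float(proj.max() - proj.min())


# ---------------------------------------------------------------------------
# synthetic generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LumenWidthProfile:
    """Radial lumen width as a fraction of the inter-turn gap, clamped.

    ``scale`` rescales the whole width field; values < 1 emulate a
    segmentation restricted closer to the scala tympani rather than the whole
    bony labyrinth.
    """

    fraction: float = 0.85
    floor: float = 0.45
    cap: float = 2.6
    scale: float = 1.0

    def width(self, r_outer: np.ndarray, b: float) -> np.ndarray:
        gap = r_outer * (1.0 - np.exp(-2.0 * np.pi * b))
        return self.scale * np.clip(self.fraction * gap, self.floor, self.cap)


def synthesize_cochlea(
    size: str | None = None,
    A_mm: float | None = None,
    turns: float = 2.0,
    lumen_width_profile: LumenWidthProfile | None = None,
    seed: int | None = None,
    spiral_b: float = 0.12,
    theta_step_deg: float = 1.0,
    noise_amplitude: float = 0.0,
) -> CochleaContour2D:
    """Build synthetic inner/outer lumen walls as two offset logarithmic
    spirals whose basal-turn greatest lateral dimension equals the target
    distance A (within measurement resolution).

    One of ``size`` (preset CS/CM/CL) or ``A_mm`` must be given.
    """
    if size is not None:
        if size not in SIZE_PRESETS:
            raise InvalidInputError(f"unknown size preset {size!r}")
        A_target = SIZE_PRESETS[size]
        size_class = size
    elif A_mm is not None:
        A_target = float(A_mm)
        size_class = "custom"
    else:
        raise InvalidInputError("either size or A_mm must be given")
    lo, hi = A_PLAUSIBLE_RANGE
    if not lo <= A_target <= hi:
        raise InvalidConfigError(
            f"A={A_target} mm outside the plausible human range [{lo}, {hi}]"
        )
    if turns < 1.75:
        raise InvalidConfigError(f"turns={turns} below the minimum of 1.75")
    prof = lumen_width_profile or LumenWidthProfile()

    theta = np.deg2rad(np.arange(0.0, 360.0 * turns + theta_step_deg / 2, theta_step_deg))
    # provisional basal radius; rescaled to the target A after measurement
    r_b = A_target / (1.0 + np.exp(-spiral_b * np.pi))
    r_out = r_b * np.exp(-spiral_b * theta)
    width = prof.width(r_out, spiral_b)
    if np.any(width >= r_out * (1.0 - np.exp(-2.0 * np.pi * spiral_b)) + 1e-12):
        warnings.warn("lumen width reaches the inter-turn gap; walls may touch")
    if noise_amplitude > 0.0:
        rng = np.random.default_rng(seed)
        wobble = noise_amplitude * np.sin(
            theta * rng.uniform(2.0, 4.0) + rng.uniform(0, 2 * np.pi)
        )
        r_out = r_out + wobble
    r_in = r_out - width
    if np.any(r_in <= 0):
        raise InvalidConfigError("inner wall radius non-positive; widen spiral or narrow lumen")
    unit = np.stack([np.cos(theta), np.sin(theta)], axis=-1)
    outer = r_out[:, None] * unit
    inner = r_in[:, None] * unit

    inner, outer = canonicalize_contours(inner, outer)
    contour = CochleaContour2D(
        inner_contour=inner,
        outer_contour=outer,
        cochleostomy_point=0.5 * (inner[0] + outer[0]),
        entry_direction=np.array([-1.0, 0.0]),
        size_class=size_class,
        meta={"turns": turns, "spiral_b": spiral_b, "A_target": A_target},
    )
    measured = measure_distance_A(contour)
    factor = A_target / measured
    inner = inner * factor
    outer = outer * factor
    inner, outer = canonicalize_contours(inner, outer)
    contour = CochleaContour2D(
        inner_contour=inner,
        outer_contour=outer,
        cochleostomy_point=0.5 * (inner[0] + outer[0]),
        entry_direction=np.array([-1.0, 0.0]),
        size_class=size_class,
        meta={"turns": turns, "spiral_b": spiral_b, "A_target": A_target},
    )
    contour.distance_A = measure_distance_A(contour)

    # basal 180 degrees must accommodate the widest part of the array
    half_turn = len(theta) // int(2 * turns) if turns else len(theta)
    n = max(len(inner), len(outer))
    w = contour.lumen_width[: max(half_turn, 8) * n // len(theta)]
    if np.any(w < MAX_ELECTRODE_WIDTH):
        contour.narrow_lumen_warning = True
        warnings.warn("basal lumen narrower than the electrode; insertion will be contact-forced")
    return contour
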