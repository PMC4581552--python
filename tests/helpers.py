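"""Independent oracles shared by unit and acceptance tests."""

from __future__ import annotations

import numpy as np
import shapely
from scipy.stats import qmc

from cisim.cochlea import CochleaContour2D
from cisim.electrode import ElectrodeOutline


def montecarlo_overlap_area(outline, contour: CochleaContour2D, n: int = 1 << 17) -> float:
    """Point-sampling estimate of area(outline ∩ forbidden shell).

    Independent of polygon clipping: quasi-random points over the outline's
    bounding box are classified by point-in-polygon tests only.
    """
    poly = outline.polygon
    minx, miny, maxx, maxy = poly.bounds
    sampler = qmc.Sobol(d=2, scramble=False)
    pts = sampler.random(n)
    xs = minx + pts[:, 0] * (maxx - minx)
    ys = miny + pts[:, 1] * (maxy - miny)
    inside_outline = shapely.contains_xy(poly, xs, ys)
    inside_forbidden = shapely.contains_xy(contour.forbidden_region, xs, ys)
    frac = np.mean(inside_outline & inside_forbidden)
    return float(frac * (maxx - minx) * (maxy - miny))


def straight_lumen(width: float = 2.0, length: float = 25.0) -> CochleaContour2D:
    """Synthetic straight-walled 'lumen' for closed-form overlap fixtures:
    exactly parallel walls at y = +-width/2 over x in [-length, 0]."""
    x = np.linspace(0.0, -length, 120)
    inner = np.column_stack([x, np.full_like(x, -width / 2.0)])
    outer = np.column_stack([x, np.full_like(x, width / 2.0)])
    return CochleaContour2D(
        inner_contour=inner,
        outer_contour=outer,
        cochleostomy_point=np.zeros(2),
        entry_direction=np.array([-1.0, 0.0]),
        size_class="straight-test",
    )


def rectangle_outline(
    length: float = 10.0,
    width: float = 0.8,
    y_offset: float = 0.0,
    angle_deg: float = 0.0,
) -> ElectrodeOutline:
    """Constant-width rectangular outline along -x with its centreline at
    ``y_offset``; optionally tilted about the origin."""
    k = 101
    u = np.linspace(0.0, length, k)
    path = np.column_stack([-u, np.full(k, y_offset)])
    normals = np.tile([0.0, 1.0], (k, 1))
    if angle_deg:
        a = np.deg2rad(angle_deg)
        R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        path = path @ R.T
        normals = normals @ R.T
    widths = np.full(k, width)
    half = width / 2.0
    ring = np.vstack([path + half * normals, (path - half * normals)[::-1]])
    return ElectrodeOutline(
        ring=ring,
        tip_ring=np.vstack(
            [path[:5] + half * normals[:5], (path[:5] - half * normals[:5])[::-1]]
        ),
        path=path,
        path_u=u,
        normals=normals,
        widths=widths,
        total_length=length,
        inner_offset=width / 2.0,
    )


def helical_tube_mesh(
    tube_radius: float = 0.5,
    helix_radius: float = 4.0,
    turns: float = 2.0,
    pitch_per_turn: float = 1.0,
    n_t: int = 240,
    n_psi: int = 24,
    phase_deg: float = 7.0,
):
    """Closed triangulated tube swept along a helix (analytic frame).

    ``phase_deg`` offsets the helix ends so the flat end caps never lie
    exactly inside a cutting plane of the default 5- or 15-degree grids.
    """
    import trimesh

    t = np.deg2rad(phase_deg) + np.linspace(0.0, 2 * np.pi * turns, n_t)
    psi = np.linspace(0.0, 2 * np.pi, n_psi, endpoint=False)
    cx = helix_radius * np.cos(t)
    cy = helix_radius * np.sin(t)
    cz = pitch_per_turn * t / (2 * np.pi)
    # radial and axial directions of the sweep frame
    nx, ny = np.cos(t), np.sin(t)
    verts = []
    for i in range(n_t):
        for p in psi:
            r = tube_radius
            verts.append(
                [
                    cx[i] + r * np.cos(p) * nx[i],
                    cy[i] + r * np.cos(p) * ny[i],
                    cz[i] + r * np.sin(p),
                ]
            )
    verts = np.array(verts)
    faces = []
    for i in range(n_t - 1):
        for j in range(n_psi):
            a = i * n_psi + j
            b = i * n_psi + (j + 1) % n_psi
            c = (i + 1) * n_psi + j
            d = (i + 1) * n_psi + (j + 1) % n_psi
            faces.append([a, b, c])
            faces.append([b, d, c])
    # cap the two ends with fans
    start_c = len(verts)
    verts = np.vstack([verts, [[cx[0], cy[0], cz[0]], [cx[-1], cy[-1], cz[-1]]]])
    for j in range(n_psi):
        faces.append([start_c, (j + 1) % n_psi, j])
        base = (n_t - 1) * n_psi
        faces.append([start_c + 1, base + j, base + (j + 1) % n_psi])
    return trimesh.Trimesh(vertices=verts, faces=np.array(faces), process=False)
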