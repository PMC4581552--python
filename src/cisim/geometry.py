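"""Small planar-geometry helpers shared across modules.

Everything works on ``(N, 2)`` float arrays in millimetres.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "rot2d",
    "rigid_transform",
    "polyline_arclength",
    "resample_polyline",
    "polyline_tangents",
    "circular_arc_from_frame",
    "frame_on_circular_arc",
]


def rot2d(angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[c, -s], [s, c]])


def rigid_transform(points, angle_rad=0.0, translation=(0.0, 0.0), pivot=(0.0, 0.0)):
    """Rotate ``points`` by ``angle_rad`` about ``pivot``, then translate."""
    p = np.asarray(points, dtype=float)
    pivot = np.asarray(pivot, dtype=float)
    out = (p - pivot) @ rot2d(angle_rad).T + pivot + np.asarray(translation, dtype=float)
    return out


def polyline_arclength(points) -> np.ndarray:
    """Cumulative arc length at each vertex, starting at zero."""
    p = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_polyline(points, n: int | None = None, s: np.ndarray | None = None):
    """Resample a polyline uniformly (``n`` vertices) or at arc positions ``s``."""
    p = np.asarray(points, dtype=float)
    u = polyline_arclength(p)
    if s is None:
        if n is None:
            raise ValueError("either n or s must be given")
        s = np.linspace(0.0, u[-1], n)
    s = np.asarray(s, dtype=float)
    x = np.interp(s, u, p[:, 0])
    y = np.interp(s, u, p[:, 1])
    return np.stack([x, y], axis=-1)


def polyline_tangents(points) -> np.ndarray:
    """Unit tangents via central differences (one-sided at the ends)."""
    p = np.asarray(points, dtype=float)
    t = np.gradient(p, axis=0)
    norm = np.linalg.norm(t, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return t / norm


def circular_arc_from_frame(origin, tangent_angle, kappa, s):
    """Points of a circular arc leaving ``origin`` with heading ``tangent_angle``.

    ``kappa`` is the signed curvature (positive = turn left); ``s`` the signed
    arc-length positions along the arc.  Closed form, exact for any ``s``.
    """
    s = np.asarray(s, dtype=float)
    ox, oy = np.asarray(origin, dtype=float)
    if abs(kappa) < 1e-15:
        x = ox + s * np.cos(tangent_angle)
        y = oy + s * np.sin(tangent_angle)
    else:
        x = ox + (np.sin(tangent_angle + kappa * s) - np.sin(tangent_angle)) / kappa
        y = oy - (np.cos(tangent_angle + kappa * s) - np.cos(tangent_angle)) / kappa
    return np.stack([x, y], axis=-1)


def frame_on_circular_arc(origin, tangent_angle, kappa, s):
    """(point, tangent angle) after travelling ``s`` along the arc."""
    pt = circular_arc_from_frame(origin, tangent_angle, kappa, np.atleast_1d(s))[0]
    return pt, tangent_angle + kappa * float(s)
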