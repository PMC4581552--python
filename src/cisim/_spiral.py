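"""Planar logarithmic-spiral primitive with closed-form arc-length parameterization.

The radius obeys ``r(theta) = a * exp(b * theta)`` around a centre point.  Both
the electrode array's manufactured shape and the synthetic cochlear lumen are
arcs of such spirals, so the class carries exact point/tangent/curvature
evaluation and the closed-form arc length

    s(theta0, theta) = sqrt(1 + b^2) / b * (r(theta) - r(theta0)),

which lets callers walk the curve by millimetres instead of by angle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LogSpiral"]


@dataclass(frozen=True)
class LogSpiral:
    """Logarithmic spiral ``r(theta) = a * exp(b * theta)``.

    Parameters
    ----------
    a:
        Radius at ``theta = 0`` (mm); strictly positive.
    b:
        Dimensionless growth rate per radian.  ``b > 0`` means the radius
        grows with increasing ``theta``.
    center:
        Spiral centre in the working plane (mm).
    phi:
        Orientation of the ``theta = 0`` ray (radians).
    sense:
        ``+1`` for counter-clockwise increase of the polar angle with
        ``theta``, ``-1`` for clockwise.
    """

    a: float
    b: float
    center: tuple[float, float] = (0.0, 0.0)
    phi: float = 0.0
    sense: int = 1

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError(f"spiral scale a must be positive, got {self.a}")
        if self.sense not in (-1, 1):
            raise ValueError("sense must be +1 or -1")

    # -- radial/angular closed forms -------------------------------------
    def radius(self, theta):
        return self.a * np.exp(self.b * np.asarray(theta, dtype=float))

    def theta_at_radius(self, r):
        return np.log(np.asarray(r, dtype=float) / self.a) / self.b

    def arclength(self, theta0, theta):
        """Arc length travelled from ``theta0`` to ``theta`` (signed)."""
        b = self.b
        if b == 0.0:  # degenerate circle
            return self.a * (np.asarray(theta) - theta0)
        return np.sqrt(1.0 + b * b) / b * (self.radius(theta) - self.radius(theta0))

    def theta_at_arclength(self, s, theta0=0.0):
        """Angle after travelling arc length ``s`` from ``theta0`` (signed)."""
        b = self.b
        if b == 0.0:
            return theta0 + np.asarray(s, dtype=float) / self.a
        r = self.radius(theta0) + b * np.asarray(s, dtype=float) / np.sqrt(1.0 + b * b)
        if np.any(r <= 0):
            raise ValueError("arc length runs past the spiral pole (r <= 0)")
        return self.theta_at_radius(r)

    # -- geometry --------------------------------------------------------
    def point(self, theta):
        theta = np.asarray(theta, dtype=float)
        ang = self.phi + self.sense * theta
        r = self.radius(theta)
        cx, cy = self.center
        return np.stack([cx + r * np.cos(ang), cy + r * np.sin(ang)], axis=-1)

    def tangent(self, theta, direction: int = 1):
        """Unit tangent for travel in the direction of increasing ``theta``.

        ``direction=-1`` flips the tangent (travel toward decreasing theta).
        """
        theta = np.asarray(theta, dtype=float)
        ang = self.phi + self.sense * theta
        b = self.b
        # d/dtheta of the point, then normalized
        dx = b * np.cos(ang) - self.sense * np.sin(ang)
        dy = b * np.sin(ang) + self.sense * np.cos(ang)
        t = np.stack([dx, dy], axis=-1)
        t /= np.linalg.norm(t, axis=-1, keepdims=True)
        return direction * t

    def curvature(self, theta):
        """Unsigned curvature ``1 / (r * sqrt(1 + b^2))``."""
        return 1.0 / (self.radius(theta) * np.sqrt(1.0 + self.b * self.b))

    def signed_curvature(self, theta, direction: int = 1):
        """Curvature signed by the turning sense of travel.

        Positive means the curve turns left (counter-clockwise) when walked
        in the given direction.
        """
        return self.sense * direction * self.curvature(theta)
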