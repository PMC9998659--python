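"""Analytic line-ellipsoid intersection and pole-to-cortex distances.

A line through P1, P2 is parameterized P = P1 + t (P2 - P1). Substituting it
into the centered ellipsoid equation

    ((x-x3)/a)^2 + ((y-y3)/b)^2 + ((z-z3)/c)^2 = 1

yields a quadratic chi t^2 + gamma_lin t + zeta = 0 whose discriminant
classifies the geometry (negative: miss, zero: tangent, positive: two hits).
Rotated ellipsoids are handled by transforming the line into the ellipsoid's
principal frame first, where the centered axis-aligned form applies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Ellipsoid3D, SpindleAxes

__all__ = [
    "RaySegment",
    "IntersectionResult",
    "GeometryError",
    "ContainmentError",
    "intersect_line_ellipsoid",
    "pole_cortex_distances",
]

# absolute tolerance on the normalized discriminant below which the line is
# classified as tangent (exact zero is measure-zero in floating point)
TANGENT_TOL = 1e-12


class GeometryError(ValueError):
    """Degenerate ray-tracing input."""


class ContainmentError(GeometryError):
    """A spindle pole lies outside the cortex ellipsoid."""


@dataclass
class RaySegment:
    """Line through two distinct points; t parameterizes P1 + t (P2 - P1)."""

    p1: np.ndarray
    p2: np.ndarray

    def __post_init__(self) -> None:
        self.p1 = np.asarray(self.p1, dtype=float).reshape(3)
        self.p2 = np.asarray(self.p2, dtype=float).reshape(3)
        if np.array_equal(self.p1, self.p2):
            raise GeometryError("degenerate segment: p1 == p2")

    def point_at(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.p1 + np.multiply.outer(t, self.p2 - self.p1)


@dataclass
class IntersectionResult:
    """Roots and points of the line-ellipsoid quadratic.

    ``coeffs`` holds (chi, gamma_lin, zeta); ``t_values`` the 0-2 sorted real
    roots; ``points`` the corresponding lab-frame coordinates.
    """

    coeffs: tuple[float, float, float]
    t_values: np.ndarray
    points: np.ndarray
    count: int


def intersect_line_ellipsoid(segment: RaySegment, ellipsoid: Ellipsoid3D) -> IntersectionResult:
    """Intersect an infinite line with an ellipsoid analytically.

    The line is mapped into the ellipsoid's principal frame (subtract center,
    rotate by orientation transpose); the quadratic coefficients are

        chi       = sum ((q2 - q1)_k / s_k)^2
        gamma_lin = 2 sum (q2 - q1)_k q1_k / s_k^2
        zeta      = sum (q1_k / s_k)^2 - 1

    with s = (a, b, c). Intersection points are mapped back via P1 + t(P2-P1).
    """
    R = ellipsoid.orientation
    s = np.asarray(ellipsoid.semi_axes, dtype=float)
    q1 = R.T @ (segment.p1 - ellipsoid.center)
    q2 = R.T @ (segment.p2 - ellipsoid.center)
    d = q2 - q1
    inv_sq = 1.0 / np.square(s)
    chi = float(np.sum(d * d * inv_sq))
    gamma_lin = float(2.0 * np.sum(d * q1 * inv_sq))
    zeta = float(np.sum(q1 * q1 * inv_sq) - 1.0)

    disc = gamma_lin * gamma_lin - 4.0 * chi * zeta
    scale = gamma_lin * gamma_lin + 4.0 * abs(chi * zeta)
    norm_disc = disc / scale if scale > 0 else disc

    if abs(norm_disc) <= TANGENT_TOL:
        t_vals = np.array([-gamma_lin / (2.0 * chi)])
    elif disc < 0:
        t_vals = np.empty(0)
    else:
        sq = np.sqrt(disc)
        # numerically stable quadratic roots
        q = -0.5 * (gamma_lin + np.copysign(sq, gamma_lin))
        roots = [q / chi]
        if q != 0:
            roots.append(zeta / q)
        else:
            roots.append(-gamma_lin / chi - roots[0])
        t_vals = np.sort(np.asarray(roots))
    points = segment.point_at(t_vals) if t_vals.size else np.empty((0, 3))
    return IntersectionResult(
        coeffs=(chi, gamma_lin, zeta),
        t_values=t_vals,
        points=points,
        count=int(t_vals.size),
    )


def pole_cortex_distances(
    axes: SpindleAxes, cortex: Ellipsoid3D
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Distances from each spindle pole to the cortex along the pole-to-pole axis.

    Extends the pole1-pole2 line to the cortex surface. hit1 is the
    intersection on pole1's side (t < 0 on the segment parameterization),
    hit2 on pole2's side (t > 1); d_i = ||pole_i - hit_i||.

    Raises
    ------
    ContainmentError
        If either pole lies on or outside the cortex ellipsoid (frames with
        such segmentation artifacts are excluded upstream rather than clamped).
    """
    inside = cortex.surface_value(np.vstack([axes.pole1, axes.pole2]))
    if not np.all(inside < 1.0):
        which = [name for name, v in zip(("pole1", "pole2"), inside) if v >= 1.0]
        raise ContainmentError(f"{' and '.join(which)} outside the cortex ellipsoid")
    seg = RaySegment(axes.pole1, axes.pole2)
    res = intersect_line_ellipsoid(seg, cortex)
    if res.count != 2:  # pragma: no cover - impossible for strictly interior poles
        raise GeometryError("interior poles must yield two cortex intersections")
    t_lo, t_hi = res.t_values
    hit1 = seg.point_at(t_lo)
    hit2 = seg.point_at(t_hi)
    d1 = float(np.linalg.norm(axes.pole1 - hit1))
    d2 = float(np.linalg.norm(axes.pole2 - hit2))
    return d1, d2, hit1, hit2
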