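"""Minimum-volume enclosing ellipsoids and derived spindle/cortex shape readouts.

The mitotic spindle and the cell cortex are both modeled as ellipsoids. The
cortex ellipsoid is fitted to boundary pixels of the cortex masks lifted to
their physical z planes; the spindle ellipsoid is fitted to the 3D point cloud
produced by PSF-based axial estimation. The three principal axes of the
spindle ellipsoid define its length (pole-to-pole), width and height axes,
whose endpoints are the six points used for identity tracking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Ellipsoid3D",
    "Ellipse2D",
    "SpindleAxes",
    "DegenerateGeometryError",
    "RankError",
    "fit_mvee",
    "fit_mvee_2d",
    "fit_ellipse_2d",
    "eccentricity",
    "principal_axes_endpoints",
]


class DegenerateGeometryError(ValueError):
    """Raised when a geometric fit is requested on degenerate input."""


class RankError(DegenerateGeometryError):
    """Point cloud does not span the fit dimension.

    ``deficient_dims`` records how many dimensions are missing.
    """

    def __init__(self, message: str, deficient_dims: int):
        super().__init__(message)
        self.deficient_dims = deficient_dims


@dataclass
class Ellipsoid3D:
    """Ellipsoid with center (um), sorted semi-axes a >= b >= c (um) and a
    right-handed orthonormal orientation whose columns are the unit directions
    of the a, b, c axes."""

    center: np.ndarray
    semi_axes: tuple[float, float, float]
    orientation: np.ndarray

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        self.orientation = np.asarray(self.orientation, dtype=float).reshape(3, 3)
        a, b, c = self.semi_axes
        if not (a >= b >= c > 0):
            raise ValueError(f"semi-axes must satisfy a >= b >= c > 0, got {self.semi_axes}")
        if not np.allclose(self.orientation.T @ self.orientation, np.eye(3), atol=1e-9):
            raise ValueError("orientation matrix is not orthonormal")
        if np.linalg.det(self.orientation) < 0:
            raise ValueError("orientation matrix must have det +1")

    @property
    def quadratic_form(self) -> np.ndarray:
        """Matrix M such that (p - center)^T M (p - center) <= 1 inside."""
        inv_sq = np.diag(1.0 / np.square(self.semi_axes))
        return self.orientation @ inv_sq @ self.orientation.T

    def surface_value(self, points: np.ndarray) -> np.ndarray:
        """Evaluate (p-c)^T M (p-c); 1 on the surface, < 1 inside."""
        d = np.atleast_2d(points) - self.center
        return np.einsum("ij,jk,ik->i", d, self.quadratic_form, d)

    def contains(self, points: np.ndarray, tol: float = 0.0) -> np.ndarray:
        return self.surface_value(points) <= 1.0 + tol

    @property
    def volume(self) -> float:
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * np.pi * a * b * c

    def to_record(self) -> dict:
        return {
            "center": self.center.tolist(),
            "semi_axes": [float(s) for s in self.semi_axes],
            "orientation": self.orientation.ravel().tolist(),  # row-major
        }

    @classmethod
    def from_record(cls, rec: dict) -> "Ellipsoid3D":
        return cls(
            center=np.asarray(rec["center"], float),
            semi_axes=tuple(rec["semi_axes"]),
            orientation=np.asarray(rec["orientation"], float).reshape(3, 3),
        )


@dataclass
class Ellipse2D:
    """2D ellipse: center, semi-axes A >= B, major-axis angle in (-90, 90] deg."""

    center: np.ndarray
    semi_axes: tuple[float, float]
    angle_deg: float

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(2)
        A, B = self.semi_axes
        if not (A >= B > 0):
            raise ValueError(f"semi-axes must satisfy A >= B > 0, got {self.semi_axes}")
        if not (-90.0 < self.angle_deg <= 90.0):
            raise ValueError(f"angle_deg must lie in (-90, 90], got {self.angle_deg}")


@dataclass
class SpindleAxes:
    """The six principal-axis endpoints of the spindle ellipsoid plus centroid.

    pole1/pole2 terminate the length axis (the spindle poles); width1/width2
    and height1/height2 terminate the width and height axes. All coordinates
    are physical (um).
    """

    pole1: np.ndarray
    pole2: np.ndarray
    width1: np.ndarray
    width2: np.ndarray
    height1: np.ndarray
    height2: np.ndarray
    centroid: np.ndarray

    def __post_init__(self) -> None:
        for name in ("pole1", "pole2", "width1", "width2", "height1", "height2", "centroid"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float).reshape(3))

    def axis_direction(self, axis: str) -> np.ndarray:
        """Unit vector from endpoint 1 to endpoint 2 of the named axis."""
        p1, p2 = self.endpoints(axis)
        v = p2 - p1
        n = np.linalg.norm(v)
        if n == 0:
            raise DegenerateGeometryError(f"{axis} axis has coincident endpoints")
        return v / n

    def endpoints(self, axis: str) -> tuple[np.ndarray, np.ndarray]:
        if axis == "length":
            return self.pole1, self.pole2
        if axis == "width":
            return self.width1, self.width2
        if axis == "height":
            return self.height1, self.height2
        raise KeyError(axis)

    def triad(self) -> np.ndarray:
        """3x3 matrix whose columns are the unit length/width/height directions."""
        return np.column_stack(
            [self.axis_direction("length"), self.axis_direction("width"), self.axis_direction("height")]
        )

    @property
    def length_um(self) -> float:
        return float(np.linalg.norm(self.pole2 - self.pole1))

    @property
    def width_um(self) -> float:
        return float(np.linalg.norm(self.width2 - self.width1))

    @property
    def height_um(self) -> float:
        return float(np.linalg.norm(self.height2 - self.height1))

    def replace(self, **kw) -> "SpindleAxes":
        fields = {n: getattr(self, n) for n in ("pole1", "pole2", "width1", "width2", "height1", "height2", "centroid")}
        fields.update(kw)
        return SpindleAxes(**fields)


AXIS_NAMES = ("length", "width", "height")


def _khachiyan_weights(points: np.ndarray, tolerance: float, max_iter: int) -> np.ndarray:
    """Barycentric coordinate-descent iteration for the MVEE dual weights.

    Maximizes log det of the lifted second-moment matrix over the simplex.
    Converges when the maximal Mahalanobis value is within (1 + tolerance) of
    its optimum d + 1, which bounds both containment slack and volume
    suboptimality by O(tolerance).
    """
    n, d = points.shape
    Q = np.column_stack([points, np.ones(n)])  # n x (d+1)
    u = np.full(n, 1.0 / n)
    dp1 = d + 1
    for _ in range(max_iter):
        X = Q.T @ (Q * u[:, None])
        try:
            M = np.einsum("ij,ij->i", Q @ np.linalg.inv(X), Q)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by rank check
            raise RankError("singular moment matrix during MVEE iteration", 1) from exc
        j_add = int(np.argmax(M))
        support = u > 1e-14
        j_away = int(np.flatnonzero(support)[np.argmin(M[support])])
        eps_add = M[j_add] / dp1 - 1.0
        eps_away = 1.0 - M[j_away] / dp1
        if max(eps_add, eps_away) <= tolerance:
            break
        if eps_add >= eps_away:  # Frank-Wolfe add step toward the worst point
            m = M[j_add]
            step = (m - dp1) / (dp1 * (m - 1.0))
            u *= 1.0 - step
            u[j_add] += step
        else:  # Wolfe-Atwood away step shrinking an over-weighted point
            m = M[j_away]
            step = (m - dp1) / (dp1 * (m - 1.0))  # negative
            step = max(step, -u[j_away] / (1.0 - u[j_away]))
            u *= 1.0 - step
            u[j_away] += step
            u = np.maximum(u, 0.0)
    return u


def _ellipsoid_from_quadratic(center: np.ndarray, A: np.ndarray) -> Ellipsoid3D:
    """Build an Ellipsoid3D from (p-c)^T A (p-c) = 1 with deterministic axis labels."""
    eigval, eigvec = np.linalg.eigh(A)
    # eigh ascending -> semi-axes 1/sqrt(eig) descending matches order
    semi = 1.0 / np.sqrt(eigval)
    # enforce a >= b >= c with matching columns
    order = np.argsort(semi)[::-1]
    semi = semi[order]
    vec = eigvec[:, order]
    # deterministic sign: first nonzero component of each column positive
    for k in range(3):
        col = vec[:, k]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            vec[:, k] = -col
    if np.linalg.det(vec) < 0:
        vec[:, 2] = -vec[:, 2]
    return Ellipsoid3D(center=center, semi_axes=tuple(semi), orientation=vec)


def fit_mvee(points, tolerance: float = 1e-4, max_iter: int = 10000) -> Ellipsoid3D:
    """Fit the minimum-volume enclosing ellipsoid of a 3D point cloud.

    Uses Khachiyan's barycentric coordinate-descent iteration. Every input
    point p satisfies (p - center)^T M (p - center) <= 1 + O(tolerance) and the
    volume is within a (1 + O(tolerance)) factor of optimal.

    Parameters
    ----------
    points : (n, 3) array-like
        At least 4 affinely independent points.
    tolerance : float
        Relative convergence tolerance of the dual iteration.

    Raises
    ------
    RankError
        If the points are coplanar/collinear (names the deficient dimension).
    """
    P = np.asarray(points, dtype=float)
    if P.ndim != 2 or P.shape[1] != 3:
        raise ValueError(f"expected (n, 3) points, got shape {P.shape}")
    n, d = P.shape
    centered = P - P.mean(axis=0)
    rank = np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, float(np.abs(P).max())))
    if n < d + 1 or rank < d:
        deficient = d - rank
        raise RankError(
            f"point set spans only {rank} of {d} dimensions "
            f"({deficient} deficient): MVEE undefined",
            deficient,
        )
    u = _khachiyan_weights(P, tolerance, max_iter)
    center = P.T @ u
    cov = (P.T * u) @ P - np.outer(center, center)
    A = np.linalg.inv(cov) / d
    return _ellipsoid_from_quadratic(center, A)


def fit_mvee_2d(points, tolerance: float = 1e-6, max_iter: int = 10000) -> Ellipse2D:
    """Minimum-volume (area) enclosing ellipse of a 2D point cloud."""
    P = np.asarray(points, dtype=float)
    if P.ndim != 2 or P.shape[1] != 2:
        raise ValueError(f"expected (n, 2) points, got shape {P.shape}")
    n, d = P.shape
    centered = P - P.mean(axis=0)
    rank = np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, float(np.abs(P).max())))
    if n < d + 1 or rank < d:
        raise RankError(f"point set spans only {rank} of {d} dimensions", d - rank)
    u = _khachiyan_weights(P, tolerance, max_iter)
    center = P.T @ u
    cov = (P.T * u) @ P - np.outer(center, center)
    A = np.linalg.inv(cov) / d
    eigval, eigvec = np.linalg.eigh(A)
    semi = 1.0 / np.sqrt(eigval)  # descending
    major = eigvec[:, 0] if semi[0] >= semi[1] else eigvec[:, 1]
    A_ax, B_ax = max(semi), min(semi)
    angle = np.degrees(np.arctan2(major[1], major[0]))
    angle = ((angle + 90.0) % 180.0) - 90.0
    if angle == -90.0:
        angle = 90.0
    return Ellipse2D(center=center, semi_axes=(A_ax, B_ax), angle_deg=angle)


def fit_ellipse_2d(boundary) -> Ellipse2D:
    """Direct least-squares conic fit of an ellipse to boundary points.

    Wraps the stable Halir–Flach formulation (scikit-image ``EllipseModel``)
    and normalizes to semi-axes A >= B with the major-axis angle in
    (-90, 90] degrees.

    Raises
    ------
    DegenerateGeometryError
        For fewer than 5 points or a non-elliptical conic.
    """
    from skimage.measure import EllipseModel

    pts = np.asarray(boundary, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"expected (n, 2) boundary points, got shape {pts.shape}")
    if len(pts) < 5:
        raise DegenerateGeometryError(f"ellipse fit needs >= 5 points, got {len(pts)}")
    model = EllipseModel.from_estimate(pts)
    if not model:
        raise DegenerateGeometryError("conic fit failed or is not an ellipse")
    A_ax, B_ax = model.axis_lengths  # major, minor
    if not np.isfinite([A_ax, B_ax]).all() or B_ax <= 0:
        raise DegenerateGeometryError("conic fit is not an ellipse (non-positive axis)")
    ang = float(np.degrees(model.theta))
    ang = ((ang + 90.0) % 180.0) - 90.0
    if ang == -90.0:
        ang = 90.0
    return Ellipse2D(center=tuple(model.center), semi_axes=(A_ax, B_ax), angle_deg=ang)


def eccentricity(ellipse: Ellipse2D) -> float:
    """sqrt(1 - B^2/A^2): 0 for a circle, approaching 1 for a line."""
    A, B = ellipse.semi_axes
    return float(np.sqrt(1.0 - (B * B) / (A * A)))


def principal_axes_endpoints(ellipsoid: Ellipsoid3D) -> SpindleAxes:
    """Six principal-axis endpoints of an ellipsoid as spindle axes.

    Poles terminate the longest (a) axis, width the b axis, height the c axis;
    spindle length = 2a and width = 2b are the morphometric readouts.
    """
    c = ellipsoid.center
    a, b, cc = ellipsoid.semi_axes
    u1, u2, u3 = ellipsoid.orientation.T
    return SpindleAxes(
        pole1=c - a * u1,
        pole2=c + a * u1,
        width1=c - b * u2,
        width2=c + b * u2,
        height1=c - cc * u3,
        height2=c + cc * u3,
        centroid=c.copy(),
    )
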