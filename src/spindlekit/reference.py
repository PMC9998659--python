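"""Independent reference implementations used to cross-check the fast paths.

These deliberately take a different computational route from the production
code (generic convex optimization, dense numeric scanning, exhaustive
enumeration) and are intended for validation, not analysis use.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

from .geometry import Ellipsoid3D

__all__ = [
    "mvee_volume_detmax",
    "line_ellipsoid_scan",
    "ray_march_distance",
    "best_axis_labelings",
]


def mvee_volume_detmax(points: np.ndarray, tol: float = 1e-12) -> float:
    """MVEE volume via the determinant-maximization convex program.

    Solves the dual  max log det( sum_i u_i q_i q_i^T )  over the probability
    simplex (q the lifted points) with a general-purpose SQP solver, and
    converts the optimum to the primal ellipsoid volume. Independent of the
    coordinate-descent production path.
    """
    P = np.asarray(points, dtype=float)
    n, d = P.shape
    Q = np.column_stack([P, np.ones(n)])

    def neg_logdet(u):
        X = Q.T @ (Q * u[:, None])
        sign, ld = np.linalg.slogdet(X)
        if sign <= 0:
            return 1e12
        return -ld

    def grad(u):
        X = Q.T @ (Q * u[:, None])
        Xi = np.linalg.inv(X)
        return -np.einsum("ij,jk,ik->i", Q, Xi, Q)

    u0 = np.full(n, 1.0 / n)
    res = minimize(
        neg_logdet,
        u0,
        jac=grad,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * n,
        constraints=[{"type": "eq", "fun": lambda u: u.sum() - 1.0, "jac": lambda u: np.ones(n)}],
        options={"maxiter": 2000, "ftol": tol},
    )
    u = np.clip(res.x, 0.0, None)
    u /= u.sum()
    center = P.T @ u
    cov = (P.T * u) @ P - np.outer(center, center)
    A = np.linalg.inv(cov) / d
    # volume of (x-c)^T A (x-c) <= 1
    return float(4.0 / 3.0 * np.pi / np.sqrt(np.linalg.det(A)))


def line_ellipsoid_scan(p1, p2, ellipsoid: Ellipsoid3D, t_range=(-50.0, 50.0), n=4_000_001):
    """Dense numeric root scan of the surface equation along a line.

    Evaluates f(t) = (P(t)-c)^T M (P(t)-c) - 1 on a fine grid and refines each
    sign change by bisection. Tangencies (double roots) are detected as local
    minima of f within a small tolerance of zero.
    """
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    M = ellipsoid.quadratic_form
    c = ellipsoid.center

    def f(t):
        t = np.atleast_1d(np.asarray(t, float))
        pts = p1[None, :] + t[:, None] * (p2 - p1)[None, :]
        d = pts - c
        return np.einsum("ij,jk,ik->i", d, M, d) - 1.0

    ts = np.linspace(t_range[0], t_range[1], n)
    vals = f(ts)
    roots = []
    sign_change = np.flatnonzero(np.signbit(vals[:-1]) != np.signbit(vals[1:]))
    for i in sign_change:
        lo, hi = ts[i], ts[i + 1]
        flo = vals[i]
        for _ in range(100):
            mid = 0.5 * (lo + hi)
            fm = f(mid)[0]
            if (fm < 0) == (flo < 0):
                lo, flo = mid, fm
            else:
                hi = mid
        roots.append(0.5 * (lo + hi))
    if not roots:
        # possible tangency: quadratic f has a single minimum along the line
        i = int(np.argmin(vals))
        if 0 < i < n - 1 and abs(vals[i]) < 1e-9:
            roots = [ts[i]]
    return np.asarray(sorted(roots))


def ray_march_distance(origin, direction, ellipsoid: Ellipsoid3D, step=1e-4, max_dist=200.0):
    """March a ray from an interior point until it leaves the ellipsoid,
    then bisect the crossing to high precision."""
    origin = np.asarray(origin, float)
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)

    def inside(s):
        return float(ellipsoid.surface_value(origin + s * direction)[0]) < 1.0

    s = 0.0
    coarse = step * 1000
    while inside(s + coarse) and s < max_dist:
        s += coarse
    lo, hi = s, s + coarse
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if inside(mid):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def best_axis_labelings(endpoint_series: np.ndarray) -> tuple[np.ndarray, float]:
    """Exhaustive minimal-total-displacement labeling for one axis.

    ``endpoint_series`` is (T, 2, 3): the two endpoints per frame in arbitrary
    order. Tries all 2^(T-1) per-frame swap patterns and returns the pattern
    (swap flags for frames 1..T-1) minimizing total endpoint displacement,
    with the minimal cost.
    """
    E = np.asarray(endpoint_series, float)
    T = E.shape[0]
    best_cost, best_pattern = np.inf, None
    for bits in range(2 ** (T - 1)):
        cost = 0.0
        prev = E[0]
        for t in range(1, T):
            cur = E[t] if not (bits >> (t - 1)) & 1 else E[t][::-1]
            cost += np.linalg.norm(cur[0] - prev[0]) + np.linalg.norm(cur[1] - prev[1])
            prev = cur
        if cost < best_cost:
            best_cost = cost
            best_pattern = np.array([(bits >> (t - 1)) & 1 for t in range(1, T)], dtype=bool)
    return best_pattern, float(best_cost)
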