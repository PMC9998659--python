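"""Frame-to-frame spindle rotation and displacement decomposition.

Rotation between consecutive frames is the proper rotation mapping the
previous identity-consistent axis triad onto the current one. Its Euler
angles in the ZYX factorization R = Rz(gamma) Ry(beta) Rx(alpha) are the
tumbling (alpha, about the spindle length axis direction x), rolling (beta,
about y) and rotation (gamma, about z) readouts. Spindle translation is
decomposed into longitudinal / equatorial / axial components along the
previous frame's length / width / height axes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import SpindleAxes

__all__ = [
    "RotationAngles",
    "DisplacementDecomposition",
    "rot_x",
    "rot_y",
    "rot_z",
    "compose_euler",
    "frame_rotation",
    "euler_angles",
    "decompose_displacement",
    "summarize_track",
    "ecdf_inverse",
]

GIMBAL_TOL = 1e-9


@dataclass
class RotationAngles:
    """ZYX Euler angles in degrees, each in (-180, 180].

    ``gimbal_locked`` flags |beta| = 90 deg frames where gamma is folded to 0
    and the free angle absorbed into alpha.
    """

    alpha_deg: float
    beta_deg: float
    gamma_deg: float
    gimbal_locked: bool = False

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.alpha_deg, self.beta_deg, self.gamma_deg)


@dataclass
class DisplacementDecomposition:
    """Signed um components of a displacement along the previous frame's
    length (longitudinal), width (equatorial) and height (axial) axes, with
    fractions |component| / ||displacement||."""

    delta_lg: float
    delta_eq: float
    delta_ax: float
    f_lg: float
    f_eq: float
    f_ax: float
    zero_motion: bool = False


def rot_x(angle_deg: float) -> np.ndarray:
    a = np.radians(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def rot_y(angle_deg: float) -> np.ndarray:
    a = np.radians(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def rot_z(angle_deg: float) -> np.ndarray:
    a = np.radians(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def compose_euler(alpha_deg: float, beta_deg: float, gamma_deg: float) -> np.ndarray:
    """R = Rz(gamma) Ry(beta) Rx(alpha)."""
    return rot_z(gamma_deg) @ rot_y(beta_deg) @ rot_x(alpha_deg)


def _check_rotation(R: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    R = np.asarray(R, dtype=float).reshape(3, 3)
    if not np.allclose(R.T @ R, np.eye(3), atol=max(tol, 1e-9)):
        raise ValueError("matrix is not orthonormal")
    if np.linalg.det(R) < 0:
        raise ValueError("matrix is a reflection (det < 0), not a rotation")
    return R


def frame_rotation(
    previous: SpindleAxes, current: SpindleAxes, frame: str = "lab", tol: float = 1e-6
) -> np.ndarray:
    """Rotation carrying the previous axis triad onto the current one.

    With A_t the matrix whose columns are the unit length/width/height
    directions at frame t, the lab-frame rotation is R = A_t A_{t-1}^T. With
    ``frame="spindle"`` the same rotation is expressed in the previous
    spindle's coordinates, R' = A_{t-1}^T A_t, which is invariant under a
    global lab rotation applied to all frames.
    """
    A_prev = previous.triad()
    A_cur = current.triad()
    for name, A in (("previous", A_prev), ("current", A_cur)):
        if not np.allclose(A.T @ A, np.eye(3), atol=tol):
            raise ValueError(f"{name} frame axis triad is not orthonormal within {tol}")
    if frame == "lab":
        R = A_cur @ A_prev.T
    elif frame == "spindle":
        R = A_prev.T @ A_cur
    else:
        raise ValueError(f"unknown frame {frame!r}")
    # identity-consistent triads share handedness, so R is a proper rotation
    return _check_rotation(R, tol)


def euler_angles(R: np.ndarray) -> RotationAngles:
    """Extract ZYX Euler angles from a rotation matrix.

    Defined by round-trip consistency with ``compose_euler``: for |beta| < 90
    deg, compose_euler(*euler_angles(R).as_tuple()) reproduces R to machine
    precision. At gimbal lock (|cos beta| < 1e-9) only alpha +/- gamma is
    determined; gamma is set to 0, the free angle folded into alpha, and the
    frame flagged.
    """
    R = _check_rotation(R)
    cos_beta = float(np.hypot(R[0, 0], R[1, 0]))
    if cos_beta < GIMBAL_TOL:
        beta = 90.0 if -R[2, 0] > 0 else -90.0
        if beta > 0:
            alpha = float(np.degrees(np.arctan2(R[0, 1], R[0, 2])))
        else:
            alpha = float(np.degrees(np.arctan2(-R[0, 1], -R[0, 2])))
        return RotationAngles(alpha, beta, 0.0, gimbal_locked=True)
    beta = float(np.degrees(np.arctan2(-R[2, 0], cos_beta)))
    alpha = float(np.degrees(np.arctan2(R[2, 1], R[2, 2])))
    gamma = float(np.degrees(np.arctan2(R[1, 0], R[0, 0])))
    return RotationAngles(alpha, beta, gamma)


def decompose_displacement(
    previous: SpindleAxes, current: SpindleAxes, reference: str = "centroid"
) -> DisplacementDecomposition:
    """Project the frame-to-frame displacement onto the previous spindle axes.

    ``reference`` selects the tracked point: "centroid" (default), "pole1" or
    "pole2". Components are signed um along the previous frame's unit length /
    width / height axes; fractions are |component| over the displacement norm
    and satisfy f_lg^2 + f_eq^2 + f_ax^2 = 1 for nonzero motion. Zero
    displacement yields zero fractions with ``zero_motion`` set.
    """
    if reference == "centroid":
        delta = current.centroid - previous.centroid
    elif reference in ("pole1", "pole2"):
        delta = getattr(current, reference) - getattr(previous, reference)
    else:
        raise ValueError(f"unknown reference {reference!r}")
    A = previous.triad()
    comps = A.T @ delta
    norm = float(np.linalg.norm(delta))
    if norm == 0.0:
        return DisplacementDecomposition(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, zero_motion=True)
    fr = np.abs(comps) / norm
    return DisplacementDecomposition(
        float(comps[0]), float(comps[1]), float(comps[2]), float(fr[0]), float(fr[1]), float(fr[2])
    )


def ecdf_inverse(values, percentile: float = 0.75) -> float:
    """Empirical-distribution quantile under the nearest-rank (<= p) rule.

    The returned value is the smallest sample x with ECDF(x) >= percentile,
    i.e. the ceil(p * n)-th order statistic.
    """
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("empty series")
    if not 0 < percentile <= 1:
        raise ValueError("percentile must be in (0, 1]")
    rank = int(np.ceil(percentile * v.size))
    return float(v[rank - 1])


def summarize_track(track, percentile: float = 0.75, frame: str = "lab", reference: str = "centroid") -> dict:
    """Per-movie kinematic summary of a tracked spindle.

    Computes per-frame-pair Euler angles and displacement decompositions over
    consecutive accepted frames, then medians of |alpha|, |beta|, |gamma|, the
    ECDF quantile of each angle magnitude at ``percentile``, median
    displacement fractions, and cumulative |angle| series (rotation accrued
    since the first frame). Angle rates are per frame interval.
    """
    frames = [f for f in track.frames if f is not None]
    if len(frames) < 2:
        raise ValueError("kinematic summary requires >= 2 accepted frames")
    alphas, betas, gammas = [], [], []
    decomps = []
    for prev, cur in zip(frames[:-1], frames[1:]):
        ang = euler_angles(frame_rotation(prev, cur, frame=frame))
        alphas.append(ang.alpha_deg)
        betas.append(ang.beta_deg)
        gammas.append(ang.gamma_deg)
        decomps.append(decompose_displacement(prev, cur, reference=reference))
    a, b, g = (np.abs(np.asarray(x, dtype=float)) for x in (alphas, betas, gammas))
    fr = np.array([[d.f_lg, d.f_eq, d.f_ax] for d in decomps])
    return {
        "alpha_deg": np.asarray(alphas),
        "beta_deg": np.asarray(betas),
        "gamma_deg": np.asarray(gammas),
        "median_abs_alpha_deg": float(np.median(a)),
        "median_abs_beta_deg": float(np.median(b)),
        "median_abs_gamma_deg": float(np.median(g)),
        "ecdf_abs_alpha_deg": ecdf_inverse(a, percentile),
        "ecdf_abs_beta_deg": ecdf_inverse(b, percentile),
        "ecdf_abs_gamma_deg": ecdf_inverse(g, percentile),
        "cumulative_abs_alpha_deg": np.cumsum(a),
        "cumulative_abs_beta_deg": np.cumsum(b),
        "cumulative_abs_gamma_deg": np.cumsum(g),
        "fractions": fr,
        "median_f_lg": float(np.median(fr[:, 0])),
        "median_f_eq": float(np.median(fr[:, 1])),
        "median_f_ax": float(np.median(fr[:, 2])),
        "decompositions": decomps,
    }
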