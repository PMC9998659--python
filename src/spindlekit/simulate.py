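"""Ground-truth-annotated synthetic mitotic movies.

Emulates the sparse widefield acquisition regime the package targets: a few
z-slices (default 3, 2 um apart) per 3-minute timepoint, high-resolution
pixels, a near-spherical cell cortex (in-plane eccentricity ~0.3), a bipolar
spindle whose pose follows a scripted Euler-angle/centroid trajectory, and a
chromosome plate perpendicular to the spindle long axis. Every frame carries
exact ground truth (pose, endpoints, pole-cortex distances, clean masks), so
each downstream stage can be tested against known values with no external
data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import Ellipsoid3D, SpindleAxes, principal_axes_endpoints
from .io import Calibration, Movie
from .kinematics import compose_euler
from .raytrace import pole_cortex_distances

__all__ = ["SimulationParams", "GroundTruth", "ScriptingError", "generate_movie", "corrupt_movie"]

CORRUPTION_MODES = ("neighbor_object", "nonuniform_illumination", "blur", "intensity_drop")


class ScriptingError(ValueError):
    """The scripted trajectory takes the spindle outside the cortex."""


@dataclass
class SimulationParams:
    """Scripted acquisition and scene parameters.

    Acquisition defaults mirror the targeted live-cell regime: 21 timepoints
    3 min apart, three z-slices with a 2 um gap, 512 px frames at
    0.06887 um/px. The cortex is a near-spherical ellipsoid (in-plane
    eccentricity 0.30, the median of mitotic cells); the spindle a
    metaphase-sized ellipsoid (length 12 um, width 7 um). Per-frame Euler
    increments and centroid velocity script the motion; all randomness flows
    from ``seed`` through independent per-frame streams.
    """

    n_frames: int = 21
    n_slices: int = 3
    z_step_um: float = 2.0
    dt_min: float = 3.0
    image_size_px: int = 512
    pixel_size_um: float = 0.06887
    cortex_semi_axes_um: tuple[float, float, float] = (11.0, 10.5, 10.5)
    spindle_semi_axes_um: tuple[float, float, float] = (6.0, 3.5, 3.0)
    plate_thickness_um: float = 0.8
    euler_increments_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    centroid_velocity_um: tuple[float, float, float] = (0.0, 0.0, 0.0)  # per frame
    initial_euler_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    initial_offset_um: tuple[float, float, float] = (0.0, 0.0, 0.0)
    background_level: float = 100.0
    signal_amplitude: float = 2000.0
    noise_sigma: float = 8.0
    gradient_amplitude: float = 0.0
    blur_sigma_px: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1 or self.n_slices < 1:
            raise ValueError("n_frames and n_slices must be >= 1")
        for name in ("z_step_um", "dt_min", "pixel_size_um", "plate_thickness_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if min(self.cortex_semi_axes_um) <= 0 or min(self.spindle_semi_axes_um) <= 0:
            raise ValueError("all semi-axes must be positive")
        a, b, c = self.spindle_semi_axes_um
        if not a > b >= c:
            raise ValueError("spindle semi-axes must satisfy length > width >= height")

    @property
    def calibration(self) -> Calibration:
        return Calibration(self.pixel_size_um, self.z_step_um, self.dt_min)

    @property
    def cortex_center_um(self) -> np.ndarray:
        half = self.image_size_px / 2.0 * self.pixel_size_um
        mid_z = (self.n_slices - 1) / 2.0 * self.z_step_um
        return np.array([half, half, mid_z])


@dataclass
class GroundTruth:
    """Exact per-frame scene description emitted alongside the rendered movie."""

    centroids: list
    euler_deg: list  # cumulative (alpha, beta, gamma) per frame
    spindle_ellipsoids: list
    axes: list  # SpindleAxes per frame
    pole_cortex: list  # (d1, d2) per frame
    cortex: Ellipsoid3D
    spindle_masks: np.ndarray  # (T, Z, Y, X) bool, noise-free
    cortex_masks: np.ndarray
    chromosome_masks: np.ndarray

    def frame_table(self, dt_min: float) -> "object":
        import pandas as pd

        rows = []
        for i, (c, e, d) in enumerate(zip(self.centroids, self.euler_deg, self.pole_cortex)):
            ax = self.axes[i]
            rows.append(
                {
                    "frame": i,
                    "time_min": i * dt_min,
                    "centroid_x_um": c[0],
                    "centroid_y_um": c[1],
                    "centroid_z_um": c[2],
                    "alpha_deg": e[0],
                    "beta_deg": e[1],
                    "gamma_deg": e[2],
                    "pole1_x_um": ax.pole1[0],
                    "pole1_y_um": ax.pole1[1],
                    "pole1_z_um": ax.pole1[2],
                    "pole2_x_um": ax.pole2[0],
                    "pole2_y_um": ax.pole2[1],
                    "pole2_z_um": ax.pole2[2],
                    "pole1_cortex_dist_um": d[0],
                    "pole2_cortex_dist_um": d[1],
                }
            )
        return pd.DataFrame(rows)


def _scripted_poses(params: SimulationParams) -> tuple[list, list]:
    centroids, eulers = [], []
    c0 = params.cortex_center_um + np.asarray(params.initial_offset_um, float)
    v = np.asarray(params.centroid_velocity_um, float)
    e0 = np.asarray(params.initial_euler_deg, float)
    de = np.asarray(params.euler_increments_deg, float)
    for t in range(params.n_frames):
        centroids.append(c0 + t * v)
        eulers.append(tuple(e0 + t * de))
    return centroids, eulers


def _spindle_ellipsoid(centroid: np.ndarray, euler_deg: tuple, semi: tuple) -> Ellipsoid3D:
    R = compose_euler(*euler_deg)
    return Ellipsoid3D(center=centroid, semi_axes=semi, orientation=R)


def _check_containment(spindle: Ellipsoid3D, cortex: Ellipsoid3D, frame: int) -> None:
    # sample the spindle surface; every point must be strictly inside the cortex
    u = np.linspace(0, np.pi, 12)
    v = np.linspace(0, 2 * np.pi, 24, endpoint=False)
    uu, vv = np.meshgrid(u, v)
    a, b, c = spindle.semi_axes
    local = np.stack(
        [a * np.sin(uu) * np.cos(vv), b * np.sin(uu) * np.sin(vv), c * np.cos(uu)], axis=-1
    ).reshape(-1, 3)
    pts = local @ spindle.orientation.T + spindle.center
    if not np.all(cortex.surface_value(pts) < 1.0):
        raise ScriptingError(f"scripted spindle escapes the cortex at frame {frame}")


def _slice_grids(params: SimulationParams) -> tuple[np.ndarray, np.ndarray]:
    idx = np.arange(params.image_size_px, dtype=float) * params.pixel_size_um
    xx, yy = np.meshgrid(idx, idx)  # xx varies along columns, yy along rows
    return xx, yy


def _ellipsoid_slice_field(ell: Ellipsoid3D, xx: np.ndarray, yy: np.ndarray, z: float) -> np.ndarray:
    """Normalized squared radius of the ellipsoid evaluated on a z plane."""
    pts = np.stack([xx - ell.center[0], yy - ell.center[1], np.full_like(xx, z - ell.center[2])], axis=-1)
    q = pts @ ell.orientation  # rotate into the principal frame
    s = np.asarray(ell.semi_axes)
    return np.sum(np.square(q / s), axis=-1)


def _transverse_field(ell: Ellipsoid3D, xx: np.ndarray, yy: np.ndarray, z: float) -> np.ndarray:
    """Normalized squared distance from the long axis, on a z plane."""
    pts = np.stack([xx - ell.center[0], yy - ell.center[1], np.full_like(xx, z - ell.center[2])], axis=-1)
    q = pts @ ell.orientation
    s = np.asarray(ell.semi_axes)
    return (q[..., 1] / s[1]) ** 2 + (q[..., 2] / s[2]) ** 2


def generate_movie(params: SimulationParams) -> tuple[Movie, GroundTruth]:
    """Render a synthetic three-channel movie with exact ground truth.

    Channels: ``spindle`` — the spindle ellipsoid with intensity brightest
    along the pole-to-pole axis (microtubule density is highest along the
    length axis) falling off transversely, laterally blurred; ``cortex`` — a
    brightfield-like gray field with a dark rim where the cortex ellipsoid
    crosses each slice; ``chromosome`` — a plate perpendicular to the spindle
    long axis. Clean masks are the exact per-slice ellipsoid cross-sections.
    Rendering is fully determined by ``params.seed`` with one independent
    stream per frame.
    """
    cortex = Ellipsoid3D(
        center=params.cortex_center_um,
        semi_axes=params.cortex_semi_axes_um,
        orientation=np.eye(3),
    )
    centroids, eulers = _scripted_poses(params)
    spindles = [
        _spindle_ellipsoid(c, e, params.spindle_semi_axes_um) for c, e in zip(centroids, eulers)
    ]
    for t, sp in enumerate(spindles):
        _check_containment(sp, cortex, t)

    n, zn, sz = params.n_frames, params.n_slices, params.image_size_px
    xx, yy = _slice_grids(params)
    z_planes = np.arange(zn) * params.z_step_um

    ch = {
        name: np.zeros((n, zn, sz, sz), dtype=np.uint16)
        for name in ("spindle", "cortex", "chromosome")
    }
    masks = {name: np.zeros((n, zn, sz, sz), dtype=bool) for name in ("spindle", "cortex", "chromosome")}
    axes_list, dists = [], []

    for t, sp in enumerate(spindles):
        rng = np.random.default_rng([params.seed, t])
        axes = principal_axes_endpoints(sp)
        axes_list.append(axes)
        d1, d2, _, _ = pole_cortex_distances(axes, cortex)
        dists.append((d1, d2))
        plate = Ellipsoid3D(
            center=sp.center,
            semi_axes=(
                0.9 * sp.semi_axes[1],
                0.85 * sp.semi_axes[2],
                params.plate_thickness_um / 2.0,
            ),
            orientation=_plate_orientation(sp),
        )
        for k, z in enumerate(z_planes):
            r2_sp = _ellipsoid_slice_field(sp, xx, yy, z)
            inside_sp = r2_sp <= 1.0
            rho2 = _transverse_field(sp, xx, yy, z)
            spindle_img = np.where(inside_sp, params.signal_amplitude * (1.0 - 0.8 * rho2), 0.0)
            if params.blur_sigma_px > 0:
                spindle_img = gaussian_filter(spindle_img, params.blur_sigma_px)

            r2_cx = _ellipsoid_slice_field(cortex, xx, yy, z)
            inside_cx = r2_cx <= 1.0
            rim = np.abs(np.sqrt(np.maximum(r2_cx, 0.0)) - 1.0) < 0.02
            cortex_img = np.full_like(xx, 3.0 * params.background_level)
            cortex_img[rim] = 0.3 * params.background_level

            r2_pl = _ellipsoid_slice_field(plate, xx, yy, z)
            inside_pl = r2_pl <= 1.0
            chrom_img = np.where(inside_pl, params.signal_amplitude * (1.0 - 0.5 * r2_pl), 0.0)
            if params.blur_sigma_px > 0:
                chrom_img = gaussian_filter(chrom_img, params.blur_sigma_px)

            for name, img in (("spindle", spindle_img), ("cortex", cortex_img), ("chromosome", chrom_img)):
                img = img + params.background_level
                if params.gradient_amplitude:
                    img = img + params.gradient_amplitude * xx / xx.max()
                if params.noise_sigma:
                    img = img + rng.normal(0.0, params.noise_sigma, img.shape)
                ch[name][t, k] = np.clip(img, 0, 65535).astype(np.uint16)
            masks["spindle"][t, k] = inside_sp
            masks["cortex"][t, k] = inside_cx
            masks["chromosome"][t, k] = inside_pl

    movie = Movie(channels=ch, calibration=params.calibration)
    truth = GroundTruth(
        centroids=centroids,
        euler_deg=eulers,
        spindle_ellipsoids=spindles,
        axes=axes_list,
        pole_cortex=dists,
        cortex=cortex,
        spindle_masks=masks["spindle"],
        cortex_masks=masks["cortex"],
        chromosome_masks=masks["chromosome"],
    )
    return movie, truth


def _plate_orientation(spindle: Ellipsoid3D) -> np.ndarray:
    """Plate principal frame: widest in the spindle width direction, thinnest
    along the spindle length axis (the plate normal)."""
    u_len, u_wid, u_hei = spindle.orientation.T
    R = np.column_stack([u_wid, u_hei, u_len])
    if np.linalg.det(R) < 0:
        R[:, 2] = -R[:, 2]
    return R


def corrupt_movie(movie: Movie, mode: str, magnitude: float, seed: int = 0) -> Movie:
    """Apply a reproducible acquisition-style corruption; ground truth is
    unchanged by construction.

    Modes: ``neighbor_object`` (a bright distractor blob near the border of
    the spindle channel), ``nonuniform_illumination`` (multiplicative ramp),
    ``blur`` (Gaussian blur of sigma = magnitude px), ``intensity_drop``
    (random frames dimmed by the magnitude fraction).
    """
    if mode not in CORRUPTION_MODES:
        raise ValueError(f"unknown corruption mode {mode!r}; choose from {CORRUPTION_MODES}")
    if magnitude == 0:
        return Movie(channels={k: v.copy() for k, v in movie.channels.items()}, calibration=movie.calibration)
    rng = np.random.default_rng([seed, CORRUPTION_MODES.index(mode)])
    out = {k: v.astype(np.float64, copy=True) for k, v in movie.channels.items()}
    t, zn, h, w = movie.shape
    if mode == "neighbor_object":
        yy, xx = np.mgrid[0:h, 0:w].astype(float)
        cy, cx = h * 0.08, w * 0.08  # near the top-left border
        radius = magnitude
        blob = np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * radius**2)))
        peak = max(float(v.max()) for v in out.values())
        for name in out:
            out[name] += 0.8 * peak * blob
    elif mode == "nonuniform_illumination":
        ramp = 1.0 + magnitude * (np.arange(w, dtype=float) / max(w - 1, 1))
        for name in out:
            out[name] *= ramp[None, None, None, :]
    elif mode == "blur":
        for name in out:
            for i in range(t):
                for k in range(zn):
                    out[name][i, k] = gaussian_filter(out[name][i, k], magnitude)
    elif mode == "intensity_drop":
        frames = rng.choice(t, size=max(1, t // 4), replace=False)
        for name in out:
            out[name][frames] *= 1.0 - magnitude
    channels = {k: np.clip(v, 0, 65535).astype(movie.channels[k].dtype) for k, v in out.items()}
    return Movie(channels=channels, calibration=movie.calibration)
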