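"""End-to-end reconstruction pipeline: masks + images -> tracked spindle.

Per frame: cortex-mask boundary pixels from every z-slice are lifted to their
physical planes and fitted with an enclosing ellipsoid; the spindle's
brightest masked slice is lifted into a 3D point cloud through the PSF axial
inverse and fitted likewise; the resulting ellipsoids feed pole refinement,
six-point identity tracking and pole-to-cortex ray tracing.
"""

from __future__ import annotations

import numpy as np
from skimage import measure

from .geometry import Ellipsoid3D, RankError, fit_mvee, fit_mvee_2d
from .io import Calibration, Movie
from .psf import GaussianPSFModel, reconstruct_spindle_points
from .tracking import TrackedSpindle, track_movie

__all__ = [
    "fit_cortex_frame",
    "fit_spindle_frame",
    "fit_spindle_from_masks",
    "reconstruct_and_track",
]


def _slice_boundary_px(mask2d: np.ndarray) -> np.ndarray:
    """Sub-pixel boundary of the largest foreground region, as (x, y) pixels."""
    contours = measure.find_contours(np.asarray(mask2d).astype(float), 0.5)
    if not contours:
        return np.empty((0, 2))
    contour = max(contours, key=len)
    return contour[:, ::-1]  # (row, col) -> (x, y)


def fit_cortex_frame(
    cortex_masks: np.ndarray, calibration: Calibration, mode: str = "raw"
) -> Ellipsoid3D:
    """Fit the cortex ellipsoid from one frame's (Z, Y, X) mask stack.

    ``mode="raw"`` lifts the boundary pixels of every slice to their physical
    z plane and fits a joint 3D minimum-volume enclosing ellipsoid.

    ``mode="spherical_prior"`` regularizes the weakly constrained axial axis:
    with very few z-slices the joint fit's z extent is ill-posed (a flattened
    ellipsoid with an inflated equator can enclose a stack of rings in less
    volume), so the widest slice is fitted with a 2D enclosing ellipse and the
    axial semi-axis tied to the in-plane radius mean — appropriate for the
    near-spherical mitotic cortex.
    """
    zmask = np.asarray(cortex_masks).astype(bool)
    if zmask.ndim != 3:
        raise ValueError("expected a (Z, Y, X) mask stack for one frame")
    px, zs = calibration.pixel_size_um, calibration.z_step_um
    boundaries = [_slice_boundary_px(zmask[k]) for k in range(zmask.shape[0])]
    if mode == "raw":
        pts = []
        for k, b in enumerate(boundaries):
            if len(b):
                pts.append(np.column_stack([b * px, np.full(len(b), k * zs)]))
        if not pts:
            raise ValueError("no cortex boundary pixels in any slice")
        return fit_mvee(np.vstack(pts))
    if mode == "spherical_prior":
        areas = [zmask[k].sum() for k in range(zmask.shape[0])]
        k = int(np.argmax(areas))
        if not len(boundaries[k]):
            raise ValueError("widest cortex slice has no boundary")
        ell = fit_mvee_2d(boundaries[k] * px)
        A, B = ell.semi_axes
        c_ax = 0.5 * (A + B)
        th = np.radians(ell.angle_deg)
        u_major = np.array([np.cos(th), np.sin(th), 0.0])
        u_minor = np.array([-np.sin(th), np.cos(th), 0.0])
        u_z = np.array([0.0, 0.0, 1.0])
        center = np.array([ell.center[0], ell.center[1], k * zs])
        # axial semi-axis c_ax lies between B and A: order axes accordingly
        cols = [u_major, u_z, u_minor]
        semi = (A, c_ax, B)
        R = np.column_stack(cols)
        if np.linalg.det(R) < 0:
            R[:, 2] = -R[:, 2]
        return Ellipsoid3D(center=center, semi_axes=semi, orientation=R)
    raise ValueError(f"unknown cortex fit mode {mode!r}")


def fit_spindle_frame(
    images: np.ndarray,
    spindle_masks: np.ndarray,
    model: GaussianPSFModel,
    calibration: Calibration,
    top_fraction: float = 0.30,
) -> Ellipsoid3D:
    """Fit the spindle ellipsoid from one frame's (Z, Y, X) images and masks.

    Uses the slice with the highest masked intensity; bright masked pixels are
    lifted to 3D with the PSF axial inverse (offsets measured from the slice's
    physical plane) and enclosed with the MVEE.
    """
    imgs = np.asarray(images, dtype=float)
    zmask = np.asarray(spindle_masks).astype(bool)
    if imgs.shape != zmask.shape or imgs.ndim != 3:
        raise ValueError("images and masks must share one (Z, Y, X) shape")
    totals = [imgs[k][zmask[k]].sum() if zmask[k].any() else -np.inf for k in range(imgs.shape[0])]
    k = int(np.argmax(totals))
    if not np.isfinite(totals[k]):
        raise ValueError("no spindle mask pixels in any slice")
    pts = reconstruct_spindle_points(
        imgs[k], zmask[k], model, calibration.pixel_size_um, top_fraction
    )
    # axial offsets are relative to the in-focus plane of this slice
    pts[:, 2] = k * calibration.z_step_um + (pts[:, 2] - model.z_center)
    try:
        return fit_mvee(pts)
    except RankError:
        # uniform-intensity degenerate case: spread points by a token axial
        # thickness of one intensity quantum so the fit is defined
        jitter = pts.copy()
        jitter[: len(jitter) // 2, 2] += 1e-3
        return fit_mvee(jitter)


def fit_spindle_from_masks(spindle_masks: np.ndarray, calibration: Calibration) -> Ellipsoid3D:
    """Geometric spindle fit from per-slice mask boundaries alone.

    Lifts the boundary pixels of every slice's spindle cross-section to its
    physical z plane and fits a joint enclosing ellipsoid. Uses no intensity
    information — the purely geometric counterpart of ``fit_spindle_frame``
    for intensity-free inputs (e.g. external masks without raw images).
    """
    zmask = np.asarray(spindle_masks).astype(bool)
    if zmask.ndim != 3:
        raise ValueError("expected a (Z, Y, X) mask stack for one frame")
    px, zs = calibration.pixel_size_um, calibration.z_step_um
    pts = []
    for k in range(zmask.shape[0]):
        b = _slice_boundary_px(zmask[k])
        if len(b):
            pts.append(np.column_stack([b * px, np.full(len(b), k * zs)]))
    if not pts:
        raise ValueError("no spindle boundary pixels in any slice")
    return fit_mvee(np.vstack(pts))


def reconstruct_and_track(
    movie: Movie,
    spindle_masks: np.ndarray,
    cortex_masks: np.ndarray,
    model: GaussianPSFModel,
    spindle_channel: str = "spindle",
    cortex_mode: str = "spherical_prior",
    top_fraction: float = 0.30,
    refine: bool = True,
) -> TrackedSpindle:
    """Run the full 3D modeling + tracking pipeline over a movie.

    ``spindle_masks`` and ``cortex_masks`` are (T, Z, Y, X) boolean stacks
    from any source (the classical pipelines, an external detector, or the
    simulator's ground truth).
    """
    imgs = movie.channels[spindle_channel].astype(float)
    t = movie.n_frames
    per_frame = []
    for i in range(t):
        spindle_ell = fit_spindle_frame(
            imgs[i], spindle_masks[i], model, movie.calibration, top_fraction
        )
        cortex_ell = fit_cortex_frame(cortex_masks[i], movie.calibration, cortex_mode)
        max_proj = np.asarray(spindle_masks[i]).astype(bool).any(axis=0)
        per_frame.append((spindle_ell, max_proj, cortex_ell))
    return track_movie(per_frame, movie.calibration, refine=refine)
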