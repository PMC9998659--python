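"""Pole refinement and identity-consistent six-point spindle tracking.

The MVEE tends to overestimate the spindle length axis, so pole positions are
refined by scanning the max-projected spindle mask along the pole-to-pole line
and snapping poles to the first and last foreground pixels. Endpoint
identities (which pole is "pole 1", and likewise for the width and height
endpoints) are kept consistent across frames with a per-axis 2x2 nearest-
neighbor distance matrix between consecutive time points; a cross-pairing
minimum triggers a label swap that is recorded and propagates forward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import AXIS_NAMES, Ellipsoid3D, SpindleAxes, principal_axes_endpoints
from .io import Calibration, TRACK_COLUMNS
from .raytrace import ContainmentError, pole_cortex_distances

__all__ = [
    "TrackedSpindle",
    "RefinementError",
    "refine_poles",
    "assign_identities",
    "track_movie",
    "track_table",
]


class RefinementError(RuntimeError):
    """Axis scan found no foreground mask pixels."""


@dataclass
class TrackedSpindle:
    """Per-frame spindle axes with persistent endpoint identities.

    ``frames[i]`` is None for excluded frames; ``corrections[i]`` maps axis
    name -> whether a label swap was applied at frame i; ``distances[i]`` is
    (d1, d2) pole-cortex distances or None; ``excluded_frames`` records
    (frame index, reason); ``refinement_failed`` lists frames where the pole
    scan failed and original MVEE poles were retained.
    """

    frames: list
    corrections: list
    distances: list
    excluded_frames: list
    refinement_failed: list
    calibration: Calibration

    @property
    def n_accepted(self) -> int:
        return sum(f is not None for f in self.frames)

    @property
    def n_corrections(self) -> dict:
        out = {axis: 0 for axis in AXIS_NAMES}
        for corr in self.corrections:
            for axis in AXIS_NAMES:
                out[axis] += bool(corr.get(axis, False))
        return out

    def run_report(self) -> dict:
        return {
            "n_frames": len(self.frames),
            "n_accepted": self.n_accepted,
            "corrections_per_axis": self.n_corrections,
            "excluded_frames": [{"frame": i, "reason": r} for i, r in self.excluded_frames],
            "refinement_failed_frames": list(self.refinement_failed),
        }


def refine_poles(
    spindle_mask: np.ndarray,
    poles: tuple[np.ndarray, np.ndarray],
    ellipsoid: Ellipsoid3D,
    calibration: Calibration,
) -> tuple[np.ndarray, np.ndarray]:
    """Snap MVEE pole estimates to the mask boundary along the length axis.

    Samples the pole-to-pole segment at half-pixel steps with nearest-pixel
    lookup into the max-projected mask (integer conversion introduces the
    rounding the scan is designed around); the refined poles take the x, y of
    the first and last foreground pixels hit and the z of the line at those
    scan positions, so the refined length never exceeds the original.

    Raises
    ------
    RefinementError
        If the sampled line is entirely background.
    """
    mask = np.asarray(spindle_mask).astype(bool)
    if not mask.any():
        raise RefinementError("empty spindle mask")
    p1 = np.asarray(poles[0], dtype=float)
    p2 = np.asarray(poles[1], dtype=float)
    px = calibration.pixel_size_um
    # pixel-space lateral coordinates (x = col, y = row)
    a = p1[:2] / px
    b = p2[:2] / px
    seg_px = float(np.linalg.norm(b - a))
    if seg_px == 0:
        raise RefinementError("degenerate pole axis")
    n_steps = max(int(np.ceil(seg_px / 0.5)), 1)
    ts = np.linspace(0.0, 1.0, n_steps + 1)
    xy = a[None, :] + ts[:, None] * (b - a)[None, :]
    cols = np.rint(xy[:, 0]).astype(int)
    rows = np.rint(xy[:, 1]).astype(int)
    valid = (rows >= 0) & (rows < mask.shape[0]) & (cols >= 0) & (cols < mask.shape[1])
    fg = np.zeros(ts.size, dtype=bool)
    fg[valid] = mask[rows[valid], cols[valid]]
    hits = np.flatnonzero(fg)
    if hits.size == 0:
        raise RefinementError("pole-to-pole scan line misses the mask entirely")
    i_first, i_last = hits[0], hits[-1]

    def _refined(i: int) -> np.ndarray:
        z = p1[2] + ts[i] * (p2[2] - p1[2])
        return np.array([cols[i] * px, rows[i] * px, z])

    return _refined(i_first), _refined(i_last)


def apply_refined_poles(axes: SpindleAxes, p1: np.ndarray, p2: np.ndarray) -> SpindleAxes:
    """Rebuild spindle axes around refined poles.

    The centroid moves to the refined pole midpoint; the width and height
    axes keep their half-lengths and are re-orthogonalized against the (pixel
    snapped, hence slightly re-oriented) refined length direction, re-centered
    on the new centroid (the re-applied ellipsoid update of the refinement
    procedure).
    """
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    centroid = 0.5 * (p1 + p2)
    u_len = p2 - p1
    u_len = u_len / np.linalg.norm(u_len)
    w_old = axes.axis_direction("width")
    u_wid = w_old - (w_old @ u_len) * u_len
    u_wid = u_wid / np.linalg.norm(u_wid)
    u_hei = np.cross(u_len, u_wid)
    if u_hei @ axes.axis_direction("height") < 0:
        u_hei = -u_hei
    half_w = 0.5 * np.linalg.norm(axes.width2 - axes.width1)
    half_h = 0.5 * np.linalg.norm(axes.height2 - axes.height1)
    return SpindleAxes(
        pole1=p1,
        pole2=p2,
        width1=centroid - half_w * u_wid,
        width2=centroid + half_w * u_wid,
        height1=centroid - half_h * u_hei,
        height2=centroid + half_h * u_hei,
        centroid=centroid,
    )


def assign_identities(current: SpindleAxes, previous: SpindleAxes) -> tuple[SpindleAxes, dict]:
    """Per-axis nearest-neighbor label assignment between consecutive frames.

    For each endpoint pair the 2x2 Euclidean distance matrix
    D(i, j) = d(P_i,t, P_j,t-1) is evaluated; a correct assignment keeps
    endpoint 1 at t closest to endpoint 1 at t-1. When the cross pairing has
    the smaller total distance the labels are swapped and the axis flagged.
    Exact ties keep the previous labels.
    """
    corrections = {}
    fields = {}
    names = {"length": ("pole1", "pole2"), "width": ("width1", "width2"), "height": ("height1", "height2")}
    for axis, (n1, n2) in names.items():
        c1, c2 = getattr(current, n1), getattr(current, n2)
        p1, p2 = getattr(previous, n1), getattr(previous, n2)
        d_same = np.linalg.norm(c1 - p1) + np.linalg.norm(c2 - p2)
        d_cross = np.linalg.norm(c1 - p2) + np.linalg.norm(c2 - p1)
        swap = bool(d_cross < d_same)
        corrections[axis] = swap
        fields[n1], fields[n2] = (c2, c1) if swap else (c1, c2)
    out = SpindleAxes(centroid=current.centroid, **fields)
    return out, corrections


def apply_parity(axes: SpindleAxes, parity: dict) -> SpindleAxes:
    """Re-label endpoint pairs according to the persistent correction state.

    Once an identity correction is applied it is propagated to every later
    frame, so incoming raw labels are first brought into the corrected
    convention before new nearest-neighbor matching.
    """
    fields = {}
    names = {"length": ("pole1", "pole2"), "width": ("width1", "width2"), "height": ("height1", "height2")}
    for axis, (n1, n2) in names.items():
        a, b = getattr(axes, n1), getattr(axes, n2)
        fields[n1], fields[n2] = (b, a) if parity.get(axis, False) else (a, b)
    return SpindleAxes(centroid=axes.centroid, **fields)


def track_movie(
    per_frame: list,
    calibration: Calibration,
    refine: bool = True,
    scan_overshoot: float = 1.2,
    refine_debias_px: float = 0.5,
) -> TrackedSpindle:
    """Track a spindle through a movie of per-frame reconstructions.

    ``per_frame`` holds (spindle Ellipsoid3D, max-projected spindle mask or
    None, cortex Ellipsoid3D) triples. Each frame runs: principal-axis
    endpoints -> pole refinement -> identity assignment against the last
    accepted frame -> pole-cortex ray-traced distances. Frames whose poles
    fall outside the cortex are excluded (not clamped) and logged; failed
    refinements retain the MVEE poles and are flagged. Corrections, once
    applied, persist until the next correction because matching always uses
    the last accepted (already corrected) frame.

    ``scan_overshoot`` stretches the pole-to-pole segment about the centroid
    before the shrink-only boundary scan, so poles snap to the mask boundary
    whether the ellipsoid fit over- or undershoots the spindle tips.
    ``refine_debias_px`` nudges each refined pole outward along the axis to
    compensate the float-to-integer rounding bias of the scan: the outermost
    foreground pixel center of a convex mask sits on average half a pixel
    inside the true boundary.
    """
    if not per_frame:
        raise ValueError("track_movie requires at least one frame")
    frames: list = []
    corrections: list = []
    distances: list = []
    excluded: list = []
    refine_failed: list = []
    last_accepted: SpindleAxes | None = None
    parity = {axis: False for axis in AXIS_NAMES}
    for i, (spindle_ell, mask, cortex_ell) in enumerate(per_frame):
        axes = principal_axes_endpoints(spindle_ell)
        if refine and mask is not None:
            c = axes.centroid
            scan1 = c + scan_overshoot * (axes.pole1 - c)
            scan2 = c + scan_overshoot * (axes.pole2 - c)
            try:
                r1, r2 = refine_poles(mask, (scan1, scan2), spindle_ell, calibration)
                if refine_debias_px and not np.array_equal(r1, r2):
                    u = (r2 - r1) / np.linalg.norm(r2 - r1)
                    shift = refine_debias_px * calibration.pixel_size_um
                    r1, r2 = r1 - shift * u, r2 + shift * u
                axes = apply_refined_poles(axes, r1, r2)
            except RefinementError:
                refine_failed.append(i)
        corr = {axis: False for axis in AXIS_NAMES}
        if last_accepted is not None:
            axes, corr = assign_identities(apply_parity(axes, parity), last_accepted)
            for axis in AXIS_NAMES:
                parity[axis] ^= corr[axis]
        try:
            d1, d2, _, _ = pole_cortex_distances(axes, cortex_ell)
        except ContainmentError as exc:
            frames.append(None)
            corrections.append({axis: False for axis in AXIS_NAMES})
            distances.append(None)
            excluded.append((i, str(exc)))
            continue
        frames.append(axes)
        corrections.append(corr)
        distances.append((d1, d2))
        last_accepted = axes
    if all(f is None for f in frames):
        raise ValueError("no frame passed containment: nothing tracked")
    return TrackedSpindle(
        frames=frames,
        corrections=corrections,
        distances=distances,
        excluded_frames=excluded,
        refinement_failed=refine_failed,
        calibration=calibration,
    )


def track_table(track: TrackedSpindle) -> pd.DataFrame:
    """Flatten a tracked spindle into the per-frame table written to CSV.

    Angles and displacement components are relative to the previous accepted
    frame; the first accepted frame carries zeros.
    """
    from .kinematics import decompose_displacement, euler_angles, frame_rotation

    rows = []
    prev: SpindleAxes | None = None
    for i, axes in enumerate(track.frames):
        if axes is None:
            continue
        rec = {"frame": i, "time_min": i * track.calibration.dt_min}
        for name in ("pole1", "pole2", "width1", "width2", "height1", "height2", "centroid"):
            vec = getattr(axes, name)
            for k, ax in enumerate(("x", "y", "z")):
                rec[f"{name}_{ax}_um"] = vec[k]
        d1, d2 = track.distances[i]
        rec["pole1_cortex_dist_um"] = d1
        rec["pole2_cortex_dist_um"] = d2
        if prev is not None:
            ang = euler_angles(frame_rotation(prev, axes))
            dec = decompose_displacement(prev, axes)
            rec.update(
                alpha_deg=ang.alpha_deg,
                beta_deg=ang.beta_deg,
                gamma_deg=ang.gamma_deg,
                delta_lg_um=dec.delta_lg,
                delta_eq_um=dec.delta_eq,
                delta_ax_um=dec.delta_ax,
            )
        else:
            rec.update(alpha_deg=0.0, beta_deg=0.0, gamma_deg=0.0, delta_lg_um=0.0, delta_eq_um=0.0, delta_ax_um=0.0)
        rec["corrections_applied"] = int(any(track.corrections[i].values()))
        rows.append(rec)
        prev = axes
    return pd.DataFrame(rows, columns=TRACK_COLUMNS)
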