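"""Image-stack and table I/O, calibration metadata, and intensity padding.

Conventions fixed package-wide: arrays are ordered T, Z, Y, X with x = column
index and y = row index, both 0-based. Physical coordinates are pixel indices
times ``pixel_size_um`` laterally and slice index times ``z_step_um`` axially.
Calibration comes from explicit configuration, never from TIFF tags (tags,
when present, are only logged for comparison).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

__all__ = [
    "Calibration",
    "Movie",
    "MaskStack",
    "DimensionError",
    "read_movie",
    "write_movie",
    "read_mask_stack",
    "write_mask_stack",
    "pad_image",
    "write_tracks",
    "read_tracks",
    "load_config",
]

MASK_CLASSES = ("spindle", "cortex", "chromosome")


class DimensionError(ValueError):
    """TIFF page count inconsistent with the declared stack dimensions."""


@dataclass(frozen=True)
class Calibration:
    """Physical acquisition calibration.

    pixel_size_um: lateral length per pixel (x and y); z_step_um: axial
    spacing between slices; dt_min: frame interval in minutes.
    """

    pixel_size_um: float
    z_step_um: float
    dt_min: float

    def __post_init__(self) -> None:
        if min(self.pixel_size_um, self.z_step_um, self.dt_min) <= 0:
            raise ValueError("all calibration values must be strictly positive")


@dataclass
class Movie:
    """Named channels of 4D (T, Z, Y, X) intensity arrays plus calibration."""

    channels: dict[str, np.ndarray]
    calibration: Calibration

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("movie needs at least one channel")
        shapes = {name: ch.shape for name, ch in self.channels.items()}
        ref = next(iter(shapes.values()))
        if any(len(s) != 4 for s in shapes.values()):
            raise ValueError(f"channels must be 4D (T, Z, Y, X), got {shapes}")
        if any(s != ref for s in shapes.values()):
            raise ValueError(f"all channels must share one shape, got {shapes}")
        if ref[0] < 1 or ref[1] < 1:
            raise ValueError("T and Z must both be >= 1")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def n_frames(self) -> int:
        return self.shape[0]

    @property
    def n_slices(self) -> int:
        return self.shape[1]


@dataclass
class MaskStack:
    """Integer label stack aligned to one movie channel (0 = background)."""

    labels: np.ndarray
    class_name: str

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 4:
            raise ValueError("labels must be 4D (T, Z, Y, X)")
        if self.labels.min() < 0:
            raise ValueError("labels must be >= 0")
        if self.class_name not in MASK_CLASSES:
            raise ValueError(f"class_name must be one of {MASK_CLASSES}")


def read_movie(
    path,
    calibration: Calibration,
    n_slices: int = 1,
    channel_names: tuple[str, ...] = ("channel0",),
) -> Movie:
    """Read a multi-page TIFF into a Movie.

    Pages are ordered time-major: for each frame, slices in order, and within
    each slice the channels in ``channel_names`` order. Intensities are
    preserved bit-exactly.

    Raises
    ------
    FileNotFoundError, DimensionError
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    n_channels = len(channel_names)
    n_pages = pages.shape[0]
    per_frame = n_slices * n_channels
    if n_pages % per_frame != 0:
        raise DimensionError(
            f"{path.name}: {n_pages} pages not divisible by Z*channels = "
            f"{n_slices}*{n_channels} = {per_frame}"
        )
    with tifffile.TiffFile(path) as tf:
        tags = tf.pages[0].tags
        res = tags.get("XResolution")
        if res is not None:
            logger.info("TIFF XResolution tag present (%s); using configured calibration", res.value)
    t = n_pages // per_frame
    arr = pages.reshape(t, n_slices, n_channels, *pages.shape[1:])
    channels = {name: np.ascontiguousarray(arr[:, :, i]) for i, name in enumerate(channel_names)}
    return Movie(channels=channels, calibration=calibration)


def write_movie(movie: Movie, path) -> None:
    """Write a Movie as a multi-page TIFF in read_movie's page order."""
    names = list(movie.channels)
    t, z, h, w = movie.shape
    stacked = np.stack([movie.channels[n] for n in names], axis=2)  # T,Z,C,Y,X
    tifffile.imwrite(path, stacked.reshape(t * z * len(names), h, w))


def read_mask_stack(path, class_name: str, n_slices: int = 1) -> MaskStack:
    """Read a multi-page TIFF of masks (any nonzero value is foreground)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.shape[0] % n_slices != 0:
        raise DimensionError(
            f"{path.name}: {pages.shape[0]} pages not divisible by Z = {n_slices}"
        )
    t = pages.shape[0] // n_slices
    labels = (pages != 0).astype(np.uint8).reshape(t, n_slices, *pages.shape[1:])
    return MaskStack(labels=labels, class_name=class_name)


def write_mask_stack(mask: MaskStack, path) -> None:
    """Write masks as a multi-page 0/255 uint8 TIFF."""
    t, z, h, w = mask.labels.shape
    out = np.where(mask.labels != 0, 255, 0).astype(np.uint8)
    tifffile.imwrite(path, out.reshape(t * z, h, w))


def pad_image(image: np.ndarray, target_size: tuple[int, int], patch_size: tuple[int, int]) -> np.ndarray:
    """Pad an image to target size with background-emulating patches.

    The input is centered in the target canvas; the surrounding area is tiled
    row-major with the non-overlapping input patch of lowest pixel-intensity
    sum (ties broken by smallest (row, col) patch origin), so the padding
    emulates and propagates the image background rather than introducing an
    artificial level.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("pad_image expects a 2D image")
    th, tw = target_size
    h, w = img.shape
    ph, pw = patch_size
    if th < h or tw < w:
        raise ValueError(f"target size {target_size} smaller than image {img.shape}")
    if ph > h or pw > w:
        raise ValueError(f"patch size {patch_size} larger than image {img.shape}")
    if (th, tw) == (h, w):
        return img.copy()
    # non-overlapping patch grid (remainder cropped), lowest intensity sum wins
    best = None
    for r0 in range(0, h - ph + 1, ph):
        for c0 in range(0, w - pw + 1, pw):
            s = img[r0 : r0 + ph, c0 : c0 + pw].sum(dtype=np.float64)
            if best is None or s < best[0]:
                best = (s, r0, c0)
    _, r0, c0 = best
    patch = img[r0 : r0 + ph, c0 : c0 + pw]
    reps = (int(np.ceil(th / ph)), int(np.ceil(tw / pw)))
    canvas = np.tile(patch, reps)[:th, :tw].astype(img.dtype, copy=True)
    top = (th - h) // 2
    left = (tw - w) // 2
    canvas[top : top + h, left : left + w] = img
    return canvas


# ---------------------------------------------------------------------------
# track tables

_VEC_COLS = [
    f"{point}_{ax}_um"
    for point in ("pole1", "pole2", "width1", "width2", "height1", "height2", "centroid")
    for ax in ("x", "y", "z")
]
TRACK_COLUMNS = (
    ["frame", "time_min"]
    + _VEC_COLS
    + [
        "pole1_cortex_dist_um",
        "pole2_cortex_dist_um",
        "alpha_deg",
        "beta_deg",
        "gamma_deg",
        "delta_lg_um",
        "delta_eq_um",
        "delta_ax_um",
        "corrections_applied",
    ]
)


def write_tracks(track, path) -> pd.DataFrame:
    """Write a tracked spindle as a per-frame CSV.

    One row per accepted frame with endpoint coordinates (um), pole-cortex
    distances, Euler angles and displacement components relative to the
    previous accepted frame, and a flag for identity corrections. Values
    round-trip through ``read_tracks`` to <= 1e-9 relative error.
    """
    from .tracking import track_table  # local import; tracking depends on io

    table = track_table(track)
    if table.empty:
        raise ValueError("empty track: nothing to write")
    table.to_csv(path, index=False, float_format="%.17g")
    return table


def read_tracks(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path)


def load_config(path) -> dict:
    """Load a JSON run configuration (pixel_size_um, z_step_um, dt_min,
    channel_names, plus module parameter overrides)."""
    with open(path) as fh:
        return json.load(fh)
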