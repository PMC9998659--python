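"""Classical annotation pipelines and candidate filtering/tracking.

Three conventional pipelines generate single-cell masks without any learned
model: chromosome plates from dye/GFP images via Otsu thresholding with
border clearing and contour smoothing; dye-labeled spindles via adaptive
thresholding, morphology and a convex hull joining the two half-spindles;
and tubulin spindles via an outward ("inverse") active contour seeded on the
already-segmented chromosome plate. Candidates from any source (classical or
an external detector) pass through the same conditional filter (score, area,
border location) and a centroid nearest-neighbor tracker.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import savgol_filter
from skimage import draw, measure, morphology, segmentation
from skimage.filters import gaussian, threshold_local, threshold_otsu
from skimage.segmentation import inverse_gaussian_gradient, morphological_geodesic_active_contour

from .geometry import DegenerateGeometryError, Ellipse2D, fit_ellipse_2d

__all__ = [
    "SegmentationCandidate",
    "FilterRules",
    "SnakeParams",
    "TrackSelection",
    "EmptyResultError",
    "SeedError",
    "ConvergenceError",
    "segment_chromosomes",
    "segment_spindle_threshold",
    "segment_spindle_snake",
    "conditional_filter",
    "track_centroids",
]


class EmptyResultError(RuntimeError):
    """Segmentation produced no foreground object."""


class SeedError(ValueError):
    """Active contour requires a non-empty chromosome seed mask."""


class ConvergenceError(RuntimeError):
    """Active contour collapsed instead of propagating outward."""


@dataclass
class SegmentationCandidate:
    """A candidate object mask with score and tight bounding box.

    bbox is (x_min, y_min, x_max, y_max) inclusive, x = column, y = row.
    Classical pipelines emit score 1.0 so the conditional filter treats scored
    (detector-derived) and unscored (classical) masks uniformly.
    """

    mask: np.ndarray
    score: float
    bbox: tuple[int, int, int, int]
    class_name: str
    area_px: int

    @classmethod
    def from_mask(cls, mask: np.ndarray, class_name: str, score: float = 1.0) -> "SegmentationCandidate":
        mask = np.asarray(mask).astype(bool)
        rows, cols = np.nonzero(mask)
        if rows.size == 0:
            raise EmptyResultError("cannot build a candidate from an empty mask")
        bbox = (int(cols.min()), int(rows.min()), int(cols.max()), int(rows.max()))
        return cls(mask=mask, score=float(score), bbox=bbox, class_name=class_name, area_px=int(rows.size))

    @property
    def centroid(self) -> tuple[float, float]:
        """Bounding-box centroid (x, y)."""
        x0, y0, x1, y1 = self.bbox
        return ((x0 + x1) / 2.0, (y0 + y1) / 2.0)


@dataclass(frozen=True)
class FilterRules:
    """Stage-3 conditional filtering thresholds."""

    min_score: float = 0.90
    min_area_px: int = 64
    max_area_px: int = 1_000_000
    border_margin_px: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.min_score <= 1:
            raise ValueError("min_score must lie in [0, 1]")
        if self.min_area_px >= self.max_area_px:
            raise ValueError("min_area_px must be < max_area_px")
        if self.border_margin_px < 0:
            raise ValueError("border margin must be >= 0")


@dataclass(frozen=True)
class SnakeParams:
    """Outward geodesic active contour parameters.

    smoothing plays the contour-rigidity role; balloon > 0 is the outward
    propagation force realizing the "inverse snake"; gaussian_sigma smooths
    the image before the gradient is taken.
    """

    smoothing: int = 1
    balloon: float = 1.0
    iterations: int = 200
    gaussian_sigma: float = 2.0


def _smooth_closed_boundary(contour_rc: np.ndarray, window: int, order: int) -> np.ndarray:
    """Savitzky-Golay smooth a closed boundary as two periodic 1D signals."""
    n = len(contour_rc)
    window = min(window, n if n % 2 == 1 else n - 1)
    if window <= order:
        return contour_rc
    r = savgol_filter(contour_rc[:, 0], window, order, mode="wrap")
    c = savgol_filter(contour_rc[:, 1], window, order, mode="wrap")
    return np.column_stack([r, c])


def _longest_contour(mask: np.ndarray) -> np.ndarray:
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise EmptyResultError("no boundary contour found")
    return max(contours, key=len)


def _fill_contour(contour_rc: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    rr, cc = draw.polygon(contour_rc[:, 0], contour_rc[:, 1], shape=shape)
    out = np.zeros(shape, dtype=bool)
    out[rr, cc] = True
    return out


def _contour_xy(contour_rc: np.ndarray) -> np.ndarray:
    return contour_rc[:, ::-1]  # (row, col) -> (x, y)


def segment_chromosomes(
    image: np.ndarray,
    median_size: int = 3,
    savgol_window: int = 15,
    savgol_order: int = 3,
) -> SegmentationCandidate:
    """Segment the metaphase chromosome plate.

    Median filter -> Otsu two-class threshold -> remove 8-connected components
    touching the image border -> extract the boundary -> Savitzky-Golay smooth
    -> refill. The largest surviving component is returned with score 1.0.

    Raises
    ------
    EmptyResultError
        If thresholding or border clearing leaves no foreground.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2D image")
    if savgol_order >= savgol_window:
        raise ValueError("savgol_order must be < savgol_window")
    filtered = median_filter(img, size=median_size)
    if np.ptp(filtered) == 0:
        raise EmptyResultError("constant image: Otsu threshold undefined")
    binary = filtered > threshold_otsu(filtered)
    if not binary.any():
        raise EmptyResultError("all background after Otsu thresholding")
    labels = measure.label(binary, connectivity=2)  # 8-connected neighborhood
    cleared = segmentation.clear_border(labels)
    if not cleared.any():
        raise EmptyResultError("all components touch the image border")
    sizes = np.bincount(cleared.ravel())
    sizes[0] = 0
    keep = cleared == int(np.argmax(sizes))
    contour = _smooth_closed_boundary(_longest_contour(keep), savgol_window, savgol_order)
    mask = _fill_contour(contour, img.shape)
    if not mask.any():
        raise EmptyResultError("smoothing removed the object")
    return SegmentationCandidate.from_mask(mask, "chromosome")


def segment_spindle_threshold(
    image: np.ndarray,
    median_size: tuple[int, int] = (20, 20),
    adaptive_block_px: int = 51,
    savgol_window: int = 15,
    savgol_order: int = 3,
) -> tuple[SegmentationCandidate, Ellipse2D]:
    """Segment a dye-labeled spindle by adaptive thresholding + convex hull.

    Median filter -> local-mean adaptive threshold -> 3x3-disc dilation then
    erosion -> convex hull of all retained foreground (joining the two
    half-spindles) -> boundary -> Savitzky-Golay smooth -> least-squares
    ellipse fit. Returns the hull candidate and the fitted ellipse.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2D image")
    if adaptive_block_px % 2 == 0:
        raise ValueError("adaptive_block_px must be odd")
    filtered = median_filter(img, size=median_size)
    thresh = threshold_local(filtered, block_size=adaptive_block_px, method="mean")
    # tolerance guards against float error of the mean filter on flat regions
    tol = 1e-9 * max(1.0, float(np.abs(filtered).max()))
    binary = (filtered - thresh) > tol
    selem = morphology.disk(1)  # 3x3 disc
    binary = morphology.erosion(morphology.dilation(binary, selem), selem)
    if not binary.any():
        raise DegenerateGeometryError("no foreground after adaptive thresholding")
    hull = morphology.convex_hull_image(binary)
    contour = _smooth_closed_boundary(_longest_contour(hull), savgol_window, savgol_order)
    if len(contour) < 5:
        raise DegenerateGeometryError("fewer than 5 boundary points for ellipse fit")
    ellipse = fit_ellipse_2d(_contour_xy(contour))
    mask = _fill_contour(contour, img.shape)
    return SegmentationCandidate.from_mask(mask, "spindle"), ellipse


def segment_spindle_snake(
    image: np.ndarray,
    chromosome_mask: np.ndarray,
    snake_params: SnakeParams = SnakeParams(),
    savgol_window: int = 15,
    savgol_order: int = 3,
) -> tuple[SegmentationCandidate, Ellipse2D]:
    """Segment a tubulin spindle with an outward active contour.

    Gaussian filter -> image gradient magnitude (as an inverse-gradient speed
    image) -> geodesic active contour initialized on the chromosome-mask
    boundary and propagated outward by a positive balloon force (the inverse
    snake, moving from the spindle center toward its outer boundary) ->
    boundary -> ellipse fit.

    Raises
    ------
    SeedError
        If the chromosome seed mask is empty.
    ConvergenceError
        If the contour collapses below the seed area.
    """
    img = np.asarray(image, dtype=float)
    seed = np.asarray(chromosome_mask).astype(bool)
    if img.shape != seed.shape:
        raise ValueError("image and seed mask shapes differ")
    if not seed.any():
        raise SeedError("empty chromosome seed mask")
    speed = inverse_gaussian_gradient(gaussian(img, sigma=snake_params.gaussian_sigma))
    evolved = morphological_geodesic_active_contour(
        speed,
        num_iter=snake_params.iterations,
        init_level_set=seed,
        smoothing=snake_params.smoothing,
        balloon=snake_params.balloon,
    ).astype(bool)
    if evolved.sum() < seed.sum():
        raise ConvergenceError(
            f"contour collapsed: area {int(evolved.sum())} below seed area {int(seed.sum())}"
        )
    contour = _smooth_closed_boundary(_longest_contour(evolved), savgol_window, savgol_order)
    if len(contour) < 5:
        raise DegenerateGeometryError("fewer than 5 boundary points for ellipse fit")
    ellipse = fit_ellipse_2d(_contour_xy(contour))
    mask = _fill_contour(contour, img.shape)
    return SegmentationCandidate.from_mask(mask, "spindle"), ellipse


def conditional_filter(
    candidates: list, rules: FilterRules, canvas: tuple[int, int]
) -> list:
    """Retain candidates satisfying score, area and border-location rules.

    A candidate passes when score >= min_score, min_area <= area <= max_area,
    and its bounding box lies at least border_margin_px inside every canvas
    edge. Order is preserved; the filter is idempotent.
    """
    rows, cols = canvas
    kept = []
    for cand in candidates:
        x0, y0, x1, y1 = cand.bbox
        if cand.score < rules.min_score:
            continue
        if not rules.min_area_px <= cand.area_px <= rules.max_area_px:
            continue
        if x0 < rules.border_margin_px or y0 < rules.border_margin_px:
            continue
        if x1 > cols - 1 - rules.border_margin_px or y1 > rows - 1 - rules.border_margin_px:
            continue
        kept.append(cand)
    return kept


@dataclass
class TrackSelection:
    """Per-frame tracker output; candidate is None on gap frames."""

    frame: int
    candidate_index: int | None
    candidate: SegmentationCandidate | None
    gap: bool
    centroid: tuple[float, float]


def track_centroids(candidates_per_frame: list) -> list[TrackSelection]:
    """Follow one object through time by bounding-box centroid proximity.

    Frame 0 selects the highest-score candidate (ties: lowest index); each
    later frame selects the candidate whose bbox centroid is nearest in
    Euclidean distance to the previous selection (ties: higher score, then
    lower index). Frames with no candidates yield a gap entry and the previous
    centroid is carried forward for matching.

    Raises
    ------
    ValueError
        If frame 0 has no candidates.
    """
    if not candidates_per_frame or not candidates_per_frame[0]:
        raise ValueError("tracking initialization requires >= 1 candidate at frame 0")
    selections: list[TrackSelection] = []
    first = candidates_per_frame[0]
    idx0 = max(range(len(first)), key=lambda i: (first[i].score, -i))
    prev_centroid = first[idx0].centroid
    selections.append(TrackSelection(0, idx0, first[idx0], False, prev_centroid))
    for t, cands in enumerate(candidates_per_frame[1:], start=1):
        if not cands:
            selections.append(TrackSelection(t, None, None, True, prev_centroid))
            continue
        px, py = prev_centroid
        best = min(
            range(len(cands)),
            key=lambda i: (
                (cands[i].centroid[0] - px) ** 2 + (cands[i].centroid[1] - py) ** 2,
                -cands[i].score,
                i,
            ),
        )
        prev_centroid = cands[best].centroid
        selections.append(TrackSelection(t, best, cands[best], False, prev_centroid))
    return selections
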