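"""Classical annotation pipelines, conditional filtering and centroid tracking."""

import numpy as np
import pytest

from conftest import render_ellipse
from spindlekit.geometry import DegenerateGeometryError
from spindlekit.evaluation import perpendicularity
from spindlekit.segmentation import (
    EmptyResultError,
    FilterRules,
    SeedError,
    SegmentationCandidate,
    SnakeParams,
    conditional_filter,
    segment_chromosomes,
    segment_spindle_snake,
    segment_spindle_threshold,
    track_centroids,
)


def rect_image(shape=(100, 100), origin=(30, 44), size=(40, 12), fg=200.0, bg=10.0):
    img = np.full(shape, bg)
    r0, c0 = origin
    h, w = size
    img[r0 : r0 + h, c0 : c0 + w] = fg
    return img


class TestSegmentChromosomes:
    def test_centered_rectangle_recovered_within_one_pixel(self):
        img = rect_image()
        cand = segment_chromosomes(img)
        truth = rect_image(fg=1.0, bg=0.0) > 0.5
        interior = truth.copy()
        interior[1:-1, 1:-1] &= truth[:-2, 1:-1] & truth[2:, 1:-1] & truth[1:-1, :-2] & truth[1:-1, 2:]
        interior[0, :] = interior[-1, :] = interior[:, 0] = interior[:, -1] = False
        from scipy.ndimage import binary_dilation

        assert (cand.mask & ~binary_dilation(truth)).sum() == 0  # within 1-px dilation
        assert (interior & ~cand.mask).sum() == 0  # contains the strict interior

    def test_object_touching_border_gives_empty_result(self):
        img = rect_image(origin=(0, 44))
        with pytest.raises(EmptyResultError):
            segment_chromosomes(img)

    def test_border_blob_cleared_interior_blob_kept(self):
        img = np.full((100, 100), 10.0)
        img[0:20, 0:20] = 200.0  # touches border
        img[50:70, 50:70] = 200.0  # interior
        cand = segment_chromosomes(img)
        assert cand.mask[60, 60]
        assert not cand.mask[5, 5]
        assert cand.area_px == cand.mask.sum()
        x0, y0, x1, y1 = cand.bbox
        rows, cols = np.nonzero(cand.mask)
        assert (x0, y0, x1, y1) == (cols.min(), rows.min(), cols.max(), rows.max())

    def test_level_shift_invariance(self):
        img = rect_image()
        a = segment_chromosomes(img)
        b = segment_chromosomes(img + 37.0)
        assert np.array_equal(a.mask, b.mask)


class TestSegmentSpindleThreshold:
    def test_two_half_spindles_joined_by_hull(self):
        img = np.full((100, 100), 10.0)
        yy, xx = np.mgrid[0:100, 0:100]
        blob1 = (xx - 30) ** 2 + (yy - 50) ** 2 <= 81
        blob2 = (xx - 70) ** 2 + (yy - 50) ** 2 <= 81
        img[blob1 | blob2] = 200.0
        cand, _ = segment_spindle_threshold(img, median_size=(5, 5))
        assert (cand.mask & blob1).sum() > 0.9 * blob1.sum()
        assert (cand.mask & blob2).sum() > 0.9 * blob2.sum()
        assert cand.mask[50, 50]  # hull joins the gap between the halves

    def test_solid_ellipse_axes_recovered_within_ten_percent(self):
        img, _ = render_ellipse(shape=(120, 120), center=(60, 60), semi_axes=(20, 8))
        _, ellipse = segment_spindle_threshold(img, median_size=(5, 5))
        assert ellipse.semi_axes[0] == pytest.approx(20, rel=0.10)
        assert ellipse.semi_axes[1] == pytest.approx(8, rel=0.10)

    def test_blank_image_degenerate(self):
        with pytest.raises(DegenerateGeometryError):
            segment_spindle_threshold(np.full((80, 80), 7.0), median_size=(5, 5))

    def test_level_shift_invariance(self):
        img, _ = render_ellipse(shape=(120, 120), semi_axes=(20, 8))
        a, _ = segment_spindle_threshold(img, median_size=(5, 5))
        b, _ = segment_spindle_threshold(img + 11.0, median_size=(5, 5))
        assert np.array_equal(a.mask, b.mask)


class TestSegmentSpindleSnake:
    @staticmethod
    def blurred_spindle(angle_deg=0.0):
        from scipy.ndimage import gaussian_filter

        img, inside = render_ellipse(
            shape=(140, 140), center=(70, 70), semi_axes=(25, 10), angle_deg=angle_deg, fg=200.0, bg=10.0
        )
        return gaussian_filter(img, 2.0), inside

    def test_contour_grows_from_central_seed(self):
        img, _ = self.blurred_spindle()
        seed = np.zeros_like(img, dtype=bool)
        seed[65:76, 65:76] = True
        cand, _ = segment_spindle_snake(img, seed, SnakeParams(iterations=120))
        assert cand.area_px >= seed.sum()

    def test_orientation_recovered_within_five_degrees(self):
        img, _ = self.blurred_spindle(angle_deg=25.0)
        seed = np.zeros_like(img, dtype=bool)
        seed[65:76, 65:76] = True
        _, ellipse = segment_spindle_snake(img, seed, SnakeParams(iterations=120))
        assert abs(ellipse.angle_deg - 25.0) < 5.0

    def test_empty_seed_raises(self):
        img, _ = self.blurred_spindle()
        with pytest.raises(SeedError):
            segment_spindle_snake(img, np.zeros_like(img, dtype=bool))


def make_candidate(shape, slc, score):
    mask = np.zeros(shape, bool)
    mask[slc] = True
    return SegmentationCandidate.from_mask(mask, "spindle", score=score)


class TestConditionalFilter:
    CANVAS = (100, 100)

    def test_score_below_detection_threshold_discarded(self):
        cand = make_candidate(self.CANVAS, np.s_[40:60, 40:60], 0.85)
        rules = FilterRules(min_score=0.90, min_area_px=10, max_area_px=10_000)
        assert conditional_filter([cand], rules, self.CANVAS) == []

    def test_empty_input_gives_empty_output(self):
        rules = FilterRules()
        assert conditional_filter([], rules, self.CANVAS) == []

    def test_enumerated_rule_outcomes(self):
        rules = FilterRules(min_score=0.5, min_area_px=50, max_area_px=5000, border_margin_px=5)
        small = make_candidate(self.CANVAS, np.s_[40:45, 40:45], 0.9)  # 25 px < 50
        at_border = make_candidate(self.CANVAS, np.s_[0:20, 40:60], 0.9)
        valid = make_candidate(self.CANVAS, np.s_[30:50, 30:50], 0.9)
        kept = conditional_filter([small, at_border, valid], rules, self.CANVAS)
        assert kept == [valid]

    def test_idempotence(self):
        rules = FilterRules(min_score=0.5, min_area_px=50, max_area_px=5000, border_margin_px=5)
        cands = [
            make_candidate(self.CANVAS, np.s_[30:50, 30:50], 0.9),
            make_candidate(self.CANVAS, np.s_[0:20, 40:60], 0.9),
            make_candidate(self.CANVAS, np.s_[60:90, 60:90], 0.4),
        ]
        once = conditional_filter(cands, rules, self.CANVAS)
        twice = conditional_filter(once, rules, self.CANVAS)
        assert once == twice

    def test_order_preserved(self):
        rules = FilterRules(min_score=0.5, min_area_px=10, max_area_px=5000)
        a = make_candidate(self.CANVAS, np.s_[10:30, 10:30], 0.7)
        b = make_candidate(self.CANVAS, np.s_[50:70, 50:70], 0.95)
        assert conditional_filter([a, b], rules, self.CANVAS) == [a, b]


class TestTrackCentroids:
    def test_single_candidate_followed(self):
        per_frame = [[make_candidate((50, 50), np.s_[20:30, 20:30], 1.0)] for _ in range(5)]
        sel = track_centroids(per_frame)
        assert all(s.candidate_index == 0 and not s.gap for s in sel)

    def test_stationary_pair_keeps_initial_selection(self):
        def frame():
            a = make_candidate((60, 80), np.s_[10:20, 10:20], 0.8)
            b = make_candidate((60, 80), np.s_[40:50, 60:70], 0.95)
            return [a, b]

        sel = track_centroids([frame() for _ in range(6)])
        assert sel[0].candidate_index == 1  # highest score at t=0
        assert all(s.candidate_index == 1 for s in sel)

    def test_moving_object_followed_among_distractors(self):
        frames = []
        for t in range(8):
            moving = make_candidate((100, 200), np.s_[45:55, 5 + 5 * t : 15 + 5 * t], 1.0)
            d1 = make_candidate((100, 200), np.s_[5:15, 150:160], 1.0)
            d2 = make_candidate((100, 200), np.s_[85:95, 100:110], 1.0)
            frames.append([d1, moving, d2])
        # force selection of the moving object at t=0 by score
        frames[0] = [
            make_candidate((100, 200), np.s_[5:15, 150:160], 0.5),
            make_candidate((100, 200), np.s_[45:55, 5:15], 1.0),
            make_candidate((100, 200), np.s_[85:95, 100:110], 0.5),
        ]
        sel = track_centroids(frames)
        assert all(s.candidate_index == 1 for s in sel)

    def test_gap_frames_carry_centroid(self):
        a = make_candidate((50, 50), np.s_[20:30, 20:30], 1.0)
        sel = track_centroids([[a], [], [a]])
        assert sel[1].gap and sel[1].candidate is None
        assert sel[1].centroid == sel[0].centroid
        assert sel[2].candidate_index == 0

    def test_empty_first_frame_rejected(self):
        with pytest.raises(ValueError):
            track_centroids([[], [make_candidate((50, 50), np.s_[20:30, 20:30], 1.0)]])


class TestPerpendicularityOfRenderedScene:
    def test_spindle_and_plate_fits_are_orthogonal(self):
        """A metaphase scene: spindle ellipse along one direction, chromosome
        plate perpendicular; the fitted major axes must be 90 +/- 5 deg apart."""
        from scipy.ndimage import gaussian_filter

        angle = 20.0
        spindle_img, _ = render_ellipse(shape=(160, 160), center=(80, 80), semi_axes=(35, 14), angle_deg=angle)
        plate_img, _ = render_ellipse(shape=(160, 160), center=(80, 80), semi_axes=(16, 5), angle_deg=angle + 90.0)
        _, sp_ell = segment_spindle_threshold(gaussian_filter(spindle_img, 1.0), median_size=(5, 5))
        ch = segment_chromosomes(gaussian_filter(plate_img, 1.0))
        from spindlekit.geometry import fit_ellipse_2d
        from skimage import measure

        contour = max(measure.find_contours(ch.mask.astype(float), 0.5), key=len)
        ch_ell = fit_ellipse_2d(contour[:, ::-1])
        phi, _ = perpendicularity(sp_ell, ch_ell)
        assert phi == pytest.approx(90.0, abs=5.0)
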