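"""Pole refinement and six-point identity tracking."""

import numpy as np
import pytest

from spindlekit.geometry import Ellipsoid3D, SpindleAxes, principal_axes_endpoints
from spindlekit.io import Calibration
from spindlekit.kinematics import rot_z, compose_euler
from spindlekit.reference import best_axis_labelings
from spindlekit.tracking import (
    RefinementError,
    assign_identities,
    refine_poles,
    track_movie,
)

CAL1 = Calibration(pixel_size_um=1.0, z_step_um=1.0, dt_min=1.0)


def ellipse_mask(shape=(50, 60), x_range=(10, 40), y_center=25, semi_minor=6):
    """Filled ellipse mask spanning x in [x0, x1] at the given row."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    x0, x1 = x_range
    cx, a = (x0 + x1) / 2.0, (x1 - x0) / 2.0
    return ((xx - cx) / a) ** 2 + ((yy - y_center) / semi_minor) ** 2 <= 1.0


def spindle_axes(centroid, R, half=(5.0, 2.0, 1.0)):
    c = np.asarray(centroid, float)
    u1, u2, u3 = (np.asarray(R, float)[:, k] for k in range(3))
    return SpindleAxes(
        pole1=c - half[0] * u1, pole2=c + half[0] * u1,
        width1=c - half[1] * u2, width2=c + half[1] * u2,
        height1=c - half[2] * u3, height2=c + half[2] * u3,
        centroid=c,
    )


DUMMY_ELL = Ellipsoid3D(np.array([25.0, 25.0, 0.0]), (15.0, 6.0, 1.0), np.eye(3))


class TestRefinePoles:
    def test_overshooting_poles_snap_to_mask_boundary(self):
        mask = ellipse_mask()
        p1, p2 = refine_poles(mask, (np.array([5.0, 25, 0]), np.array([45.0, 25, 0])), DUMMY_ELL, CAL1)
        assert np.allclose(p1, [10, 25, 0])
        assert np.allclose(p2, [40, 25, 0])

    def test_poles_on_boundary_unchanged(self):
        mask = ellipse_mask()
        p1, p2 = refine_poles(mask, (np.array([10.0, 25, 0]), np.array([40.0, 25, 0])), DUMMY_ELL, CAL1)
        assert np.allclose(p1, [10, 25, 0])
        assert np.allclose(p2, [40, 25, 0])

    def test_scan_missing_mask_raises(self):
        mask = ellipse_mask()
        with pytest.raises(RefinementError):
            refine_poles(mask, (np.array([5.0, 45, 0]), np.array([45.0, 45, 0])), DUMMY_ELL, CAL1)

    @pytest.mark.parametrize("overshoot", [2, 4, 6, 8, 10])
    def test_refined_length_never_exceeds_original(self, overshoot):
        mask = ellipse_mask()
        p1 = np.array([10.0 - overshoot, 25, 0])
        p2 = np.array([40.0 + overshoot, 25, 0])
        r1, r2 = refine_poles(mask, (p1, p2), DUMMY_ELL, CAL1)
        assert np.allclose(r1, [10, 25, 0]) and np.allclose(r2, [40, 25, 0])
        assert np.linalg.norm(r2 - r1) <= np.linalg.norm(p2 - p1)

    def test_z_interpolated_along_scan(self):
        mask = ellipse_mask()
        p1 = np.array([5.0, 25, 2.0])
        p2 = np.array([45.0, 25, 4.0])
        r1, r2 = refine_poles(mask, (p1, p2), DUMMY_ELL, CAL1)
        # z at the hit parameter t = (10-5)/40 and (40-5)/40
        assert r1[2] == pytest.approx(2.0 + 2.0 * (10 - 5) / 40.0, abs=0.05)
        assert r2[2] == pytest.approx(2.0 + 2.0 * (40 - 5) / 40.0, abs=0.05)


class TestAssignIdentities:
    def test_stationary_spindle_no_corrections(self):
        a = spindle_axes((0, 0, 0), np.eye(3))
        out, corr = assign_identities(a, a)
        assert not any(corr.values())
        assert np.allclose(out.pole1, a.pole1)

    def test_exact_label_swap_corrected(self):
        prev = spindle_axes((0, 0, 0), np.eye(3))
        swapped = prev.replace(pole1=prev.pole2, pole2=prev.pole1)
        out, corr = assign_identities(swapped, prev)
        assert corr["length"] and not corr["width"] and not corr["height"]
        assert np.allclose(out.pole1, prev.pole1)

    def test_rotation_matches_exhaustive_minimization(self):
        rng = np.random.default_rng(17)
        prev = spindle_axes((0, 0, 0), np.eye(3))
        cur_r = spindle_axes((0, 0, 0), rot_z(30.0))
        for flip in (False, True):
            cur = cur_r.replace(pole1=cur_r.pole2, pole2=cur_r.pole1) if flip else cur_r
            out, corr = assign_identities(cur, prev)
            for axis, (n1, n2) in {
                "length": ("pole1", "pole2"), "width": ("width1", "width2"), "height": ("height1", "height2"),
            }.items():
                c1, c2 = getattr(cur, n1), getattr(cur, n2)
                p1, p2 = getattr(prev, n1), getattr(prev, n2)
                keep = np.linalg.norm(c1 - p1) + np.linalg.norm(c2 - p2)
                swap = np.linalg.norm(c1 - p2) + np.linalg.norm(c2 - p1)
                assert corr[axis] == (swap < keep)

    def test_symmetric_tie_keeps_previous_labels(self):
        prev = spindle_axes((0, 0, 0), np.eye(3))
        # rotate 90 deg about z: both length labelings cost the same
        cur = spindle_axes((0, 0, 0), rot_z(90.0), half=(5.0, 5.0, 1.0))
        _, corr = assign_identities(cur, prev)
        assert not corr["length"]


def frames_to_per_frame(frames_axes, cortex):
    """Wrap pre-built axes as track_movie input via exact enclosing ellipsoids."""
    per = []
    for ax in frames_axes:
        tri = ax.triad()
        semi = (
            np.linalg.norm(ax.pole2 - ax.pole1) / 2,
            np.linalg.norm(ax.width2 - ax.width1) / 2,
            np.linalg.norm(ax.height2 - ax.height1) / 2,
        )
        if np.linalg.det(tri) < 0:
            tri = tri.copy()
            tri[:, 2] = -tri[:, 2]
        ell = Ellipsoid3D(ax.centroid, semi, tri)
        per.append((ell, None, cortex))
    return per


BIG_CORTEX = Ellipsoid3D(np.zeros(3), (50.0, 50.0, 50.0), np.eye(3))


class TestTrackMovie:
    def test_static_movie_zero_corrections(self):
        frames = [spindle_axes((0, 0, 0), np.eye(3))] * 21
        track = track_movie(frames_to_per_frame(frames, BIG_CORTEX), CAL1, refine=False)
        assert track.n_accepted == 21
        assert sum(track.n_corrections.values()) == 0

    def test_injected_swap_detected_once(self):
        rng = np.random.default_rng(3)
        frames = []
        for t in range(21):
            ax = spindle_axes((0.05 * t, 0.02 * t, 0.0), rot_z(2.0 * t))
            frames.append(ax)
        # inject a label swap at frame 10 on the length axis
        frames[10:] = [f.replace(pole1=f.pole2, pole2=f.pole1) for f in frames[10:]]
        track = track_movie(frames_to_per_frame(frames, BIG_CORTEX), CAL1, refine=False)
        length_flags = [track.corrections[i]["length"] for i in range(21)]
        assert length_flags[10] and sum(length_flags) == 1
        # identity restored: pole1 moves smoothly across the swap
        jump = np.linalg.norm(track.frames[10].pole1 - track.frames[9].pole1)
        assert jump < 1.0

    def test_matches_exhaustive_minimal_labeling(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            T = 8
            frames = []
            for t in range(T):
                R = compose_euler(rng.uniform(-10, 10), rng.uniform(-10, 10), 20.0 * t)
                frames.append(spindle_axes(rng.normal(scale=0.1, size=3), R))
            # scramble labels randomly per frame
            scrambled = []
            for f in frames:
                if rng.random() < 0.5:
                    f = f.replace(pole1=f.pole2, pole2=f.pole1)
                scrambled.append(f)
            track = track_movie(frames_to_per_frame(scrambled, BIG_CORTEX), CAL1, refine=False)
            series = np.array([[s.pole1, s.pole2] for s in scrambled])
            pattern, best_cost = best_axis_labelings(series)
            got = 0.0
            for prev, cur in zip(track.frames[:-1], track.frames[1:]):
                got += np.linalg.norm(cur.pole1 - prev.pole1) + np.linalg.norm(cur.pole2 - prev.pole2)
            assert got == pytest.approx(best_cost, abs=1e-9)

    def test_rigid_transform_invariance(self):
        rng = np.random.default_rng(5)
        frames = [spindle_axes((0.1 * t, 0, 0), rot_z(3.0 * t)) for t in range(8)]
        t1 = track_movie(frames_to_per_frame(frames, BIG_CORTEX), CAL1, refine=False)
        Q = compose_euler(10.0, 20.0, 30.0)
        shift = np.array([3.0, -2.0, 1.0])

        def xf(ax):
            f = {
                n: Q @ getattr(ax, n) + shift
                for n in ("pole1", "pole2", "width1", "width2", "height1", "height2", "centroid")
            }
            return SpindleAxes(**f)

        moved_cortex = Ellipsoid3D(Q @ BIG_CORTEX.center + shift, BIG_CORTEX.semi_axes, Q)
        t2 = track_movie(frames_to_per_frame([xf(f) for f in frames], moved_cortex), CAL1, refine=False)
        assert t1.n_corrections == t2.n_corrections
        d1 = np.array([d for d in t1.distances])
        d2 = np.array([d for d in t2.distances])
        assert np.allclose(d1, d2, atol=1e-6)

    def test_pole_outside_cortex_excluded_and_logged(self):
        small_cortex = Ellipsoid3D(np.zeros(3), (6.0, 6.0, 6.0), np.eye(3))
        good = spindle_axes((0, 0, 0), np.eye(3))
        bad = spindle_axes((3.0, 0, 0), np.eye(3))  # pole2 at x=8 outside r=6
        track = track_movie(frames_to_per_frame([good, bad, good], small_cortex), CAL1, refine=False)
        assert track.n_accepted == 2
        assert track.frames[1] is None
        assert track.excluded_frames[0][0] == 1
        assert "pole" in track.excluded_frames[0][1]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            track_movie([], CAL1)
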