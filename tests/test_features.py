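"""Gait-feature extractors against geometric and counting oracles."""

import numpy as np
import pytest

from cowgait.features import (
    back_curvature,
    circumcircle_curvature,
    extract_all,
    lateral_sway_amplitude,
    movement_asymmetry_index,
    split_left_right,
    trunk_inclination,
    vertical_oscillation_back,
    vertical_oscillation_head,
)


def circumradius_by_bisectors(p1, p2, p3):
    """Independent oracle: circumcentre via perpendicular-bisector
    intersection, solved as a 2x2 linear system."""
    p1, p2, p3 = (np.asarray(p, float) for p in (p1, p2, p3))
    a = np.array([p2 - p1, p3 - p1])
    b = 0.5 * np.array(
        [p2 @ p2 - p1 @ p1, p3 @ p3 - p1 @ p1]
    )
    centre = np.linalg.solve(a, b)
    return np.linalg.norm(p1 - centre)


class TestCircumcircle:
    def test_points_on_known_circle(self):
        ang = np.array([0.3, 1.9, 4.0])
        pts = 50.0 * np.stack([np.cos(ang), np.sin(ang)], axis=1)
        assert circumcircle_curvature(*pts) == pytest.approx(0.02, abs=1e-12)

    def test_collinear_gives_zero(self):
        assert circumcircle_curvature((0, 0), (60, 0), (120, 0)) == 0.0

    def test_coincident_rejected(self):
        with pytest.raises(ValueError):
            circumcircle_curvature((1, 1), (1, 1), (3, 4))

    def test_matches_bisector_oracle_on_random_triangles(self, rng):
        for _ in range(300):
            pts = rng.uniform(-100, 100, size=(3, 2))
            k = circumcircle_curvature(*pts)
            if k == 0.0:
                continue
            assert k == pytest.approx(1.0 / circumradius_by_bisectors(*pts), abs=1e-9)


class TestBackCurvature:
    def test_flat_back_zero(self, make_seq):
        seq = make_seq({"withers": 1800, "lumbar": 1800, "sacral_tuber": 1800})
        assert back_curvature(seq) == 0.0

    def test_arch_recovers_target(self, make_seq):
        from cowgait.simulate import arch_sag_for_curvature

        k = 0.0008
        # spine spans 60 px at 1 cm/px: chord 60 cm
        sag_cm = arch_sag_for_curvature(k, 60.0)
        seq = make_seq(
            {
                "withers": 1800,
                "lumbar": 1800 - 10 * sag_cm,
                "sacral_tuber": 1800,
            }
        )
        assert back_curvature(seq) == pytest.approx(k, abs=1e-9)

    def test_max_over_frames_semantics(self, make_seq):
        T = 7
        lumbar = np.full(T, 1800.0)
        lumbar[5] = 1780.0  # arch only in frame 5
        seq = make_seq({"withers": 1800, "lumbar": lumbar, "sacral_tuber": 1800}, T=T)
        frame5 = circumcircle_curvature((0, 140), (30, 142), (60, 140))
        assert back_curvature(seq) == pytest.approx(frame5, abs=1e-12)


class TestSplitLeftRight:
    def test_symmetric_disk_halves(self):
        ys, xs = np.mgrid[0:41, 0:41]
        disk = (ys - 20) ** 2 + (xs - 20) ** 2 <= 15**2
        left, right = split_left_right(disk, (20, 5), (20, 35))
        assert abs(int(left.sum()) - int(right.sum())) <= 41

    def test_rotated_axis_swaps_membership(self, rng):
        mask = rng.random((30, 30)) < 0.5
        l1, r1 = split_left_right(mask, (15, 5), (15, 25))
        l2, r2 = split_left_right(mask, (15, 25), (15, 5))
        # strictly-right pixels become strictly-left under axis reversal
        assert (r1 & ~l2).sum() == 0
        assert (r2 & ~l1).sum() == 0

    def test_signed_distance_oracle(self, rng):
        mask = rng.random((25, 20)) < 0.6
        p1, p2 = np.array([3.0, 4.0]), np.array([17.0, 21.0])
        left, right = split_left_right(mask, p1, p2)
        axis = p2 - p1
        for y in range(25):
            for x in range(20):
                if not mask[y, x]:
                    assert not left[y, x] and not right[y, x]
                    continue
                cross = axis[0] * (y - p1[1]) - axis[1] * (x - p1[0])
                assert left[y, x] == (cross >= 0)

    def test_degenerate_axis_rejected(self):
        with pytest.raises(ValueError):
            split_left_right(np.ones((5, 5), bool), (2, 2), (2, 2))


class TestMAI:
    def _regions(self, H=10, W=10):
        left = np.zeros((H, W), bool)
        right = np.zeros((H, W), bool)
        left[:, : W // 2] = True
        right[:, W // 2 :] = True
        return left, right

    def test_symmetric_motion_zero(self):
        flow = np.full((2, 10, 10), 1.3)
        assert movement_asymmetry_index(flow[None], [self._regions()]) == 0.0

    def test_three_to_one_ratio(self):
        left, right = self._regions()
        flow = np.zeros((2, 10, 10))
        flow[0][left] = 3.0
        flow[0][right] = 1.0
        assert movement_asymmetry_index(flow[None], [(left, right)]) == pytest.approx(0.5)

    def test_bounded_on_random_flows(self, rng):
        left, right = self._regions()
        for _ in range(200):
            flow = rng.normal(size=(1, 2, 10, 10))
            mai = movement_asymmetry_index(flow, [(left, right)])
            assert 0.0 <= mai <= 1.0

    def test_no_motion_gives_zero(self):
        flow = np.zeros((1, 2, 10, 10))
        assert movement_asymmetry_index(flow, [self._regions()]) == 0.0

    def test_empty_region_rejected(self):
        flow = np.ones((1, 2, 10, 10))
        left = np.ones((10, 10), bool)
        with pytest.raises(ValueError):
            movement_asymmetry_index(flow, [(left, np.zeros((10, 10), bool))])

    def test_translating_texture_recovered_by_flow(self, rng):
        # left half translates 2 px/frame, right half 1 px/frame:
        # analytic MAI = (2-1)/(2+1) = 1/3
        from cowgait.features import flow_fields

        H, W, T = 96, 64, 6
        noise = rng.normal(size=(H, W))
        F = np.fft.fft2(noise)
        ky = np.fft.fftfreq(H)[:, None]
        kx = np.fft.fftfreq(W)[None, :]
        F *= np.exp(-(np.hypot(ky, kx) / 0.06) ** 2)
        tex = np.real(np.fft.ifft2(F))
        tex = (tex - tex.min()) / (tex.max() - tex.min())

        def scroll(img, s):
            ph = np.exp(-2j * np.pi * np.fft.fftfreq(H)[:, None] * s)
            return np.real(np.fft.ifft(np.fft.fft(img, axis=0) * ph, axis=0))

        frames = np.stack(
            [
                np.where(
                    np.arange(W)[None, :] < W // 2, scroll(tex, 2.0 * t), scroll(tex, 1.0 * t)
                )
                for t in range(T)
            ]
        )
        flows = flow_fields(frames)
        left = np.zeros((H, W), bool)
        left[:, : W // 2] = True
        mai = movement_asymmetry_index(flows, [(left, ~left)] * (T - 1))
        assert mai == pytest.approx(1 / 3, rel=0.3)


class TestOscillations:
    def test_constant_depths_zero(self, make_seq):
        seq = make_seq({})
        assert vertical_oscillation_back(seq) == 0.0
        assert vertical_oscillation_head(seq) == 0.0
        assert trunk_inclination(seq) == 0.0
        assert lateral_sway_amplitude(seq) == 0.0

    def test_vob_from_withers_sinusoid(self, make_seq):
        T = 9
        withers = 1800 + 20 * np.cos(np.linspace(0, 2 * np.pi, T))  # 4 cm pp
        seq = make_seq({"withers": withers}, T=T)
        assert vertical_oscillation_back(seq) == pytest.approx(4.0, abs=1e-9)

    def test_voh_poll_range(self, make_seq):
        poll = np.array([2000.0, 1950.0, 2010.0, 1990.0])
        seq = make_seq({"poll": poll}, T=4)
        assert vertical_oscillation_head(seq) == pytest.approx(6.0)

    def test_ti_single_frame_offset(self, make_seq):
        T = 6
        ls = np.full(T, 1850.0)
        ls[3] = 1900.0  # 5 cm left-right gap in one frame only
        seq = make_seq({"left_scapula": ls, "right_scapula": 1850.0}, T=T)
        assert trunk_inclination(seq) == pytest.approx(5.0)

    def test_brute_force_oracles_on_random_tracks(self, make_seq, rng):
        T = 8
        depths = {
            name: rng.uniform(1700, 1900, size=T)
            for name in (
                "poll",
                "withers",
                "lumbar",
                "sacral_tuber",
                "left_scapula",
                "right_scapula",
                "left_tuber_coxae",
                "right_tuber_coxae",
            )
        }
        seq = make_seq(depths, T=T)
        cm = {k: v / 10 for k, v in depths.items()}
        assert vertical_oscillation_back(seq) == pytest.approx(
            max(np.ptp(cm[n]) for n in ("withers", "lumbar", "sacral_tuber"))
        )
        assert vertical_oscillation_head(seq) == pytest.approx(np.ptp(cm["poll"]))
        expected_ti = max(
            np.abs(cm["left_scapula"] - cm["right_scapula"]).max(),
            np.abs(cm["left_tuber_coxae"] - cm["right_tuber_coxae"]).max(),
        )
        assert trunk_inclination(seq) == pytest.approx(expected_ti)

    def test_lsas_from_swaying_tracks(self, make_seq, rng):
        T = 8
        base = {
            "poll": (40, 100), "withers": (40, 80),
            "left_scapula": (55, 72), "right_scapula": (25, 72),
            "lumbar": (40, 50), "left_tuber_coxae": (54, 28),
            "right_tuber_coxae": (26, 28), "sacral_tuber": (40, 20),
        }
        tracks = {
            n: np.tile(np.asarray(xy, float), (T, 1)) for n, xy in base.items()
        }
        sway = rng.uniform(-4, 4, size=T)
        for n in tracks:
            tracks[n][:, 0] += sway
        seq = make_seq({}, tracks_px=tracks, T=T, scale=1.5)
        assert lateral_sway_amplitude(seq) == pytest.approx(1.5 * np.ptp(sway))


class TestExtractAll:
    def test_constant_sequence_all_zero_except_bc(self, make_seq):
        seq = make_seq({})
        with pytest.warns(UserWarning, match="MAI flagged absent"):
            vec = extract_all(seq)
        assert vec.mai is None
        assert vec.vob == vec.voh == vec.ti == vec.lsas == 0.0
        assert vec.bc == 0.0  # flat template

    def test_rigid_translation_invariance(self, make_seq, rng):
        depths = {
            "withers": rng.uniform(1750, 1850, 5),
            "lumbar": rng.uniform(1750, 1850, 5),
            "sacral_tuber": rng.uniform(1750, 1850, 5),
            "poll": rng.uniform(1950, 2050, 5),
        }
        seq = make_seq(depths)
        tracks2 = {
            n: v + np.array([3.0, -7.0]) for n, v in seq.keypoints.items()
        }
        seq2 = make_seq(depths, tracks_px=tracks2)
        assert back_curvature(seq2) == pytest.approx(back_curvature(seq), abs=1e-12)
        assert vertical_oscillation_back(seq2) == pytest.approx(
            vertical_oscillation_back(seq)
        )
        assert vertical_oscillation_head(seq2) == pytest.approx(
            vertical_oscillation_head(seq)
        )
        assert trunk_inclination(seq2) == pytest.approx(trunk_inclination(seq))

    def test_scale_doubles_lsas(self, make_seq, rng):
        T = 6
        base = {
            "poll": (40, 100), "withers": (40, 80),
            "left_scapula": (55, 72), "right_scapula": (25, 72),
            "lumbar": (40, 50), "left_tuber_coxae": (54, 28),
            "right_tuber_coxae": (26, 28), "sacral_tuber": (40, 20),
        }
        tracks = {n: np.tile(np.asarray(xy, float), (T, 1)) for n, xy in base.items()}
        tracks["lumbar"][:, 0] += rng.uniform(-3, 3, T)
        s1 = make_seq({}, tracks_px={n: v.copy() for n, v in tracks.items()}, scale=1.0)
        s2 = make_seq({}, tracks_px={n: v.copy() for n, v in tracks.items()}, scale=2.0)
        assert lateral_sway_amplitude(s2) == pytest.approx(
            2 * lateral_sway_amplitude(s1)
        )
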