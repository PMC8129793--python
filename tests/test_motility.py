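"""Sector classification, tracking, speed, roundness and tumbling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bcquant import synthetic
from bcquant.motility import (
    Extension,
    Track,
    analyze_timelapse,
    classify_sector,
    detect_rearrangement,
    extension_angle,
    forward_speed,
    migration_index,
    percent_reduction,
    roundness,
    sector_summary,
    track_centroid,
    tumbling_index,
)


def _oracle_sector(angle):
    """Literal transcription of the interval definition."""
    a = angle % 360
    if 315 <= a < 360 or 0 <= a < 45:
        return "front"
    if 45 <= a < 135 or 225 <= a < 315:
        return "side"
    return "back"


class TestAngles:
    @pytest.mark.parametrize("ext,expected", [
        ((5.0, 0.0), 0.0),     # directly right
        ((0.0, -5.0), 90.0),   # directly above on screen (-y)
        ((-5.0, 0.0), 180.0),  # directly left
        ((0.0, 5.0), 270.0),   # directly below
    ])
    def test_cardinal_directions(self, ext, expected):
        assert extension_angle((0.0, 0.0), ext) == pytest.approx(expected)

    def test_every_integer_degree_matches_interval_definition(self):
        for deg in range(720):
            assert classify_sector(deg) == _oracle_sector(deg)

    @pytest.mark.parametrize("angle,sector", [
        (0, "front"), (90, "side"), (180, "back"),
        (45, "side"), (135, "back"), (225, "side"), (315, "front"),
        (405, "side"),
    ])
    def test_boundary_conventions(self, angle, sector):
        assert classify_sector(angle) == sector

    @given(st.floats(-1e6, 1e6, allow_nan=False), st.integers(-5, 5))
    @settings(max_examples=200, derandomize=True)
    def test_periodic_mod_360(self, angle, k):
        assert classify_sector(angle) == classify_sector(angle + 360.0 * k)


class TestSectorSummary:
    def _ext(self, angle, frame=0, area=5.0):
        return Extension(frame, area, angle % 360, classify_sector(angle))

    def test_all_front(self):
        df = sector_summary([self._ext(10.0)] * 4).set_index("sector")
        assert df.loc["front", "percent"] == 100.0
        assert df.loc["side", "n_extensions"] == 0

    def test_one_per_slot(self):
        df = sector_summary([self._ext(a) for a in (0, 90, 270, 180)]).set_index("sector")
        assert df.loc["front", "percent"] == 25.0
        assert df.loc["side", "percent"] == 50.0
        assert df.loc["back", "percent"] == 25.0
        assert df["percent"].sum() == pytest.approx(100.0)

    def test_empty_reports_missing_not_zero(self):
        df = sector_summary([]).set_index("sector")
        assert (df["n_extensions"] == 0).all()
        assert df["percent"].isna().all()


class TestTrackAndSpeed:
    def test_static_mask_constant_track(self, disk_mask):
        track = track_centroid([disk_mask] * 4, pixel_size=0.62, frame_interval=3.0)
        assert np.ptp(track.x_um) == 0.0

    def test_translated_mask_known_step(self, disk_mask):
        masks = [np.roll(disk_mask, 2 * t, axis=1) for t in range(4)]
        track = track_centroid(masks, pixel_size=0.62, frame_interval=3.0)
        np.testing.assert_allclose(np.diff(track.x_um), 1.24, atol=1e-9)

    def test_track_within_half_micron_of_truth(self, cluster_spec, default_protrusions):
        motion = synthetic.MotionSpec(forward_speed_um_per_min=0.45, n_frames=8)
        stack, truth = synthetic.make_timelapse(cluster_spec, default_protrusions,
                                                motion, seed=2)
        from bcquant.imaging import split_body_extensions, threshold_cluster
        masks = [split_body_extensions(threshold_cluster(f), stack.pixel_size).body_mask
                 for f in stack.frames]
        track = track_centroid(masks, stack.pixel_size, 3.0)
        rms = np.sqrt(np.mean((track.x_um - truth.track_xy_um[:, 0]) ** 2
                              + (track.y_um - truth.track_xy_um[:, 1]) ** 2))
        assert rms <= 0.5

    def test_printed_control_speed_arithmetic(self):
        track = Track(np.array([0.0, 1.35, 2.70]), np.zeros(3), frame_interval=3.0)
        assert forward_speed(track) == pytest.approx(0.45)

    def test_constant_position_zero_speed(self):
        track = Track(np.full(5, 7.0), np.zeros(5), frame_interval=3.0)
        assert forward_speed(track) == 0.0

    def test_truth_speed_recovered_exactly_without_jitter(self):
        track = Track(np.arange(10) * 0.27, np.zeros(10), frame_interval=3.0)
        assert forward_speed(track) == pytest.approx(0.09)

    @given(st.floats(-100, 100, allow_nan=False))
    @settings(max_examples=50, derandomize=True)
    def test_translation_invariance(self, shift):
        x = np.array([0.0, 1.0, 3.0, 6.0])
        t1 = Track(x, np.zeros(4), 3.0)
        t2 = Track(x + shift, np.zeros(4), 3.0)
        assert forward_speed(t1) == pytest.approx(forward_speed(t2))

    def test_speed_scales_inversely_with_frame_interval(self):
        x = np.array([0.0, 1.0, 2.0])
        assert forward_speed(Track(x, np.zeros(3), 1.5)) == pytest.approx(
            2 * forward_speed(Track(x, np.zeros(3), 3.0)))


class TestScalarMetrics:
    def test_percent_reduction_printed_example(self):
        assert percent_reduction(0.45, 0.09) == pytest.approx(80.0)

    def test_percent_reduction_degenerate_cases(self):
        assert percent_reduction(0.3, 0.3) == 0.0
        assert percent_reduction(0.3, 0.0) == 100.0

    def test_percent_reduction_requires_positive_control(self):
        with pytest.raises(ValueError):
            percent_reduction(0.0, 0.1)

    @pytest.mark.parametrize("x,expected", [(100.0, 100.0), (0.0, 0.0), (50.0, 50.0),
                                            (130.0, 100.0), (-10.0, 0.0)])
    def test_migration_index(self, x, expected):
        assert migration_index(x, 0.0, 100.0) == expected

    def test_migration_index_requires_ordered_landmarks(self):
        with pytest.raises(ValueError):
            migration_index(10.0, 50.0, 50.0)


class TestRoundness:
    def test_disk_is_round(self, disk_mask):
        assert roundness(disk_mask) >= 0.9

    def test_bar_is_not_round(self):
        bar = np.zeros((20, 20), dtype=bool)
        bar[5, 3:13] = True  # 10x1 bar: 4*pi*10/22^2 = 0.26 analytically
        assert roundness(bar) < 0.5

    def test_translation_invariant(self, disk_mask):
        assert roundness(disk_mask) == pytest.approx(
            roundness(np.roll(disk_mask, 7, axis=1)))


class TestRearrangement:
    def _ring(self, angles, radii):
        th = np.radians(angles)
        return np.column_stack([radii * np.cos(th), -radii * np.sin(th)])

    def test_identical_sets_false(self):
        pts = self._ring([0, 60, 120, 180, 240, 300], np.array([3, 7, 3, 7, 3, 7.0]))
        assert not detect_rearrangement(pts, pts)

    def test_rigid_translation_false(self):
        pts = self._ring([0, 60, 120, 180, 240, 300], np.array([3, 7, 3, 7, 3, 7.0]))
        assert not detect_rearrangement(pts, pts + np.array([2.0, -1.0]))

    def test_angular_swap_true(self):
        radii = np.array([3, 7, 3, 7, 3, 7.0])
        a = self._ring([0, 60, 120, 180, 240, 300], radii)
        b = self._ring([35, 25, 120, 180, 240, 300], radii)  # pair 0/1 crossed
        assert detect_rearrangement(a, b)

    def test_mismatched_counts_use_common_subset(self):
        radii = np.array([3, 7, 3, 7, 3, 7.0])
        a = self._ring([0, 60, 120, 180, 240, 300], radii)
        assert not detect_rearrangement(a, a[:5])


class TestTumblingIndex:
    def test_all_first_half_qualifying_is_100(self):
        rounded = np.array([1] * 10 + [0] * 10, dtype=bool)
        score = tumbling_index(rounded, rounded.copy())
        assert score.tumbling_index_pct == 100.0

    def test_no_qualifying_frames_is_0(self):
        flags = np.zeros(20, dtype=bool)
        assert tumbling_index(flags, flags).tumbling_index_pct == 0.0

    def test_isolated_qualifying_frame_does_not_count(self):
        rounded = np.zeros(10, dtype=bool)
        rounded[3] = True
        assert tumbling_index(rounded, rounded.copy()).tumbling_index_pct == 0.0

    def test_two_consecutive_frames_count(self):
        q = np.zeros(10, dtype=bool)
        q[2:4] = True
        assert tumbling_index(q, q.copy()).tumbling_index_pct == pytest.approx(40.0)

    def test_monotone_in_added_qualifying_frames(self):
        base = np.zeros(12, dtype=bool)
        base[0:2] = True
        more = base.copy()
        more[3:5] = True
        assert (tumbling_index(more, more.copy()).tumbling_index_pct
                >= tumbling_index(base, base.copy()).tumbling_index_pct)

    def test_requires_rounded_and_rearranged(self):
        rounded = np.ones(10, dtype=bool)
        rearranged = np.zeros(10, dtype=bool)
        assert tumbling_index(rounded, rearranged).tumbling_index_pct == 0.0


class TestEndToEndRecovery:
    def test_sector_fractions_recovered_within_3_binomial_sd(self):
        """Measured sector fractions on a synthetic movie track the
        generator's sampling weights (law of large numbers band)."""
        weights = (0.54, 0.30, 0.16)
        cluster = synthetic.ClusterSpec(noise_sd=8.0)
        prot = synthetic.ProtrusionSpec(sector_weights=weights)
        motion = synthetic.MotionSpec(forward_speed_um_per_min=0.09, n_frames=60)
        stack, _ = synthetic.make_timelapse(cluster, prot, motion, seed=7)
        res = analyze_timelapse(stack)
        df = res["sector_summary"].set_index("sector")
        n = int(df["n_extensions"].sum())
        assert n >= 100
        for sector, w in zip(("front", "side", "back"), weights):
            frac = df.loc[sector, "percent"] / 100.0
            assert abs(frac - w) <= 3 * np.sqrt(w * (1 - w) / n)

    def test_speed_recovered_within_5_percent(self):
        """Forward speed from segmentation matches the generator's speed
        when protrusion geometry is held fixed across frames."""
        cluster = synthetic.ClusterSpec(noise_sd=8.0)
        prot = synthetic.ProtrusionSpec(explicit_angles_deg=[0.0, 120.0],
                                        length_um=(5.0, 5.0), width_um=(3.0, 3.0))
        motion = synthetic.MotionSpec(forward_speed_um_per_min=0.45, n_frames=20)
        stack, _ = synthetic.make_timelapse(cluster, prot, motion, seed=3)
        res = analyze_timelapse(stack)
        assert res["forward_speed_um_per_min"] == pytest.approx(0.45, rel=0.05)

    def test_control_movie_has_zero_tumbling(self):
        cluster = synthetic.ClusterSpec(noise_sd=8.0)
        motion = synthetic.MotionSpec(forward_speed_um_per_min=0.45, n_frames=20)
        stack, _ = synthetic.make_timelapse(cluster, synthetic.ProtrusionSpec(),
                                            motion, seed=1)
        res = analyze_timelapse(stack)
        assert res["tumbling_index_pct"] == 0.0
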