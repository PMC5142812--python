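"""Marking-event detector, bout segmentation, and bout statistics."""

import numpy as np
import pytest

from blazedtrail import (
    DetectorConfig,
    MarkEvent,
    Trajectory,
    detect_marks,
    extreme_bout_probability,
    median_ci_binomial,
    segment_bouts,
    speed_profile,
)


def _straight_traj(speeds, frame_rate=50.0):
    t = np.arange(len(speeds)) / frame_rate
    x = np.concatenate([[0.0], np.cumsum(np.asarray(speeds[:-1]) / frame_rate)])
    return Trajectory(id="ant", t=t, x=x, y=np.zeros_like(t), frame_rate=frame_rate)


class TestSpeedProfile:
    def test_uniform_motion(self):
        traj = _straight_traj(np.full(200, 5.0))
        speed, accel = speed_profile(traj, DetectorConfig(smoothing_frames=1))
        assert np.allclose(speed, 5.0)
        assert np.allclose(accel, 0.0, atol=1e-9)

    def test_stationary_ant(self):
        t = np.arange(100) / 50.0
        traj = Trajectory(id="a", t=t, x=np.zeros(100), y=np.zeros(100), frame_rate=50.0)
        speed, _ = speed_profile(traj)
        assert np.allclose(speed, 0.0)

    def test_linear_speed_ramp(self):
        fr = 50.0
        t = np.arange(int(fr)) / fr
        speeds = 10.0 * t  # 0 -> 10 cm/s over 1 s
        traj = _straight_traj(speeds, fr)
        _, accel = speed_profile(traj, DetectorConfig(smoothing_frames=1))
        assert np.median(accel[5:-5]) == pytest.approx(10.0, rel=0.05)

    def test_too_short_rejected(self):
        t = np.array([0.0, 0.02])
        traj = Trajectory(id="a", t=t, x=t, y=t, frame_rate=50.0)
        with pytest.raises(ValueError):
            speed_profile(traj)


def _dip_profile(fr=50.0, cruise=5.0, dip_to=2.0, dip_width=0.2, t0=2.0, total=4.0):
    t = np.arange(int(total * fr)) / fr
    shape = np.clip(1.0 - np.abs(t - t0) / (dip_width / 2), 0.0, None)
    return _straight_traj(cruise - (cruise - dip_to) * shape, fr)


class TestDetectMarks:
    def test_sharp_dip_detected_once(self):
        # 5 -> 0.8 -> 5 cm/s within 0.2 s: |a| ~ 42 cm/s^2, one event
        traj = _dip_profile(dip_to=0.8)
        events = detect_marks(traj, DetectorConfig(smoothing_frames=1))
        assert len(events) == 1
        assert events[0].t == pytest.approx(2.0, abs=0.05)

    def test_constant_speed_no_events(self):
        traj = _straight_traj(np.full(300, 5.0))
        assert detect_marks(traj) == []

    def test_slow_shallow_dip_fails_acceleration_gate(self):
        # dip to 3.0 cm/s over 2 s: below v_min but |a| ~ 2 cm/s^2
        traj = _dip_profile(dip_to=3.0, dip_width=2.0, t0=2.0, total=5.0)
        assert detect_marks(traj, DetectorConfig(smoothing_frames=1)) == []

    def test_event_position_at_minimum(self):
        traj = _dip_profile(dip_to=0.8)
        ev = detect_marks(traj, DetectorConfig(smoothing_frames=1))[0]
        assert ev.x == pytest.approx(np.interp(ev.t, traj.t, traj.x))


class TestSegmentBouts:
    def _load(self):
        t = np.arange(500) / 50.0
        return Trajectory(
            id="load", t=t, x=np.zeros_like(t), y=np.zeros_like(t), frame_rate=50.0
        )

    def test_single_event_bout(self):
        bouts = segment_bouts([MarkEvent("a", 1.0, 3.0, 0.0)], self._load())
        assert len(bouts) == 1
        assert bouts[0].start_distance_cm == pytest.approx(3.0)
        assert bouts[0].bout_length_cm == pytest.approx(3.0)

    def test_interleaved_ants_not_merged(self):
        events = [
            MarkEvent("a", 1.0, 3.0, 0.0),
            MarkEvent("b", 1.5, 4.0, 0.0),
            MarkEvent("a", 2.0, 5.0, 0.0),
        ]
        bouts = segment_bouts(events, self._load())
        assert len(bouts) == 2
        assert sum(len(b.events) for b in bouts) == 3

    def test_gap_splits_bouts(self):
        events = [MarkEvent("a", 1.0, 3.0, 0.0), MarkEvent("a", 9.0, 4.0, 0.0)]
        bouts = segment_bouts(events, self._load(), max_gap_s=2.0)
        assert len(bouts) == 2

    def test_outward_walk_bout_length_is_furthest_mark(self):
        events = [
            MarkEvent("a", 1.0 + 0.2 * i, 3.0 + 9.0 * i / 8.0, 0.0) for i in range(9)
        ]
        bouts = segment_bouts(events, self._load())
        assert len(bouts) == 1 and len(bouts[0].events) == 9
        assert bouts[0].start_distance_cm == pytest.approx(3.0)
        assert bouts[0].bout_length_cm == pytest.approx(12.0)


class TestMedianCiBinomial:
    def test_identical_values_collapse(self):
        assert median_ci_binomial([7.0] * 9) == (7.0, 7.0)

    def test_small_sample_returns_full_range(self):
        # Binomial(5, 1/2) cannot cover 95% with anything narrower
        assert median_ci_binomial([1, 2, 3, 4, 5]) == (1.0, 5.0)

    def test_known_ranks_at_n20(self):
        x = np.arange(1.0, 21.0)
        lo, hi = median_ci_binomial(x, conf=0.95)
        assert (lo, hi) == (6.0, 15.0)

    @pytest.mark.parametrize("n", [20, 100, 735])
    def test_coverage_at_least_nominal(self, n):
        """Empirical coverage of the 95% CI stays >= 93% over 1000
        simulated uniform samples (conservative order-statistic ranks)."""
        rng = np.random.default_rng(42 + n)
        hits = 0
        sims = 1000
        samples = rng.uniform(size=(sims, n))
        for row in samples:
            lo, hi = median_ci_binomial(row)
            hits += lo <= 0.5 <= hi
        assert hits / sims >= 0.93


class TestExtremeBoutProbability:
    def test_paper_style_tail_numbers(self):
        p, pk = extreme_bout_probability(16, 735, 12)
        assert p == pytest.approx(0.0218, abs=5e-4)
        assert pk < 1e-6

    def test_zero_tail(self):
        assert extreme_bout_probability(0, 10, 3) == (0.0, 0.0)

    def test_half_tail(self):
        assert extreme_bout_probability(5, 10, 2) == (0.5, 0.25)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            extreme_bout_probability(11, 10, 2)
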