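"""Dive detection, phase partitioning, and kinematic features."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import orcaforage as of
from .conftest import flat_series


def trapezoid_depth(n, fs, t0, down_s, flat_s, depth):
    """Depth trace with one trapezoidal dive starting at t0 seconds."""
    t = np.arange(n) / fs
    d = np.zeros(n)
    rise = (t - t0) / down_s
    fall = (t - t0 - down_s - flat_s) / down_s
    prof = np.clip(np.minimum(rise, 1.0 - fall), 0.0, 1.0) * depth
    d[(t >= t0) & (t <= t0 + 2 * down_s + flat_s)] = prof[
        (t >= t0) & (t <= t0 + 2 * down_s + flat_s)
    ]
    return d


class TestDetectDives:
    def test_constant_surface_has_no_dives(self):
        s = flat_series()
        assert of.detect_dives(s) == []

    def test_single_trapezoid_boundaries_at_half_meter_crossings(self):
        fs = 10.0
        depth = trapezoid_depth(8000, fs, t0=400.0, down_s=40.0, flat_s=40.0, depth=50.0)
        s = flat_series(8000, fs, depth)
        dives = of.detect_dives(s)
        assert len(dives) == 1
        d = dives[0]
        # depth crosses 0.5 m at t0 + 0.4 s (slope 1.25 m/s); the recorded
        # boundary is the adjacent surface sample
        assert d.start_time == pytest.approx(400.4, abs=2 / fs)
        assert d.end_time == pytest.approx(400 + 120 - 0.4, abs=2 / fs)
        assert d.max_depth == pytest.approx(50.0)

    def test_short_spike_is_not_a_dive(self):
        fs = 10.0
        depth = trapezoid_depth(8000, fs, t0=400.0, down_s=1.0, flat_s=0.5, depth=5.0)
        s = flat_series(8000, fs, depth)
        assert of.detect_dives(s) == []  # 2.5 s < the 4-s minimum

    def test_exclusion_window_drops_early_dives(self):
        fs = 10.0
        depth = trapezoid_depth(8000, fs, 100.0, 20.0, 20.0, 30.0) + trapezoid_depth(
            8000, fs, 500.0, 20.0, 20.0, 30.0
        )
        s = flat_series(8000, fs, depth)
        dives = of.detect_dives(s)
        assert len(dives) == 1 and dives[0].start_time > 400

    def test_shallow_excursion_below_one_meter_ignored(self):
        fs = 10.0
        depth = trapezoid_depth(8000, fs, 400.0, 10.0, 30.0, 0.9)
        s = flat_series(8000, fs, depth)
        assert of.detect_dives(s) == []

    def test_short_series_warns_and_returns_empty(self):
        s = flat_series(100, 10.0)
        with pytest.warns(UserWarning):
            assert of.detect_dives(s) == []

    def test_rerun_is_identity(self, sim_deployment):
        _, dep = sim_deployment
        assert of.detect_dives(dep.series) == of.detect_dives(dep.series)


class TestPartitionPhases:
    def test_v_dive_bottom_contains_samples_above_70pct(self):
        fs = 10.0
        depth = trapezoid_depth(8000, fs, 400.0, 50.0, 0.0, 100.0)  # V to 100 m
        s = flat_series(8000, fs, depth)
        (d,) = of.detect_dives(s)
        d = of.partition_phases(d, s)
        i0 = int(d.descent_end * fs)
        i1 = int(d.ascent_start * fs)
        seg = depth[int(d.start_time * fs) : int(d.end_time * fs) + 1]
        inside = depth[i0 : i1 + 1]
        assert inside.min() >= 0.70 * seg.max() - 1e-9
        # the samples right outside the bottom are below threshold
        assert depth[i0 - 1] < 0.70 * seg.max()
        assert depth[i1 + 1] < 0.70 * seg.max()

    def test_shelf_below_threshold_excluded_from_bottom(self):
        # 50-m trapezoid with a 30-m shelf on descent: 30 < 0.7 * 50 = 35,
        # so the shelf belongs to the descent, not the bottom
        fs = 10.0
        t = np.arange(8000) / fs
        d = np.zeros(8000)
        seg = (t >= 400) & (t < 430)
        d[seg] = (t[seg] - 400) / 30 * 30
        d[(t >= 430) & (t < 460)] = 30.0  # shelf
        seg = (t >= 460) & (t < 480)
        d[seg] = 30 + (t[seg] - 460)
        d[(t >= 480) & (t < 505)] = 50.0
        seg = (t >= 505) & (t < 555)
        d[seg] = np.maximum(50 - (t[seg] - 505), 0.0)
        s = flat_series(8000, fs, d)
        (dive,) = of.detect_dives(s)
        dive = of.partition_phases(dive, s)
        # first sample at >= 35 m is on the second ramp, at t = 465
        assert dive.descent_end == pytest.approx(465.0, abs=0.2)
        assert d[int(dive.descent_end * fs)] >= 35.0 - 1e-9

    def test_phases_partition_the_dive(self, sim_deployment):
        _, dep = sim_deployment
        for d in of.detect_dives(dep.series):
            d = of.partition_phases(d, dep.series)
            assert d.start_time < d.descent_end <= d.ascent_start < d.end_time


class TestJerk:
    def test_constant_acceleration_gives_zero_jerk(self):
        s = flat_series(100, 10.0)
        s.accel[:] = 1.5
        assert np.all(of.jerk_magnitude(s) == 0.0)

    def test_single_axis_step(self):
        s = flat_series(100, 20.0)
        s.accel[:] = 0.0
        s.accel[50:, 0] = 0.3
        j = of.jerk_magnitude(s)
        assert j[49] == pytest.approx(0.3 * 20.0)
        assert np.count_nonzero(j) == 1

    def test_rotating_acceleration_small_angle_closed_form(self):
        # constant-magnitude vector rotating at omega: |jerk| ~ |a| * omega
        fs, omega, a = 200.0, 2.0, 1.3
        t = np.arange(4000) / fs
        s = flat_series(4000, fs)
        s.accel = np.column_stack(
            [a * np.cos(omega * t), a * np.sin(omega * t), np.zeros_like(t)]
        )
        j = of.jerk_magnitude(s)
        assert np.median(j) == pytest.approx(a * omega, rel=1e-3)


class TestCircularVariance:
    def test_identical_headings_zero(self):
        assert of.circular_variance([77.0] * 10) == pytest.approx(0.0, abs=1e-12)

    def test_four_cardinal_directions_one(self):
        assert of.circular_variance([0, 90, 180, 270]) == pytest.approx(1.0, abs=1e-12)

    def test_two_orthogonal_closed_form(self):
        assert of.circular_variance([0, 90]) == pytest.approx(1 - np.sqrt(2) / 2)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            of.circular_variance([])

    @given(
        st.lists(st.floats(0, 360, allow_nan=False), min_size=1, max_size=30),
        st.floats(-720, 720, allow_nan=False),
    )
    @settings(max_examples=50, deadline=None)
    def test_rotation_invariance(self, headings, shift):
        a = of.circular_variance(headings)
        b = of.circular_variance([(h + shift) % 360 for h in headings])
        assert a == pytest.approx(b, abs=1e-9)


class TestPhaseFeatures:
    def test_constructed_spike_in_bottom_phase(self):
        fs = 10.0
        depth = trapezoid_depth(12000, fs, 400.0, 40.0, 60.0, 80.0)
        s = flat_series(12000, fs, depth)
        s.accel[:] = 0.0
        # baseline jerk: small alternating wiggle so the median is positive
        s.accel[::2, 2] = 0.005
        med = of.deployment_median_jerk(s)
        c = int(470 * fs)  # mid-bottom
        s.accel[c, 0] = 10 * med / fs + s.accel[c, 0]
        s.roll[c - 1 : c + 2] = -45.0  # the jerk spike spans two intervals
        (d,) = of.detect_dives(s)
        d = of.partition_phases(d, s)
        d = of.phase_features(d, s, of.deployment_median_jerk(s))
        bot = d.features["bottom"]
        assert bot.jerk_peak == pytest.approx(10.0, rel=0.05)
        assert bot.roll_at_jerk_peak == pytest.approx(45.0)
        assert d.features["descent"].heading_circular_variance == pytest.approx(0.0, abs=1e-9)

    def test_zero_median_jerk_rejected(self, sim_deployment):
        _, dep = sim_deployment
        d = of.partition_phases(of.detect_dives(dep.series)[0], dep.series)
        with pytest.raises(ValueError):
            of.phase_features(d, dep.series, 0.0)

    def test_truth_dive_recovery_on_simulation(self, sim_deployment):
        cfg, dep = sim_deployment
        dives = of.detect_dives(dep.series)
        truth = dep.truth["dive_intervals"]
        assert len(dives) == len(truth)
        tol = 2.0 / cfg.sampling_rate
        for d, (s0, e0) in zip(dives, truth):
            assert abs(d.start_time - s0) <= tol
            assert abs(d.end_time - e0) <= tol + 1.0 / cfg.sampling_rate
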