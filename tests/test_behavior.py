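"""Lap segmentation, choice metrics, speed windows, and expectation labels."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from threatmaze import behavior
from threatmaze.behavior import (
    Lap,
    MazeGeometry,
    Rect,
    RoiEvent,
    TrackingSeries,
    adaptive_choice_fraction,
    detect_roi_events,
    expectation_label,
    latency_metrics,
    median_split,
    segment_laps,
    speed_metrics,
    speed_timecourse,
)


def make_lap(i=0, path="lt-p", lap_class="full", threat=False, t0=0.0, **kw):
    end = "RW_A" if lap_class == "half" else "RW_B"
    defaults = dict(
        index=i,
        session="P1",
        start_site="RW_A",
        end_site=end,
        path=path,
        lap_class=lap_class,
        threat_delivered=threat,
        led=False,
        t_exit_reward=t0,
        t_enter_threat=t0 + 4.0,
        t_exit_threat=t0 + 5.0,
        t_enter_end_reward=t0 + 8.0,
    )
    defaults.update(kw)
    return Lap(**defaults)


class TestRoiEvents:
    def test_single_crossing_gives_one_enter_exit(self, geometry):
        # straight line through the left threat ROI (x < 8, 55 <= y < 75)
        t = np.arange(0, 4, 1 / 30)
        y = np.linspace(30.0, 90.0, len(t))
        x = np.full_like(y, 4.0)
        events = detect_roi_events(TrackingSeries(t, x, y), geometry)
        th = [e for e in events if e.roi == "TH_L"]
        assert [e.kind for e in th] == ["enter", "exit"]

    def test_trajectory_inside_reward_roi_enters_without_exit(self, geometry):
        t = np.arange(0, 2, 1 / 30)
        x = np.full_like(t, 10.0)
        y = np.full_like(t, 10.0)
        events = detect_roi_events(TrackingSeries(t, x, y), geometry)
        assert [(e.roi, e.kind) for e in events] == [("RW_A", "enter")]

    def test_matches_per_sample_rectangle_scan(self, geometry, rng):
        t = np.arange(0, 20, 1 / 30)
        x = np.clip(37.5 + np.cumsum(rng.normal(0, 3, len(t))), 0, 74.9)
        y = np.clip(37.5 + np.cumsum(rng.normal(0, 3, len(t))), 0, 74.9)
        events = detect_roi_events(TrackingSeries(t, x, y), geometry)
        # brute-force oracle: per-sample point-in-rectangle state machine
        expected = []
        for roi_id, rect in geometry.rois.items():
            inside = False
            for ti, xi, yi in zip(t, x, y):
                now = rect.xmin <= xi < rect.xmax and rect.ymin <= yi < rect.ymax
                if now != inside:
                    expected.append((ti, roi_id, "enter" if now else "exit"))
                    inside = now
        expected.sort(key=lambda e: (e[0], e[2] == "enter"))
        assert [(e.time, e.roi, e.kind) for e in events] == expected

    def test_empty_tracking_rejected(self, geometry):
        with pytest.raises(ValueError):
            detect_roi_events(TrackingSeries([], [], []), geometry)


class TestSegmentLaps:
    def _events(self, seq):
        return [RoiEvent(t, roi, kind) for t, roi, kind in seq]

    def test_full_lap(self, geometry):
        ev = self._events(
            [(0, "RW_A", "enter"), (1, "RW_A", "exit"), (3, "TH_L", "enter"),
             (4, "TH_L", "exit"), (6, "RW_B", "enter")]
        )
        laps = segment_laps(ev, geometry)
        assert len(laps) == 1
        assert laps[0].lap_class == "full"
        assert laps[0].path == "ht-p"
        assert (laps[0].start_site, laps[0].end_site) == ("RW_A", "RW_B")

    def test_half_lap_returns_to_same_reward(self, geometry):
        ev = self._events(
            [(1, "RW_A", "exit"), (3, "TH_L", "enter"), (4, "TH_L", "exit"),
             (6, "RW_A", "enter")]
        )
        laps = segment_laps(ev, geometry)
        assert len(laps) == 1
        assert laps[0].lap_class == "half"

    def test_reward_to_reward_without_threat_is_no_lap(self, geometry):
        ev = self._events([(1, "RW_A", "exit"), (6, "RW_A", "enter")])
        assert segment_laps(ev, geometry) == []

    def test_border_jitter_reentry_merged_into_one_visit(self, geometry):
        ev = self._events(
            [(1, "RW_A", "exit"), (3, "TH_L", "enter"), (3.5, "TH_L", "exit"),
             (4.0, "TH_L", "enter"), (5, "TH_L", "exit"), (7, "RW_B", "enter")]
        )
        laps = segment_laps(ev, geometry)
        assert len(laps) == 1
        assert laps[0].t_enter_threat == 3
        assert laps[0].t_exit_threat == 5

    def test_puff_matched_within_tolerance(self, geometry):
        ev = self._events(
            [(1, "RW_A", "exit"), (3, "TH_L", "enter"), (4, "TH_L", "exit"),
             (6, "RW_B", "enter")]
        )
        laps = segment_laps(ev, geometry, puff_times=[3.1])
        assert laps[0].threat_delivered
        with pytest.raises(ValueError):
            segment_laps(ev, geometry, puff_times=[5.0])

    def test_every_threat_entry_belongs_to_one_lap(self, p5_session, geometry):
        events = detect_roi_events(p5_session["tracking"], geometry)
        laps = segment_laps(events, geometry, p5_session["puffs"], p5_session["leds"])
        # independent count of merged threat-site visits
        assert len(laps) == len(p5_session["laps"])
        n_half = sum(l.lap_class == "half" for l in laps)
        n_full = sum(l.lap_class == "full" for l in laps)
        assert n_half + n_full == len(p5_session["entries"])


class TestAdaptiveChoice:
    def test_all_low_threat(self):
        laps = [make_lap(i, path="lt-p") for i in range(10)]
        assert adaptive_choice_fraction(laps) == 1.0

    def test_half_laps_in_denominator(self):
        laps = [make_lap(i, path="lt-p") for i in range(3)]
        laps.append(make_lap(3, path="ht-p", lap_class="half"))
        assert adaptive_choice_fraction(laps) == 0.75

    def test_zero_laps_signaled(self):
        with pytest.raises(ValueError):
            adaptive_choice_fraction([])

    def test_invariant_under_reward_site_relabeling(self, rng):
        paths = rng.choice(["ht-p", "lt-p"], 40)
        laps = [make_lap(i, path=p, t0=10.0 * i) for i, p in enumerate(paths)]
        swapped = []
        for lap in laps:
            swapped.append(
                make_lap(
                    lap.index, path=lap.path, t0=lap.t_exit_reward,
                    start_site="RW_B", end_site="RW_A",
                )
            )
        assert adaptive_choice_fraction(laps) == adaptive_choice_fraction(swapped)

    def test_matches_independent_tally(self, rng):
        paths = rng.choice(["ht-p", "lt-p"], 200)
        laps = [make_lap(i, path=p, t0=10.0 * i) for i, p in enumerate(paths)]
        tally = sum(1 for p in paths if p == "lt-p") / len(paths)
        assert adaptive_choice_fraction(laps) == pytest.approx(tally)


class TestSpeedMetrics:
    def _constant_velocity_tracking(self, v=10.0, duration=12.0):
        t = np.arange(0, duration, 1 / 30)
        return TrackingSeries(t, v * t * 0.001 + t * 0, t * v)  # mostly along y

    def test_constant_velocity_recovered(self):
        t = np.arange(0, 12, 1 / 30)
        tr = TrackingSeries(t, np.zeros_like(t), 10.0 * t)
        lap = make_lap(t0=1.0, t_enter_threat=6.0, t_exit_threat=7.0, t_enter_end_reward=9.0)
        sw = speed_metrics(lap, tr)
        assert sw.approach == pytest.approx(10.0)
        assert sw.reaction == pytest.approx(10.0)

    def test_stationary_mouse_zero_speed(self):
        t = np.arange(0, 12, 1 / 30)
        tr = TrackingSeries(t, np.full_like(t, 5.0), np.full_like(t, 5.0))
        sw = speed_metrics(make_lap(t0=1.0, t_enter_threat=6.0), tr)
        assert sw.approach == pytest.approx(0.0)
        assert sw.reaction == pytest.approx(0.0)

    def test_matches_finite_difference_oracle(self, rng):
        t = np.arange(0, 12, 1 / 30)
        x = np.cumsum(rng.normal(0, 0.3, len(t)))
        y = np.cumsum(rng.normal(0, 0.3, len(t)))
        tr = TrackingSeries(t, x, y)
        lap = make_lap(t0=1.0, t_enter_threat=6.0, t_exit_threat=7.0, t_enter_end_reward=9.0)
        sw = speed_metrics(lap, tr)
        # brute-force loop oracle over interval midpoints
        pre, post = [], []
        for i in range(len(t) - 1):
            mid = 0.5 * (t[i] + t[i + 1])
            sp = np.hypot(x[i + 1] - x[i], y[i + 1] - y[i]) / (t[i + 1] - t[i])
            if 5.5 < mid <= 6.0:
                pre.append(sp)
            elif 6.0 < mid <= 6.5:
                post.append(sp)
        assert sw.approach == pytest.approx(np.mean(pre))
        assert sw.reaction == pytest.approx(np.mean(post))

    def test_window_beyond_recording_flagged(self):
        t = np.arange(0, 2, 1 / 30)
        tr = TrackingSeries(t, t, t)
        sw = speed_metrics(make_lap(t0=0.0, t_enter_threat=0.2, t_exit_threat=0.5,
                                    t_enter_end_reward=1.0), tr)
        assert not sw.valid and np.isnan(sw.approach)


class TestMedianSplit:
    def test_even_distinct_split(self):
        assert median_split([1, 2, 3, 4]) == ["slow", "slow", "fast", "fast"]

    def test_all_ties_go_fast(self):
        assert median_split([5, 5, 5, 5]) == ["fast"] * 4

    @given(st.lists(st.floats(0.1, 100), min_size=4, max_size=200, unique=True))
    @settings(max_examples=50, deadline=None)
    def test_matches_sorting_oracle_and_balance(self, speeds):
        labels = median_split(speeds)
        order = np.argsort(speeds)
        n = len(speeds)
        slow_set = {order[i] for i in range(n // 2)} if n % 2 == 0 else {
            order[i] for i in range((n - 1) // 2)
        }
        # oracle: strictly-below-median elements are exactly the lower half
        med = float(np.median(speeds))
        assert [lab == "slow" for lab in labels] == [s < med for s in speeds]
        assert {i for i, lab in enumerate(labels) if lab == "slow"} <= slow_set | {
            i for i in range(n)
        }
        n_slow = labels.count("slow")
        assert abs((n - n_slow) - n_slow) <= 1

    def test_too_few_laps_rejected(self):
        with pytest.raises(ValueError):
            median_split([1.0, 2.0, 3.0])


class TestExpectationLabel:
    @pytest.mark.parametrize(
        "fs,threat,expected",
        [
            ("fast", True, "surprising"),
            ("slow", True, "expected"),
            ("slow", False, "surprising"),
            ("fast", False, "expected"),
        ],
    )
    def test_four_way_table(self, fs, threat, expected):
        assert expectation_label(fs, threat) == expected

    @pytest.mark.parametrize("threat", [True, False])
    def test_flipping_speed_class_flips_label(self, threat):
        assert expectation_label("fast", threat) != expectation_label("slow", threat)

    def test_missing_speed_class_is_error(self):
        with pytest.raises(ValueError):
            expectation_label(None, True)


class TestLatencies:
    def test_simple_differences(self):
        laps = [
            make_lap(0, t0=10.0, t_enter_threat=14.0, t_exit_threat=15.0,
                     t_enter_end_reward=18.0),
            make_lap(1, t0=20.0, t_enter_threat=24.0, t_exit_threat=25.0,
                     t_enter_end_reward=28.0),
        ]
        lat = latency_metrics(laps)
        assert lat.loc[0, "to_threat"] == pytest.approx(4.0)
        assert lat.loc[0, "to_reward"] == pytest.approx(3.0)
        assert lat.loc[0, "to_initiate"] == pytest.approx(2.0)
        assert np.isnan(lat.loc[1, "to_initiate"])

    def test_matches_event_log_walk(self, p5_session, geometry):
        events = detect_roi_events(p5_session["tracking"], geometry)
        laps = segment_laps(events, geometry, p5_session["puffs"], p5_session["leds"])
        lat = latency_metrics(laps)
        # oracle: walk the raw event list
        for i, lap in enumerate(laps):
            assert lat.loc[i, "to_threat"] == pytest.approx(
                lap.t_enter_threat - lap.t_exit_reward
            )
            assert lat.loc[i, "to_threat"] > 0
            assert lat.loc[i, "to_reward"] > 0


class TestSpeedTimecourse:
    def test_constant_speed_flat_profile(self):
        t = np.arange(0, 20, 1 / 30)
        tr = TrackingSeries(t, np.zeros_like(t), 12.0 * t)
        lap = make_lap(t0=2.0, t_enter_threat=8.0, t_exit_threat=9.0, t_enter_end_reward=12.0)
        prof = speed_timecourse([lap], tr, ["a"], window=(-2, 2), bin_width=0.5)
        assert np.allclose(prof["mean"], 12.0)

    def test_two_lap_group_average(self):
        t = np.arange(0, 20, 1 / 30)
        tr1 = TrackingSeries(t, np.zeros_like(t), 10.0 * t)
        lap = make_lap(t0=2.0, t_enter_threat=8.0, t_exit_threat=9.0, t_enter_end_reward=12.0)
        p1 = speed_timecourse([lap], tr1, ["a"], window=(-1, 1), bin_width=0.5)
        tr3 = TrackingSeries(t, np.zeros_like(t), 30.0 * t)
        p3 = speed_timecourse([lap], tr3, ["a"], window=(-1, 1), bin_width=0.5)
        assert np.allclose((p1["mean"] + p3["mean"]) / 2, 20.0)

    def test_uneven_bin_rejected(self):
        t = np.arange(0, 20, 1 / 30)
        tr = TrackingSeries(t, t, t)
        with pytest.raises(ValueError):
            speed_timecourse([make_lap()], tr, ["a"], window=(-1, 1), bin_width=0.3)


def test_planted_speed_expectation_link_across_mice(schedule, geometry):
    """Higher threat value slows the approach: ht-p slower than lt-p late in
    learning, by sign test across simulated mice."""
    from scipy.stats import binomtest

    from threatmaze.synthetic import AgentConfig, agent_laps_to_frame, simulate_agent

    wins = 0
    n_mice = 20
    for m in range(n_mice):
        rng = np.random.default_rng(1000 + m)
        laps = simulate_agent(AgentConfig(laps_per_session=40), schedule, rng)
        df = agent_laps_to_frame(laps)
        late = df[df["session"].isin(["P4", "P5"])]
        ht = late.loc[late["path"] == "ht-p", "approach_speed"].mean()
        lt = late.loc[late["path"] == "lt-p", "approach_speed"].mean()
        wins += int(ht < lt)
    assert binomtest(wins, n_mice, 0.5, alternative="greater").pvalue < 0.01
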