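"""Behavioral analysis of probabilistic spatial threat learning.

Mice shuttle between two reward sites at opposite corners of a square maze,
passing through one of two threat sites (maze corners) where an air puff is
delivered with a path-specific probability.  This module turns raw position
tracking plus a maze description into laps, path-choice metrics, approach /
reaction speeds, and per-lap "expected" vs "surprising" outcome labels
inferred from a median split of approach speed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Rect",
    "MazeGeometry",
    "StageSession",
    "StageSchedule",
    "TrackingSeries",
    "RoiEvent",
    "Lap",
    "SpeedWindows",
    "detect_roi_events",
    "segment_laps",
    "adaptive_choice_fraction",
    "speed_metrics",
    "median_split",
    "expectation_label",
    "latency_metrics",
    "speed_timecourse",
    "laps_to_frame",
    "laps_from_frame",
]

LAP_COLUMNS = [
    "index",
    "session",
    "start_site",
    "end_site",
    "path",
    "lap_class",
    "threat_delivered",
    "led",
    "t_exit_reward",
    "t_enter_threat",
    "t_exit_threat",
    "t_enter_end_reward",
]


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle, half-open: [xmin, xmax) x [ymin, ymax).

    Half-open edges guarantee that adjacent rectangles cannot both contain
    the same point, so ROI membership is unambiguous.
    """

    xmin: float
    ymin: float
    xmax: float
    ymax: float

    def __post_init__(self) -> None:
        if not (self.xmin < self.xmax and self.ymin < self.ymax):
            raise ValueError(f"degenerate rectangle: {self}")

    def contains(self, x, y):
        """Vectorized point-in-rectangle test (half-open)."""
        x = np.asarray(x)
        y = np.asarray(y)
        return (x >= self.xmin) & (x < self.xmax) & (y >= self.ymin) & (y < self.ymax)

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.xmin + self.xmax), 0.5 * (self.ymin + self.ymax))


@dataclass(frozen=True)
class MazeGeometry:
    """Square maze with two reward corners and two threat corners.

    ``path_ids`` maps each threat-ROI id to the label of the path it sits
    on (e.g. ``"ht-p"`` / ``"lt-p"``, or ``"threat"`` / ``"no-threat"`` in
    the deterministic paradigm).
    """

    side_length: float = 75.0
    reward_rois: Mapping[str, Rect] = field(
        default_factory=lambda: {
            "RW_A": Rect(0.0, 0.0, 20.0, 20.0),
            "RW_B": Rect(55.0, 55.0, 75.0, 75.0),
        }
    )
    threat_rois: Mapping[str, Rect] = field(
        default_factory=lambda: {
            "TH_L": Rect(0.0, 55.0, 8.0, 75.0),
            "TH_R": Rect(55.0, 0.0, 75.0, 8.0),
        }
    )
    path_ids: Mapping[str, str] = field(
        default_factory=lambda: {"TH_L": "ht-p", "TH_R": "lt-p"}
    )

    def __post_init__(self) -> None:
        if len(self.reward_rois) != 2 or len(self.threat_rois) != 2:
            raise ValueError("geometry needs exactly two reward and two threat ROIs")
        if set(self.path_ids) != set(self.threat_rois):
            raise ValueError("path_ids must map every threat ROI")
        rects = list(self.reward_rois.values()) + list(self.threat_rois.values())
        for i, a in enumerate(rects):
            for b in rects[i + 1 :]:
                if a.xmin < b.xmax and b.xmin < a.xmax and a.ymin < b.ymax and b.ymin < a.ymax:
                    raise ValueError("ROIs overlap")

    @property
    def rois(self) -> dict[str, Rect]:
        return {**self.reward_rois, **self.threat_rois}

    def roi_kind(self, roi_id: str) -> str:
        if roi_id in self.reward_rois:
            return "reward"
        if roi_id in self.threat_rois:
            return "threat"
        raise KeyError(roi_id)

    def path_of(self, threat_roi: str) -> str:
        return self.path_ids[threat_roi]

    def low_threat_path(self, session: "StageSession") -> str:
        """Path label with the lower scheduled threat probability."""
        if session.p_threat_lt > session.p_threat_ht:
            raise ValueError("schedule has p_lt > p_ht; labels are swapped")
        return "lt-p" if "lt-p" in self.path_ids.values() else min(
            self.path_ids.values()
        )


@dataclass(frozen=True)
class StageSession:
    """One daily session with its per-path threat probabilities."""

    label: str
    p_threat_ht: float
    p_threat_lt: float
    led_policy: Literal["none", "half_of_puffs", "all_puffs"] = "none"

    def __post_init__(self) -> None:
        for p in (self.p_threat_ht, self.p_threat_lt):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0,1]: {p}")


@dataclass(frozen=True)
class StageSchedule:
    """Ordered training schedule (e.g. T1-5, P1-5, R1-5)."""

    sessions: tuple[StageSession, ...]

    def __post_init__(self) -> None:
        labels = [s.label for s in self.sessions]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate session labels")

    def __iter__(self):
        return iter(self.sessions)

    def __getitem__(self, label: str) -> StageSession:
        for s in self.sessions:
            if s.label == label:
                return s
        raise KeyError(label)

    @staticmethod
    def probabilistic(led_policy: str = "none") -> "StageSchedule":
        """The standard 15-day design: pre-training, 75/25, 50/50."""
        sessions = (
            [StageSession(f"T{i}", 0.0, 0.0, "none") for i in range(1, 6)]
            + [StageSession(f"P{i}", 0.75, 0.25, led_policy) for i in range(1, 6)]
            + [StageSession(f"R{i}", 0.50, 0.50, led_policy) for i in range(1, 6)]
        )
        return StageSchedule(tuple(sessions))

    @staticmethod
    def deterministic(led_policy: str = "none") -> "StageSchedule":
        sessions = [StageSession(f"T{i}", 0.0, 0.0, "none") for i in range(1, 6)] + [
            StageSession(f"D{i}", 1.0, 0.0, led_policy) for i in range(1, 4)
        ]
        return StageSchedule(tuple(sessions))


@dataclass
class TrackingSeries:
    """Position tracking: time (s), x/y (cm), nominally 30 Hz."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    nominal_rate: float = 30.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")
        if len(self.t) and np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    @staticmethod
    def from_csv(path) -> "TrackingSeries":
        df = pd.read_csv(path)
        return TrackingSeries(df["time_s"].to_numpy(), df["x_cm"].to_numpy(), df["y_cm"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.t, "x_cm": self.x, "y_cm": self.y}).to_csv(
            path, index=False
        )


@dataclass(frozen=True)
class RoiEvent:
    time: float
    roi: str
    kind: Literal["enter", "exit"]


@dataclass
class Lap:
    index: int
    session: str
    start_site: str
    end_site: str
    path: str
    lap_class: Literal["full", "half"]
    threat_delivered: bool
    led: bool
    t_exit_reward: float
    t_enter_threat: float
    t_exit_threat: float
    t_enter_end_reward: float

    def __post_init__(self) -> None:
        ts = [self.t_exit_reward, self.t_enter_threat, self.t_exit_threat, self.t_enter_end_reward]
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise ValueError(f"lap timestamps not monotone: {ts}")
        if (self.lap_class == "half") != (self.start_site == self.end_site):
            raise ValueError("half lap iff start_site == end_site")


@dataclass
class SpeedWindows:
    """Approach / reaction speeds (cm/s) around a threat-site entry."""

    approach: float
    reaction: float
    fast_slow: Literal["fast", "slow", None] = None
    expectation: Literal["expected", "surprising", None] = None
    valid: bool = True


def laps_to_frame(laps: Sequence[Lap]) -> pd.DataFrame:
    return pd.DataFrame([vars(lap) for lap in laps], columns=LAP_COLUMNS)


def laps_from_frame(df: pd.DataFrame) -> list[Lap]:
    return [
        Lap(
            index=int(r["index"]),
            session=str(r["session"]),
            start_site=str(r["start_site"]),
            end_site=str(r["end_site"]),
            path=str(r["path"]),
            lap_class=str(r["lap_class"]),
            threat_delivered=bool(r["threat_delivered"]),
            led=bool(r["led"]),
            t_exit_reward=float(r["t_exit_reward"]),
            t_enter_threat=float(r["t_enter_threat"]),
            t_exit_threat=float(r["t_exit_threat"]),
            t_enter_end_reward=float(r["t_enter_end_reward"]),
        )
        for _, r in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# ROI events


def detect_roi_events(tracking: TrackingSeries, geometry: MazeGeometry) -> list[RoiEvent]:
    """Detect ROI enter/exit events from position samples.

    Entry is timestamped at the first sample strictly inside the (half-open)
    rectangle; exit at the first sample outside after a visit.  Events per
    ROI strictly alternate enter/exit.  Gaps > 1 s between samples are
    logged as warnings.
    """
    if len(tracking) == 0:
        raise ValueError("empty tracking series")
    gaps = np.diff(tracking.t)
    n_gaps = int(np.sum(gaps > 1.0))
    if n_gaps:
        logger.warning("%d tracking gaps exceed 1 s", n_gaps)

    events: list[RoiEvent] = []
    for roi_id, rect in geometry.rois.items():
        inside = rect.contains(tracking.x, tracking.y)
        flips = np.flatnonzero(np.diff(inside.astype(np.int8)))
        if inside[0]:
            events.append(RoiEvent(float(tracking.t[0]), roi_id, "enter"))
        for i in flips:
            kind = "enter" if inside[i + 1] else "exit"
            events.append(RoiEvent(float(tracking.t[i + 1]), roi_id, kind))
    events.sort(key=lambda e: (e.time, e.kind == "enter"))
    return events


def _match_log(times: np.ndarray, entries: np.ndarray, tol: float, what: str) -> np.ndarray:
    """Match event-log timestamps to threat-site entry times within tol."""
    matched = np.zeros(len(entries), dtype=bool)
    for t in times:
        d = np.abs(entries - t)
        i = int(np.argmin(d)) if len(d) else -1
        if i < 0 or d[i] > tol:
            raise ValueError(f"{what} at t={t:.3f}s matches no threat-site entry within {tol}s")
        matched[i] = True
    return matched


def segment_laps(
    events: Sequence[RoiEvent],
    geometry: MazeGeometry,
    puff_times: Iterable[float] = (),
    led_times: Iterable[float] = (),
    session: str = "",
    *,
    merge_gap: float = 2.0,
    match_tol: float = 0.5,
) -> list[Lap]:
    """Segment ROI events into full / half laps.

    A *full* lap: reward-site exit -> threat-site pass -> other reward site.
    A *half* lap returns to the same reward site after entering a threat
    site.  Reward-to-reward excursions that never enter a threat ROI are not
    laps.  Re-entries into the same threat ROI within ``merge_gap`` seconds
    of exiting it are merged into one visit (tracking jitter at borders).
    Puff/LED log timestamps are attributed to the nearest threat-site entry
    within ``match_tol`` seconds; unmatched timestamps raise.
    """
    # collapse threat visits: (roi, t_enter, t_exit)
    visits: list[list] = []  # [roi, t_enter, t_exit]
    open_visit: dict[str, list] = {}
    reward_ev: list[tuple[float, str, str]] = []
    for ev in events:
        kind = geometry.roi_kind(ev.roi)
        if kind == "reward":
            reward_ev.append((ev.time, ev.roi, ev.kind))
            continue
        if ev.kind == "enter":
            if visits and visits[-1][0] == ev.roi and ev.time - visits[-1][2] <= merge_gap and not open_visit:
                open_visit[ev.roi] = visits.pop()  # merged re-entry
            else:
                open_visit[ev.roi] = [ev.roi, ev.time, math.inf]
        else:
            v = open_visit.pop(ev.roi, None)
            if v is None:
                continue  # exit without tracked entry (series started inside)
            v[2] = ev.time
            visits.append(v)
    for v in open_visit.values():  # never exited (end of session)
        visits.append(v)
    visits.sort(key=lambda v: v[1])

    laps: list[Lap] = []
    cur_exit: tuple[float, str] | None = None  # (time, reward roi) of last exit
    cur_visits: list[list] = []
    vi = 0
    for t, roi, kind in reward_ev:
        if kind == "exit":
            cur_exit = (t, roi)
            cur_visits = []
        elif kind == "enter" and cur_exit is not None:
            while vi < len(visits) and visits[vi][1] < t:
                if visits[vi][1] >= cur_exit[0]:
                    cur_visits.append(visits[vi])
                vi += 1
            if cur_visits:
                first = cur_visits[0]
                last_exit = min(cur_visits[-1][2], t)
                lap_class = "half" if roi == cur_exit[1] else "full"
                laps.append(
                    Lap(
                        index=len(laps),
                        session=session,
                        start_site=cur_exit[1],
                        end_site=roi,
                        path=geometry.path_of(first[0]),
                        lap_class=lap_class,
                        threat_delivered=False,
                        led=False,
                        t_exit_reward=cur_exit[0],
                        t_enter_threat=first[1],
                        t_exit_threat=last_exit,
                        t_enter_end_reward=t,
                    )
                )
            cur_exit = None
            cur_visits = []

    entries = np.array([lap.t_enter_threat for lap in laps])
    puffed = _match_log(np.asarray(list(puff_times), dtype=float), entries, match_tol, "puff")
    ledded = _match_log(np.asarray(list(led_times), dtype=float), entries, match_tol, "led")
    for lap, p, l in zip(laps, puffed, ledded):
        lap.threat_delivered = bool(p)
        lap.led = bool(l)
    return laps


# ---------------------------------------------------------------------------
# Choice and speed metrics


def adaptive_choice_fraction(laps: Sequence[Lap], low_threat_path: str = "lt-p") -> float:
    """Fraction of (full + half) laps taken on the lower-threat path."""
    if len(laps) == 0:
        raise ValueError("adaptive choice fraction undefined for zero laps")
    n_low = sum(1 for lap in laps if lap.path == low_threat_path)
    return n_low / len(laps)


def _finite_difference_speeds(tracking: TrackingSeries) -> tuple[np.ndarray, np.ndarray]:
    """Per-interval speeds (cm/s) timestamped at interval midpoints."""
    dt = np.diff(tracking.t)
    disp = np.hypot(np.diff(tracking.x), np.diff(tracking.y))
    return 0.5 * (tracking.t[:-1] + tracking.t[1:]), disp / dt


def speed_metrics(
    lap: Lap,
    tracking: TrackingSeries,
    window: float = 0.5,
    *,
    smooth: int | None = None,
) -> SpeedWindows:
    """Approach / reaction speed around the lap's threat-site entry.

    Approach: mean finite-difference speed over the ``window`` seconds
    immediately before ``t_enter_threat``; reaction: the window immediately
    after.  No smoothing by default (the 500-ms average already suppresses
    frame jitter); pass ``smooth=n`` for an n-sample moving average.
    Windows reaching beyond the recording mark the result invalid.
    """
    tm, sp = _finite_difference_speeds(tracking)
    if smooth and smooth > 1:
        kernel = np.ones(smooth) / smooth
        sp = np.convolve(sp, kernel, mode="same")
    t0 = lap.t_enter_threat
    if t0 - window < tracking.t[0] or t0 + window > tracking.t[-1]:
        return SpeedWindows(np.nan, np.nan, valid=False)
    pre = (tm > t0 - window) & (tm <= t0)
    post = (tm > t0) & (tm <= t0 + window)
    if pre.sum() < 2 or post.sum() < 2:
        return SpeedWindows(np.nan, np.nan, valid=False)
    return SpeedWindows(float(sp[pre].mean()), float(sp[post].mean()))


def median_split(approach_speeds: Sequence[float]) -> list[str]:
    """Label laps 'slow' (strictly below the session median) or 'fast'.

    Speeds at the median go to 'fast', keeping 'slow' strictly sub-median.
    All-identical speeds thus yield all-fast (warned).
    """
    speeds = np.asarray(approach_speeds, dtype=float)
    if np.sum(np.isfinite(speeds)) < 4:
        raise ValueError("median split needs >= 4 laps with valid approach speed")
    med = float(np.nanmedian(speeds))
    labels = ["slow" if s < med else "fast" for s in speeds]
    if all(lab == "fast" for lab in labels):
        logger.warning("all approach speeds at/above the median; no slow laps")
    return labels


def expectation_label(fast_slow: str, threat_delivered: bool) -> str:
    """Expected vs surprising outcome from approach speed x outcome.

    Slow approach signals the mouse expected a threat, so: fast+threat and
    slow+omission are surprising; slow+threat and fast+omission expected.
    """
    if fast_slow not in ("fast", "slow"):
        raise ValueError(f"fast_slow must be 'fast' or 'slow', got {fast_slow!r}")
    surprising = (fast_slow == "fast") == bool(threat_delivered)
    return "surprising" if surprising else "expected"


def latency_metrics(laps: Sequence[Lap]) -> pd.DataFrame:
    """Per-lap latencies (s): to_threat, to_reward, to_initiate.

    to_initiate is the dwell in the end reward site before the *next* lap's
    reward-site exit; absent (NaN) for the last lap of a session.
    """
    rows = []
    for i, lap in enumerate(laps):
        nxt = laps[i + 1] if i + 1 < len(laps) else None
        to_initiate = (
            nxt.t_exit_reward - lap.t_enter_end_reward
            if nxt is not None and nxt.session == lap.session
            else np.nan
        )
        rows.append(
            {
                "index": lap.index,
                "session": lap.session,
                "to_threat": lap.t_enter_threat - lap.t_exit_reward,
                "to_reward": lap.t_enter_end_reward - lap.t_exit_threat,
                "to_initiate": to_initiate,
            }
        )
    return pd.DataFrame(rows)


def speed_timecourse(
    laps: Sequence[Lap],
    tracking: TrackingSeries,
    groups: Mapping[int, str] | Sequence[str],
    window: tuple[float, float] = (-2.0, 2.0),
    bin_width: float = 0.1,
) -> pd.DataFrame:
    """Mean +/- SEM speed per time bin around threat entry, per lap group.

    ``groups`` assigns a group label per lap (by position).  Returns a tidy
    frame (group, t_center, mean, sem, n).  Empty groups are simply absent.
    """
    n_bins = (window[1] - window[0]) / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("bin_width must evenly divide the window")
    n_bins = int(round(n_bins))
    if not isinstance(groups, Mapping):
        groups = dict(enumerate(groups))
    tm, sp = _finite_difference_speeds(tracking)
    edges = np.linspace(window[0], window[1], n_bins + 1)
    per_group: dict[str, list[np.ndarray]] = {}
    for i, lap in enumerate(laps):
        label = groups.get(i)
        if label is None:
            continue
        rel = tm - lap.t_enter_threat
        prof = np.full(n_bins, np.nan)
        idx = np.digitize(rel, edges) - 1
        ok = (idx >= 0) & (idx < n_bins)
        for b in range(n_bins):
            sel = ok & (idx == b)
            if sel.any():
                prof[b] = sp[sel].mean()
        per_group.setdefault(str(label), []).append(prof)
    rows = []
    centers = 0.5 * (edges[:-1] + edges[1:])
    for label, profiles in per_group.items():
        arr = np.vstack(profiles)
        n = np.sum(np.isfinite(arr), axis=0)
        mean = np.nanmean(arr, axis=0)
        with np.errstate(invalid="ignore"):
            sem = np.nanstd(arr, axis=0, ddof=1) / np.sqrt(np.maximum(n, 1))
        for c, m, s, k in zip(centers, mean, sem, n):
            rows.append({"group": label, "t_center": c, "mean": m, "sem": s, "n": int(k)})
    return pd.DataFrame(rows)
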