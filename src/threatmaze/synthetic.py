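"""Synthetic maze behavior and calcium traces with known ground truth.

The generator is a test harness, not a model of mice: a Rescorla-Wagner
learner with softmax path choice produces lap sequences under any stage
schedule; a trajectory synthesizer renders those laps as 30-Hz position
tracking on the square maze; and a calcium synthesizer renders per-cell
20-Hz traces whose event-locked transients encode outcomes, signed or
unsigned prediction errors, or expectations, on top of Gaussian noise.

Prediction errors follow the aversive convention: positive for unexpected
threat delivery, negative for unexpected threat omission
(PE = outcome - V, outcome 1 for a puff and 0 for an omission).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import MazeGeometry, StageSchedule, TrackingSeries

__all__ = [
    "AgentConfig",
    "CellSpec",
    "AgentLap",
    "agent_laps_to_frame",
    "simulate_agent",
    "simulate_tracking",
    "simulate_calcium",
    "default_cell_population",
]


@dataclass
class AgentConfig:
    """Rescorla-Wagner + softmax agent with an expectation-linked speed model.

    Per-path threat values V in [0, 1] are updated as V += alpha * PE with
    PE = outcome - V; paths are drawn with p(path) proportional to
    exp(-V/temperature), so higher threat value means lower choice
    probability.  Approach speed is base - slope*V + noise (slower when a
    threat is expected); reaction speed accelerates after surprising
    threats and lags after surprising omissions via ``reaction_gain`` * PE.
    ``switch_override`` decouples choice from the learned values entirely
    (the behavioral signature of the opsin groups): the agent switches to
    the alternate path after every threat lap and chooses at random after
    omissions, so its choice reflects only the last outcome, never the
    integrated threat history.
    """

    alpha_pos: float = 0.3  # learning rate for positive PEs (threats)
    alpha_neg: float = 0.3  # for negative PEs (omissions)
    softmax_temperature: float = 0.25
    v0: float = 0.5
    base_speed: float = 30.0  # cm/s
    expectation_slope: float = 20.0  # cm/s per unit V
    speed_noise_sd: float = 2.0
    reaction_gain: float = 10.0  # cm/s per unit PE
    min_speed: float = 5.0
    half_lap_prob: float = 0.05
    laps_per_session: int = 60
    switch_override: bool = False

    def __post_init__(self) -> None:
        for a in (self.alpha_pos, self.alpha_neg):
            if not 0.0 <= a <= 1.0:
                raise ValueError("learning rates must be in [0,1]")
        if self.softmax_temperature <= 0:
            raise ValueError("softmax temperature must be positive")


@dataclass
class AgentLap:
    """One simulated lap with its latent agent state."""

    session: str
    index: int
    start_site: str
    end_site: str
    path: str
    lap_class: str
    threat_delivered: bool
    led: bool
    pe: float
    v_path: float  # value of the chosen path before the update
    v_ht: float
    v_lt: float
    approach_speed: float
    reaction_speed: float


def simulate_agent(
    config: AgentConfig,
    schedule: StageSchedule,
    rng: np.random.Generator,
    ht_path: str = "ht-p",
    lt_path: str = "lt-p",
) -> list[AgentLap]:
    """Run the agent through a stage schedule, emitting one record per lap."""
    v = {ht_path: config.v0, lt_path: config.v0}
    laps: list[AgentLap] = []
    site = "RW_A"
    forced_switch_from: str | None = None
    for sess in schedule:
        p_threat = {ht_path: sess.p_threat_ht, lt_path: sess.p_threat_lt}
        for i in range(config.laps_per_session):
            if config.switch_override:
                if forced_switch_from is not None:
                    path = lt_path if forced_switch_from == ht_path else ht_path
                else:
                    path = ht_path if rng.random() < 0.5 else lt_path
            else:
                dv = (v[lt_path] - v[ht_path]) / config.softmax_temperature
                p_ht = 1.0 / (1.0 + math.exp(-dv))
                path = ht_path if rng.random() < p_ht else lt_path
            threat = bool(rng.random() < p_threat[path])
            if sess.led_policy == "all_puffs":
                led = threat
            elif sess.led_policy == "half_of_puffs":
                led = threat and bool(rng.random() < 0.5)
            else:
                led = False
            v_before = v[path]
            pe = (1.0 if threat else 0.0) - v_before
            alpha = config.alpha_pos if pe > 0 else config.alpha_neg
            v[path] = v_before + alpha * pe
            approach = max(
                config.min_speed,
                config.base_speed
                - config.expectation_slope * v_before
                + rng.normal(0.0, config.speed_noise_sd),
            )
            reaction = max(
                config.min_speed,
                config.base_speed + config.reaction_gain * pe + rng.normal(0.0, config.speed_noise_sd),
            )
            half = bool(rng.random() < config.half_lap_prob)
            end = site if half else ("RW_B" if site == "RW_A" else "RW_A")
            laps.append(
                AgentLap(
                    session=sess.label,
                    index=i,
                    start_site=site,
                    end_site=end,
                    path=path,
                    lap_class="half" if half else "full",
                    threat_delivered=threat,
                    led=led,
                    pe=pe,
                    v_path=v_before,
                    v_ht=v[ht_path],
                    v_lt=v[lt_path],
                    approach_speed=approach,
                    reaction_speed=reaction,
                )
            )
            forced_switch_from = path if threat else None
            site = end
    return laps


def agent_laps_to_frame(laps: list[AgentLap]) -> pd.DataFrame:
    return pd.DataFrame([vars(l) for l in laps])


# ---------------------------------------------------------------------------
# Tracking synthesis


def _route(geometry: MazeGeometry, start_site: str, threat_roi: str, end_site: str):
    """Polyline through ROI centers for one lap (possibly a turnaround)."""
    a = geometry.reward_rois[start_site].center
    t = geometry.threat_rois[threat_roi].center
    b = geometry.reward_rois[end_site].center
    if start_site == end_site:
        return [a, t, a]
    return [a, t, b]


def _first_crossing(points, rect) -> float:
    """Arc length at which the polyline first enters the rectangle."""
    s = 0.0
    for (x0, y0), (x1, y1) in zip(points, points[1:]):
        seg = math.hypot(x1 - x0, y1 - y0)
        # scan finely; exact edge crossing is not needed, only the speed
        # profile anchor (<1 mm error at 2000 steps)
        for frac in np.linspace(0.0, 1.0, 2001):
            if rect.contains(x0 + frac * (x1 - x0), y0 + frac * (y1 - y0)):
                return s + frac * seg
        s += seg
    raise ValueError("route never enters the threat ROI")


def simulate_tracking(
    laps: list[AgentLap],
    geometry: MazeGeometry | None = None,
    rng: np.random.Generator | None = None,
    dt: float = 1.0 / 30.0,
    dwell: float = 2.0,
    approach_window: float = 0.5,
    base_speed: float = 30.0,
):
    """Render agent laps as a 30-Hz tracking series plus event logs.

    Each lap follows the polyline reward-center -> threat-center ->
    end-reward-center at the lap's base speed, switching to the scheduled
    approach speed over the ``approach_window``-plus-margin stretch before
    the threat-ROI entry and to the reaction speed for an equal stretch
    after it.  Between laps the mouse dwells at the reward center.  Returns
    ``(tracking, puff_times, led_times, entry_times)``; puff/LED events are
    stamped 100 ms after the threat-site entry.
    """
    geometry = geometry or MazeGeometry()
    rng = rng or np.random.default_rng(0)
    roi_by_path = {p: roi for roi, p in geometry.path_ids.items()}
    t_list: list[float] = []
    xy: list[tuple[float, float]] = []
    puffs: list[float] = []
    leds: list[float] = []
    entries: list[float] = []
    clock = 0.0

    def emit_dwell(center, duration):
        nonlocal clock
        n = max(1, int(round(duration / dt)))
        for _ in range(n):
            jitter = rng.normal(0.0, 0.05, size=2)
            t_list.append(clock)
            xy.append((center[0] + jitter[0], center[1] + jitter[1]))
            clock += dt

    if laps:
        emit_dwell(geometry.reward_rois[laps[0].start_site].center, dwell)
    for lap in laps:
        roi = roi_by_path[lap.path]
        pts = _route(geometry, lap.start_site, roi, lap.end_site)
        s_entry = _first_crossing(pts, geometry.threat_rois[roi])
        seg_len = [math.hypot(b[0] - a[0], b[1] - a[1]) for a, b in zip(pts, pts[1:])]
        total = sum(seg_len)
        margin = 1.6 * approach_window  # covers the window plus entry-detection lag
        a_start = max(0.0, s_entry - lap.approach_speed * margin)
        r_end = min(total, s_entry + lap.reaction_speed * margin)

        def speed_at(s):
            if a_start <= s < s_entry:
                return lap.approach_speed
            if s_entry <= s < r_end:
                return lap.reaction_speed
            return base_speed

        cum = np.concatenate([[0.0], np.cumsum(seg_len)])

        def point_at(s):
            s = min(s, total - 1e-9)
            k = int(np.searchsorted(cum, s, side="right")) - 1
            k = min(k, len(seg_len) - 1)
            frac = (s - cum[k]) / seg_len[k]
            (x0, y0), (x1, y1) = pts[k], pts[k + 1]
            return (x0 + frac * (x1 - x0), y0 + frac * (y1 - y0))

        s = 0.0
        entered = False
        while s < total:
            s += speed_at(s) * dt
            if s >= total:
                break
            t_list.append(clock)
            xy.append(point_at(s))
            if not entered and s >= s_entry:
                entered = True
                entries.append(clock)
                if lap.threat_delivered:
                    puffs.append(clock + 0.1)
                if lap.led:
                    leds.append(clock + 0.1)
            clock += dt
        emit_dwell(geometry.reward_rois[lap.end_site].center, dwell + rng.uniform(0, 0.5))

    arr = np.asarray(xy).reshape(-1, 2)
    tracking = TrackingSeries(np.asarray(t_list), arr[:, 0], arr[:, 1])
    return tracking, np.asarray(puffs), np.asarray(leds), np.asarray(entries)


# ---------------------------------------------------------------------------
# Calcium synthesis


@dataclass
class CellSpec:
    """Generative spec for one synthetic cell.

    kind: 'outcome' (fixed-amplitude transient on ``outcome`` laps of
    ``path``), 'signed_pe' (amplitude proportional to PE, dipping for
    negative PE), 'unsigned_pe' (proportional to |PE|), 'expectation'
    (pre-entry ramp proportional to V), or 'none'.

    Every cell additionally carries a fixed, smooth approach-corridor
    tuning template (SD ``tuning_sd``) replayed at each threat-site entry
    and tapering off shortly after entry.  This mimics the stereotyped
    location/locomotion activity of prefrontal cells on the run-up to the
    corner; because it repeats across laps it does not average out, so the
    baseline SD of a lap-averaged trace stays finite instead of collapsing
    as 1/sqrt(laps), keeping z magnitudes in a realistic range.
    """

    cell_id: str
    kind: str
    amplitude: float = 1.0
    path: str | None = None  # for outcome cells
    outcome: str | None = None  # 'threat' | 'omission' for outcome cells
    noise_sd: float = 0.25
    tuning_sd: float = 0.0625  # SD of the replayed approach template
    rise_tau: float = 0.05  # s, GCaMP6f-like
    decay_tau: float = 0.5  # s
    led_gain: float = 1.0  # amplitude multiplier on LED laps ("opsin-like")

    def __post_init__(self) -> None:
        if self.kind not in ("outcome", "signed_pe", "unsigned_pe", "expectation", "none"):
            raise ValueError(f"unknown cell kind {self.kind!r}")
        if self.kind == "outcome" and (self.path is None or self.outcome not in ("threat", "omission")):
            raise ValueError("outcome cells need path and outcome")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


def _kernel(rise_tau: float, decay_tau: float, rate: float, duration: float = 3.0) -> np.ndarray:
    """Double-exponential transient, peak-normalized to 1."""
    t = np.arange(0.0, duration, 1.0 / rate)
    k = np.exp(-t / decay_tau) - np.exp(-t / rise_tau)
    return k / k.max()


def _tuning_template(rng: np.random.Generator, rate: float, sd: float) -> tuple[np.ndarray, int]:
    """Smooth per-cell approach-corridor activity, replayed at every entry.

    Covers -1.25 s .. +2.05 s around the threat-site entry, scaled to the
    requested SD over the pre-entry second and exponentially tapered (tau
    150 ms) after entry, where the mouse has run past the tuned stretch.
    Returns (template, pre_samples).
    """
    pre, post = 1.25, 2.05
    n_pre = int(round(pre * rate))
    n = n_pre + int(round(post * rate))
    white = rng.normal(0.0, 1.0, size=n + 20)
    width = max(1, int(round(0.15 * rate)))
    g = np.exp(-0.5 * (np.arange(-3 * width, 3 * width + 1) / width) ** 2)
    smooth = np.convolve(white, g / g.sum(), mode="same")[10 : 10 + n]
    base_sd = smooth[:n_pre].std()
    if base_sd > 0:
        smooth = smooth * (sd / base_sd)
    t_post = np.arange(n - n_pre) / rate
    smooth[n_pre:] *= np.exp(-t_post / 0.15)
    return smooth, n_pre


def default_cell_population(
    n_cells: int = 100,
    rng: np.random.Generator | None = None,
    snr: float = 4.0,
    fractions: dict | None = None,
) -> list[CellSpec]:
    """A mixed population: planted PE coders, outcome cells, silent cells.

    ``snr`` is transient amplitude over baseline noise SD.  Default mix:
    20% signed-PE, 10% unsigned-PE, 30% outcome (split over path/outcome),
    10% expectation, 30% none.
    """
    rng = rng or np.random.default_rng(0)
    fractions = fractions or {
        "signed_pe": 0.2,
        "unsigned_pe": 0.1,
        "outcome": 0.3,
        "expectation": 0.1,
        "none": 0.3,
    }
    noise_sd = 0.25
    amp = snr * noise_sd
    kinds = []
    for kind, frac in fractions.items():
        kinds += [kind] * int(round(frac * n_cells))
    kinds = kinds[:n_cells] + ["none"] * (n_cells - len(kinds))
    rng.shuffle(kinds)
    combos = [("ht-p", "threat"), ("ht-p", "omission"), ("lt-p", "threat"), ("lt-p", "omission")]
    specs = []
    for i, kind in enumerate(kinds):
        path = outcome = None
        if kind == "outcome":
            path, outcome = combos[i % 4]
        specs.append(
            CellSpec(
                cell_id=f"cell{i:03d}",
                kind=kind,
                amplitude=amp if kind != "none" else 0.0,
                path=path,
                outcome=outcome,
                noise_sd=noise_sd,
            )
        )
    return specs


def simulate_calcium(
    laps: list[AgentLap],
    entry_times: np.ndarray,
    cell_specs: list[CellSpec],
    rng: np.random.Generator,
    rate: float = 20.0,
    t_end: float | None = None,
):
    """Render per-cell 20-Hz traces with event-locked transients.

    Outcome transients are placed at entry + 100 ms (the puff latency);
    expectation cells ramp linearly over the second before entry with slope
    proportional to the pre-update path value.  Returns ``(TraceMatrix,
    ground_truth DataFrame)``.
    """
    from .neural import TraceMatrix

    if len(entry_times) != len(laps):
        raise ValueError("one entry time per lap required")
    if t_end is None:
        t_end = (entry_times[-1] if len(entry_times) else 0.0) + 10.0
    t = np.arange(0.0, t_end, 1.0 / rate)
    n = len(t)
    values = np.empty((n, len(cell_specs)))
    truth = []
    ramp_len = int(rate)  # 1-s pre-entry ramp for expectation cells
    for ci, spec in enumerate(cell_specs):
        trace = rng.normal(0.0, spec.noise_sd, size=n)
        kern = _kernel(spec.rise_tau, spec.decay_tau, rate)
        template, n_pre = _tuning_template(rng, rate, spec.tuning_sd)
        for t_entry in entry_times:
            start = int(round(t_entry * rate)) - n_pre
            if start >= 0 and start + len(template) <= n:
                trace[start : start + len(template)] += template
        for lap, t_entry in zip(laps, entry_times):
            amp = 0.0
            if spec.kind == "outcome":
                hit = lap.path == spec.path and (
                    lap.threat_delivered if spec.outcome == "threat" else not lap.threat_delivered
                )
                if hit:
                    amp = spec.amplitude * (spec.led_gain if lap.led else 1.0)
            elif spec.kind == "signed_pe":
                amp = spec.amplitude * lap.pe
            elif spec.kind == "unsigned_pe":
                amp = spec.amplitude * abs(lap.pe)
            elif spec.kind == "expectation":
                start = int(round((t_entry - 1.0) * rate))
                if start >= 0 and start + ramp_len <= n:
                    trace[start : start + ramp_len] += (
                        spec.amplitude * lap.v_path * np.linspace(0.0, 1.0, ramp_len)
                    )
                continue
            if amp != 0.0:
                onset = int(round((t_entry + 0.1) * rate))
                if 0 <= onset < n:
                    seg = min(len(kern), n - onset)
                    trace[onset : onset + seg] += amp * kern[:seg]
        values[:, ci] = trace
        truth.append(
            {
                "cell": spec.cell_id,
                "kind": spec.kind,
                "path": spec.path,
                "outcome": spec.outcome,
                "amplitude": spec.amplitude,
            }
        )
    return TraceMatrix(t, values, [s.cell_id for s in cell_specs]), pd.DataFrame(truth)
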