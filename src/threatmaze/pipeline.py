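"""End-to-end analysis stages tying behavior, neural, and history modules.

These helpers operate on in-memory objects; the CLI wraps them with file
I/O.  The canonical flow per session is: tracking -> ROI events -> laps ->
approach/reaction speeds -> per-session median split -> expectation labels;
calcium traces are then aligned to the lap threat-site entries and reduced
to per-lap-type response magnitudes for responder and prediction-error
classification.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import behavior, choice_history, neural
from .behavior import MazeGeometry, TrackingSeries

__all__ = [
    "behavioral_lap_table",
    "add_expectation_labels",
    "lap_type_masks",
    "response_magnitude_table",
    "pe_classification_run",
]


def behavioral_lap_table(
    tracking: TrackingSeries,
    geometry: MazeGeometry,
    puff_times=(),
    led_times=(),
    session: str = "",
    speed_window: float = 0.5,
) -> pd.DataFrame:
    """Segment one session's tracking into laps with speed metrics."""
    events = behavior.detect_roi_events(tracking, geometry)
    laps = behavior.segment_laps(events, geometry, puff_times, led_times, session)
    frame = behavior.laps_to_frame(laps)
    approach, reaction, valid = [], [], []
    for lap in laps:
        sw = behavior.speed_metrics(lap, tracking, speed_window)
        approach.append(sw.approach)
        reaction.append(sw.reaction)
        valid.append(sw.valid)
    frame["approach_speed"] = approach
    frame["reaction_speed"] = reaction
    frame["speed_valid"] = valid
    return frame


def add_expectation_labels(lap_frame: pd.DataFrame) -> pd.DataFrame:
    """Per-session median split of approach speed -> fast/slow -> labels.

    The median is computed per session over laps with valid speeds; the
    expectation label crosses fast/slow with the delivered outcome.
    """
    frame = lap_frame.copy()
    frame["fast_slow"] = pd.NA
    frame["expectation"] = pd.NA
    for sess, sub in frame.groupby("session", sort=False):
        ok = sub["speed_valid"].astype(bool) & np.isfinite(sub["approach_speed"])
        if ok.sum() < 4:
            continue
        labels = behavior.median_split(sub.loc[ok, "approach_speed"].to_numpy())
        frame.loc[sub.index[ok], "fast_slow"] = labels
        frame.loc[sub.index[ok], "expectation"] = [
            behavior.expectation_label(fs, td)
            for fs, td in zip(labels, sub.loc[ok, "threat_delivered"])
        ]
    return frame


def lap_type_masks(lap_frame: pd.DataFrame, led_free_threats: bool = True) -> dict[str, np.ndarray]:
    """Boolean masks for the standard lap types.

    Expectation x outcome types ('threat_surprising', ...) and per-path
    outcome types ('threat@ht-p', ...).  Threat lap types exclude LED laps
    when ``led_free_threats`` (isolating learning effects from direct
    stimulation effects); LED-comparison types ('puff', 'puff_led',
    'omission') are always included.
    """
    threat = lap_frame["threat_delivered"].to_numpy(dtype=bool)
    led = lap_frame["led"].to_numpy(dtype=bool)
    exp = lap_frame["expectation"].to_numpy(dtype=object) if "expectation" in lap_frame else None
    no_led_threat = threat & ~led if led_free_threats else threat
    masks: dict[str, np.ndarray] = {
        "omission": ~threat,
        "puff": threat & ~led,
        "puff_led": threat & led,
    }
    for path in pd.unique(lap_frame["path"]):
        onpath = (lap_frame["path"] == path).to_numpy()
        masks[f"threat@{path}"] = no_led_threat & onpath
        masks[f"omission@{path}"] = ~threat & onpath
    if exp is not None:
        for outcome, base in (("threat", no_led_threat), ("omission", ~threat)):
            for label in ("surprising", "expected"):
                masks[f"{outcome}_{label}"] = base & (exp == label)
    return masks


def response_magnitude_table(
    aligned: neural.AlignedTensor, masks: dict[str, np.ndarray], min_laps: int = 1
) -> pd.DataFrame:
    """Cells x lap-type response magnitudes (NaN for empty/undefined types)."""
    cols = {}
    for name, mask in masks.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.sum() < min_laps:
            cols[name] = np.full(len(aligned.cell_ids), np.nan)
            continue
        zavg = neural.lap_type_average_z(aligned, mask)
        cols[name] = neural.response_magnitude(zavg)
    return pd.DataFrame(cols, index=aligned.cell_ids)


def pe_classification_run(
    traces,
    lap_frame: pd.DataFrame,
    entry_times,
    threshold: float = 2.0,
    min_laps: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full neural stage: align, reduce, and classify PE coding per cell.

    Returns ``(magnitudes, classification)``.  Laps whose alignment window
    falls outside the recording are dropped from every lap type.
    """
    aligned = neural.align_to_event(traces, np.asarray(entry_times, dtype=float))
    kept_frame = lap_frame.iloc[aligned.kept].reset_index(drop=True)
    masks = lap_type_masks(kept_frame)
    mags = response_magnitude_table(aligned, masks, min_laps=min_laps)
    diff = neural.differential_activity(mags)
    classification = neural.classify_pe_type(diff, threshold=threshold)
    return mags, classification
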