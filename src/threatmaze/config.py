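"""Declarative run configuration.

A single YAML file carries the maze geometry, stage schedule, analysis
thresholds, cohort composition, and seed; every default equals the study
conventions (response threshold 2 z, differential threshold +/-2 z, 500-ms
speed windows, 100-ms bins over -1..+2 s, history windows k = 1..50,
alpha = 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .behavior import MazeGeometry, Rect, StageSchedule
from .synthetic import AgentConfig

__all__ = ["Thresholds", "RunConfig", "load_config"]


@dataclass(frozen=True)
class Thresholds:
    response_threshold: float = 2.0  # z, outcome responders
    differential_threshold: float = 2.0  # z, PE classification (+/-)
    speed_window: float = 0.5  # s, approach/reaction windows
    bin_width: float = 0.1  # s, alignment bins
    align_window: tuple[float, float] = (-1.0, 2.0)  # s around entry
    k_max: int = 50  # history windows 1..k_max
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if min(self.response_threshold, self.differential_threshold, self.speed_window, self.bin_width) <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class RunConfig:
    seed: int = 0
    paradigm: str = "probabilistic"  # or "deterministic"
    led_policy: str = "none"
    n_mice: int = 4
    groups: dict = field(default_factory=lambda: {"control": False, "override": True})
    agent: AgentConfig = field(default_factory=AgentConfig)
    geometry: MazeGeometry = field(default_factory=MazeGeometry)
    thresholds: Thresholds = field(default_factory=Thresholds)
    n_cells: int = 60
    snr: float = 4.0

    def schedule(self) -> StageSchedule:
        if self.paradigm == "probabilistic":
            return StageSchedule.probabilistic(self.led_policy)
        if self.paradigm == "deterministic":
            return StageSchedule.deterministic(self.led_policy)
        raise ValueError(f"unknown paradigm {self.paradigm!r}")

    def echo(self) -> dict:
        """Complete parameter echo for the run log."""
        d = {
            "seed": self.seed,
            "paradigm": self.paradigm,
            "led_policy": self.led_policy,
            "n_mice": self.n_mice,
            "groups": dict(self.groups),
            "agent": asdict(self.agent),
            "thresholds": asdict(self.thresholds),
            "n_cells": self.n_cells,
            "snr": self.snr,
            "geometry": {
                "side_length": self.geometry.side_length,
                "reward_rois": {k: vars(v) for k, v in self.geometry.reward_rois.items()},
                "threat_rois": {k: vars(v) for k, v in self.geometry.threat_rois.items()},
                "path_ids": dict(self.geometry.path_ids),
            },
        }
        return d


def _geometry_from_dict(d: dict) -> MazeGeometry:
    def rects(sub):
        return {k: Rect(**v) for k, v in sub.items()}

    return MazeGeometry(
        side_length=d.get("side_length", 75.0),
        reward_rois=rects(d["reward_rois"]) if "reward_rois" in d else MazeGeometry().reward_rois,
        threat_rois=rects(d["threat_rois"]) if "threat_rois" in d else MazeGeometry().threat_rois,
        path_ids=d.get("path_ids", MazeGeometry().path_ids),
    )


def load_config(path) -> RunConfig:
    """Read a YAML run configuration; absent keys take the defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = RunConfig()
    thr = raw.get("thresholds", {})
    if "align_window" in thr:
        thr["align_window"] = tuple(thr["align_window"])
    return RunConfig(
        seed=int(raw.get("seed", cfg.seed)),
        paradigm=raw.get("paradigm", cfg.paradigm),
        led_policy=raw.get("led_policy", cfg.led_policy),
        n_mice=int(raw.get("n_mice", cfg.n_mice)),
        groups=raw.get("groups", cfg.groups),
        agent=AgentConfig(**raw.get("agent", {})),
        geometry=_geometry_from_dict(raw.get("geometry", {})),
        thresholds=Thresholds(**thr),
        n_cells=int(raw.get("n_cells", cfg.n_cells)),
        snr=float(raw.get("snr", cfg.snr)),
    )
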