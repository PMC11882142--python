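import numpy as np
import pytest

from threatmaze.behavior import MazeGeometry, StageSchedule
from threatmaze.synthetic import AgentConfig, simulate_agent, simulate_tracking


@pytest.fixture
def geometry():
    return MazeGeometry()


@pytest.fixture
def schedule():
    return StageSchedule.probabilistic()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def p5_session(geometry, schedule, rng):
    """One simulated probabilistic session rendered to tracking."""
    cfg = AgentConfig(laps_per_session=25)
    laps = [l for l in simulate_agent(cfg, schedule, rng) if l.session == "P5"]
    tracking, puffs, leds, entries = simulate_tracking(laps, geometry, rng)
    return {"laps": laps, "tracking": tracking, "puffs": puffs, "leds": leds, "entries": entries}
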