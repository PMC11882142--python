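"""End-to-end pipeline runner: simulate a cohort, analyze every stage,
write tidy CSV outputs and a run log.

Deterministic given (config, seed): every random stream is spawned from a
single seed sequence and the log carries a complete config echo.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, behavior, choice_history, neural, stats
from .config import RunConfig
from .pipeline import (
    add_expectation_labels,
    behavioral_lap_table,
    pe_classification_run,
)
from .synthetic import (
    AgentConfig,
    agent_laps_to_frame,
    default_cell_population,
    simulate_agent,
    simulate_calcium,
    simulate_tracking,
)

__all__ = ["run_pipeline", "simulate_mouse_session_tables"]


def _mouse_rng(seed: int, group_idx: int, mouse_idx: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(group_idx, mouse_idx))
    )


def simulate_mouse_session_tables(
    agent_cfg: AgentConfig, schedule, rng, geometry, sessions=None, speed_window=0.5
) -> pd.DataFrame:
    """Simulate one mouse and re-analyze its rendered tracking per session.

    Runs the full round trip (agent -> tracking -> ROI events -> laps ->
    speeds) for the requested sessions and returns the concatenated,
    expectation-labeled lap table.
    """
    agent_laps = simulate_agent(agent_cfg, schedule, rng)
    frames = []
    for sess in schedule:
        if sessions is not None and sess.label not in sessions:
            continue
        sess_laps = [l for l in agent_laps if l.session == sess.label]
        if not sess_laps:
            continue
        tracking, puffs, leds, _ = simulate_tracking(sess_laps, geometry, rng)
        frames.append(
            behavioral_lap_table(
                tracking, geometry, puffs, leds, sess.label, speed_window
            )
        )
    return add_expectation_labels(pd.concat(frames, ignore_index=True))


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Simulate the configured cohort end to end and write the report bundle.

    Outputs (CSV unless noted): per-mouse lap tables, per-session adaptive
    choice, post-threat switching, history-correlation coefficients and
    per-mouse significance, neural PE classification with planted ground
    truth, the Session x Group mixed ANOVA on adaptive choice, and
    ``run_log.txt`` with the full config echo.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    schedule = config.schedule()
    prob_sessions = [s.label for s in schedule if s.label.startswith(("P", "D"))]

    lap_tables = []
    choice_rows = []
    corr_rows = []
    sig_flags: dict[str, list[bool]] = {}
    switch_rows = []

    for gi, (group, override) in enumerate(sorted(config.groups.items())):
        sig_flags[group] = []
        for mi in range(config.n_mice):
            rng = _mouse_rng(config.seed, gi, mi)
            agent_cfg = AgentConfig(
                **{**vars(config.agent), "switch_override": bool(override)}
            )
            agent_laps = simulate_agent(agent_cfg, schedule, rng)
            frame = agent_laps_to_frame(agent_laps)
            frame.insert(0, "mouse", f"{group}{mi}")
            frame.insert(0, "group", group)
            lap_tables.append(frame)

            for sess in schedule:
                sub = frame[frame["session"] == sess.label]
                if len(sub):
                    choice_rows.append(
                        {
                            "group": group,
                            "mouse": f"{group}{mi}",
                            "session": sess.label,
                            "adaptive_choice": float(np.mean(sub["path"] == "lt-p")),
                        }
                    )

            prob = frame[frame["session"].isin(prob_sessions)]
            series = choice_history.ChoiceSeries(
                prob["path"].to_numpy(), prob["threat_delivered"].to_numpy()
            )
            corr = choice_history.history_choice_correlation(
                series, range(1, config.thresholds.k_max + 1)
            )
            corr.insert(0, "mouse", f"{group}{mi}")
            corr.insert(0, "group", group)
            corr_rows.append(corr)
            flags = choice_history.significant_any_k(corr, config.thresholds.alpha)
            sig_flags[group].append(bool(flags.get("ht-p", False)))

            for path in ("ht-p", "lt-p"):
                sw = choice_history.post_outcome_switch(prob, path, prob_sessions)
                for sess, val in sw.items():
                    switch_rows.append(
                        {
                            "group": group,
                            "mouse": f"{group}{mi}",
                            "conditioning_path": path,
                            "session": sess,
                            "p_choose_lt_next": val,
                        }
                    )

    laps_df = pd.concat(lap_tables, ignore_index=True)
    laps_df.to_csv(outdir / "laps.csv", index=False)
    choice_df = pd.DataFrame(choice_rows)
    choice_df.to_csv(outdir / "adaptive_choice.csv", index=False)
    pd.concat(corr_rows, ignore_index=True).to_csv(outdir / "history_correlation.csv", index=False)
    pd.DataFrame(switch_rows).to_csv(outdir / "post_threat_switch.csv", index=False)

    # group-level inference on the probabilistic-stage adaptive choice
    prob_choice = choice_df[choice_df["session"].isin(prob_sessions)]
    anova = stats.mixed_anova(
        prob_choice, dv="adaptive_choice", between="group", within="session", subject="mouse"
    )
    anova.to_frame().to_csv(outdir / "anova_adaptive_choice.csv")

    table, chi2, pval = choice_history.count_significant_mice(sig_flags)
    table.assign(chi2=chi2, p=pval).to_csv(outdir / "significant_mice.csv")

    # neural stage: planted cohort on the probabilistic-stage laps of the
    # first mouse of each group
    neural_rows = []
    for gi, (group, override) in enumerate(sorted(config.groups.items())):
        rng = _mouse_rng(config.seed, gi, 1000)
        agent_cfg = AgentConfig(**{**vars(config.agent), "switch_override": bool(override)})
        agent_laps = [
            l for l in simulate_agent(agent_cfg, schedule, rng) if l.session in prob_sessions
        ]
        entries = 10.0 + 8.0 * np.arange(len(agent_laps))
        specs = default_cell_population(config.n_cells, rng, snr=config.snr)
        traces, truth = simulate_calcium(agent_laps, entries, specs, rng)
        frame = agent_laps_to_frame(agent_laps)
        frame["approach_speed"] = frame["approach_speed"].astype(float)
        frame["speed_valid"] = True
        frame = add_expectation_labels(frame)
        _, classification = pe_classification_run(
            traces, frame, entries, threshold=config.thresholds.differential_threshold
        )
        merged = classification.join(truth.set_index("cell"), how="left")
        merged.insert(0, "group", group)
        neural_rows.append(merged)
    neural_df = pd.concat(neural_rows)
    neural_df.to_csv(outdir / "pe_classification.csv")

    log = {
        "version": __version__,
        "config": config.echo(),
        "outputs": sorted(p.name for p in outdir.glob("*.csv")),
    }
    (outdir / "run_log.txt").write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    return log
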