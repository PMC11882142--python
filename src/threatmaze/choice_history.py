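"""Outcome-history analyses of path choice.

Two questions about how past air puffs drive future path choice:

* after a threat on a given path, how often does the mouse take the
  low-threat path on the very next lap (post-outcome switching)?
* over how many past laps does the mouse integrate threat occurrences?
  Operationalized as the Pearson correlation between the lap-by-lap choice
  (1 = high-threat path) and the threat probability estimated from the
  trailing k visits to each path, for k = 1..50.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ChoiceSeries",
    "post_outcome_switch",
    "rolling_threat_probability",
    "history_choice_correlation",
    "history_correlation_fast",
    "significant_any_k",
    "count_significant_mice",
]


@dataclass
class ChoiceSeries:
    """Lap-ordered choices concatenated across probabilistic sessions.

    choice_code is 1 for the high-threat path, 0 for the low-threat path.
    """

    path: np.ndarray  # path id per lap
    threat_delivered: np.ndarray  # bool per lap
    ht_path: str = "ht-p"
    lt_path: str = "lt-p"

    def __post_init__(self) -> None:
        self.path = np.asarray(self.path, dtype=object)
        self.threat_delivered = np.asarray(self.threat_delivered, dtype=bool)
        if len(self.path) != len(self.threat_delivered):
            raise ValueError("path and threat_delivered must have equal length")

    def __len__(self) -> int:
        return len(self.path)

    @property
    def choice_code(self) -> np.ndarray:
        return (self.path == self.ht_path).astype(float)

    @staticmethod
    def from_lap_frame(df: pd.DataFrame, sessions=None, ht_path="ht-p", lt_path="lt-p"):
        """Build from a lap table, keeping within-session lap order.

        ``sessions``: ordered session labels to concatenate (default: all in
        order of appearance).
        """
        if sessions is not None:
            df = df[df["session"].isin(list(sessions))]
            order = {s: i for i, s in enumerate(sessions)}
            df = df.sort_values(["session", "index"], key=lambda c: c.map(order) if c.name == "session" else c)
        return ChoiceSeries(
            df["path"].to_numpy(), df["threat_delivered"].to_numpy(), ht_path, lt_path
        )


def post_outcome_switch(
    lap_frame: pd.DataFrame,
    conditioning_path: str,
    sessions,
    lt_path: str = "lt-p",
    min_qualifying: int = 2,
) -> pd.Series:
    """Per-session proportion of choosing the low-threat path on the lap
    after a threat on ``conditioning_path``.

    Qualifying laps are threat-delivered laps on the conditioning path that
    have a subsequent lap in the same session.  Sessions with fewer than
    ``min_qualifying`` such laps are discarded (NaN).
    """
    out = {}
    for sess in sessions:
        sub = lap_frame[lap_frame["session"] == sess].sort_values("index")
        paths = sub["path"].to_numpy()
        threat = sub["threat_delivered"].to_numpy(dtype=bool)
        qual = np.flatnonzero((paths[:-1] == conditioning_path) & threat[:-1])
        if len(qual) < min_qualifying:
            out[sess] = np.nan
            continue
        out[sess] = float(np.mean(paths[qual + 1] == lt_path))
    return pd.Series(out, name=f"p_lt_after_threat_on_{conditioning_path}")


def rolling_threat_probability(series: ChoiceSeries, path: str, k: int) -> np.ndarray:
    """Estimated threat probability at each lap: mean outcome over the most
    recent ``k`` visits to ``path`` strictly before that lap.

    NaN until k visits to the path have occurred.  Sessions are concatenated
    with no reset at boundaries.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(series)
    est = np.full(n, np.nan)
    history: list[bool] = []
    run_sum = 0
    for i in range(n):
        if len(history) >= k:
            est[i] = run_sum / k
        if series.path[i] == path:
            history.append(series.threat_delivered[i])
            run_sum += int(series.threat_delivered[i])
            if len(history) > k:
                run_sum -= int(history[-(k + 1)])
    if not np.any(np.isfinite(est)):
        raise ValueError(f"k={k} exceeds the number of visits to {path!r}")
    return est


def history_choice_correlation(
    series: ChoiceSeries, k_range=range(1, 51), min_laps: int = 3
) -> pd.DataFrame:
    """Pearson r between choice_code and each path's rolling threat estimate.

    One row per (path, k): ``path, k, r, p, n``.  r/p are NaN when fewer
    than ``min_laps`` laps have a defined estimate or either series has
    zero variance.  p is the standard two-sided t-transform p-value.
    """
    choice = series.choice_code
    rows = []
    for path in (series.ht_path, series.lt_path):
        for k in k_range:
            try:
                est = rolling_threat_probability(series, path, k)
            except ValueError:
                rows.append({"path": path, "k": k, "r": np.nan, "p": np.nan, "n": 0})
                continue
            ok = np.isfinite(est)
            n = int(ok.sum())
            if (
                n < min_laps
                or np.all(est[ok] == est[ok][0])
                or np.all(choice[ok] == choice[ok][0])
            ):
                rows.append({"path": path, "k": k, "r": np.nan, "p": np.nan, "n": n})
                continue
            r, p = sps.pearsonr(choice[ok], est[ok])
            rows.append({"path": path, "k": k, "r": float(r), "p": float(p), "n": n})
    return pd.DataFrame(rows)


def history_correlation_fast(
    choice_code: np.ndarray,
    path_is_ht: np.ndarray,
    threat: np.ndarray,
    k_max: int = 50,
    min_laps: int = 3,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Vectorized equivalent of :func:`history_choice_correlation`.

    Operates on plain arrays (choice_code, boolean ht-path indicator,
    boolean threat outcome) and returns ``{path: (r, p)}`` with arrays over
    k = 1..k_max.  Used for large null/planted simulations; agrees with the
    reference implementation to numerical precision (see tests).
    """
    n = len(choice_code)
    out = {}
    for label, mask in (("ht-p", path_is_ht.astype(bool)), ("lt-p", ~path_is_ht.astype(bool))):
        vidx = np.flatnonzero(mask)
        o = threat[vidx].astype(float)
        cs = np.concatenate([[0.0], np.cumsum(o)])
        # visits strictly before each lap
        nvis_before = np.cumsum(mask) - mask.astype(int)
        r_arr = np.full(k_max, np.nan)
        p_arr = np.full(k_max, np.nan)
        for k in range(1, k_max + 1):
            if len(o) < k:
                break
            win = (cs[k:] - cs[:-k]) / k  # trailing mean after >=k visits
            # lap i uses window ending at visit nvis_before[i]; defined when
            # nvis_before[i] >= k
            ok = nvis_before >= k
            m = int(ok.sum())
            if m < min_laps:
                continue
            est = win[nvis_before[ok] - k]
            c = choice_code[ok]
            sc, se = c.std(), est.std()
            if sc == 0 or se == 0:
                continue
            r = float(np.mean((c - c.mean()) * (est - est.mean())) / (sc * se))
            r = max(-1.0, min(1.0, r))
            if m > 2 and abs(r) < 1.0:
                t = r * np.sqrt((m - 2) / (1 - r * r))
                p = 2.0 * float(sps.t.sf(abs(t), m - 2))
            else:
                p = 0.0 if abs(r) == 1.0 else np.nan
            r_arr[k - 1], p_arr[k - 1] = r, p
        out[label] = (r_arr, p_arr)
    return out


def significant_any_k(corr: pd.DataFrame, alpha: float = 0.05) -> pd.Series:
    """Per-path flag: any k with p < alpha (no multiplicity correction,
    matching the 'significant at any window length' criterion)."""
    return corr.groupby("path")["p"].apply(lambda p: bool((p < alpha).any()))


def count_significant_mice(flags_by_group: dict[str, list[bool]]):
    """2x2 chi-square (1 df, no continuity correction) on significant-mouse
    counts across two groups.

    ``flags_by_group``: group label -> per-mouse significance flags.
    Returns (table DataFrame, chi2, p).
    """
    from .stats import chi_square_2x2

    if len(flags_by_group) != 2:
        raise ValueError("exactly two groups required")
    (g1, f1), (g2, f2) = flags_by_group.items()
    table = pd.DataFrame(
        {
            "significant": [int(np.sum(f1)), int(np.sum(f2))],
            "not_significant": [len(f1) - int(np.sum(f1)), len(f2) - int(np.sum(f2))],
        },
        index=[g1, g2],
    )
    chi2, p = chi_square_2x2(table.to_numpy())
    return table, chi2, p
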