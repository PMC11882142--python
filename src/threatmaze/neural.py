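"""Event-aligned calcium-response extraction and prediction-error coding.

Single-cell calcium traces (nominally 20 Hz) are aligned to threat-site
entries, binned at 100 ms over -1 s .. +2 s, averaged across laps of one
type, and z-normalized with the mean/SD of the 1-s pre-entry baseline (the
first 10 bins), per lap type.  The response magnitude is the mean z over
the first 500 ms after entry (bins 11-15, 1-based).  Cells are classified
as outcome responders (magnitude > 2) and, from the surprising-minus-
expected differential activity with thresholds +/-2, into signed
(Up-Down / Down-Up) and unsigned (Up-Up / Down-Down) prediction-error
coders.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "TraceMatrix",
    "AlignedTensor",
    "align_to_event",
    "lap_type_average_z",
    "response_magnitude",
    "classify_outcome_responders",
    "led_effect_distribution",
    "differential_activity",
    "classify_pe_type",
    "pe_proportions",
    "PE_LABELS",
    "SIGNED_LABELS",
    "UNSIGNED_LABELS",
]

N_BINS = 30
N_BASELINE_BINS = 10
RESPONSE_BINS = slice(10, 15)  # first 500 ms post entry (bins 11-15, 1-based)

PE_LABELS = ("Up-Up", "Up-Down", "Down-Up", "Down-Down", "Threat-only", "Omission-only", "none")
SIGNED_LABELS = frozenset({"Up-Down", "Down-Up"})
UNSIGNED_LABELS = frozenset({"Up-Up", "Down-Down"})


@dataclass
class TraceMatrix:
    """Cells x time fluorescence traces with a shared time base."""

    t: np.ndarray  # (n_samples,)
    values: np.ndarray  # (n_samples, n_cells)
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.t):
            raise ValueError("values must be (n_samples, n_cells)")
        if self.values.shape[1] != len(self.cell_ids):
            raise ValueError("cell_ids length mismatch")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("traces contain non-finite values")
        dt = np.diff(self.t)
        if len(dt) and (dt.min() <= 0 or dt.max() / dt.min() > 1.5):
            raise ValueError("trace sampling must be uniform within tolerance")

    @staticmethod
    def from_csv(path) -> "TraceMatrix":
        df = pd.read_csv(path)
        cells = [c for c in df.columns if c != "time_s"]
        return TraceMatrix(df["time_s"].to_numpy(), df[cells].to_numpy(), cells)

    def to_csv(self, path) -> None:
        out = pd.DataFrame(self.values, columns=self.cell_ids)
        out.insert(0, "time_s", self.t)
        out.to_csv(path, index=False)


@dataclass
class AlignedTensor:
    """cells x events x 30 bins of 100 ms spanning -1 s .. +2 s."""

    data: np.ndarray  # (n_cells, n_events, N_BINS)
    event_times: np.ndarray
    cell_ids: list[str]
    kept: np.ndarray  # indices of the input events that were in range

    def __post_init__(self) -> None:
        if self.data.ndim != 3 or self.data.shape[2] != N_BINS:
            raise ValueError(f"aligned tensor must have {N_BINS} bins")


def align_to_event(
    traces: TraceMatrix,
    event_times,
    window: tuple[float, float] = (-1.0, 2.0),
    bin_width: float = 0.1,
) -> AlignedTensor:
    """Bin trace samples into half-open 100-ms bins around each event.

    Per-bin value is the mean of samples with timestamps in
    [t_event + j*bin, t_event + (j+1)*bin).  Events whose window is not
    fully covered by the recording are dropped (logged).
    """
    event_times = np.asarray(event_times, dtype=float)
    n_bins = int(round((window[1] - window[0]) / bin_width))
    kept, tensors = [], []
    for i, t0 in enumerate(event_times):
        if t0 + window[0] < traces.t[0] or t0 + window[1] > traces.t[-1]:
            logger.info("event at t=%.2fs too close to recording edge; dropped", t0)
            continue
        rel = traces.t - t0
        # 1-ns guard so samples on a bin edge go to the upper bin regardless
        # of floating-point representation of the edge
        idx = np.floor((rel - window[0] + 1e-9) / bin_width).astype(int)
        ok = (rel >= window[0] - 1e-9) & (rel < window[1] - 1e-9)
        binned = np.full((n_bins, traces.values.shape[1]), np.nan)
        for b in range(n_bins):
            sel = ok & (idx == b)
            if sel.any():
                binned[b] = traces.values[sel].mean(axis=0)
        kept.append(i)
        tensors.append(binned.T)  # (cells, bins)
    if not kept:
        raise ValueError("no event fully covered by the recording")
    data = np.stack(tensors, axis=1)  # (cells, events, bins)
    return AlignedTensor(data, event_times[kept], list(traces.cell_ids), np.asarray(kept))


def lap_type_average_z(
    aligned: AlignedTensor, lap_mask, *, ddof: int = 1, per_lap: bool = False
) -> np.ndarray:
    """Lap-averaged, baseline-z-normalized response per cell for one lap type.

    Averages the binned activity across the selected laps, then z-scores
    with the mean and SD of the first 10 (pre-entry) bins of that average.
    ``per_lap=True`` instead z-scores each lap before averaging (sensitivity
    variant).  Cells with zero baseline SD come back all-NaN (undefined).

    Returns (n_cells, 30).
    """
    lap_mask = np.asarray(lap_mask)
    if lap_mask.dtype == bool:
        if not lap_mask.any():
            raise ValueError("no laps of the requested type")
        sub = aligned.data[:, lap_mask, :]
    else:
        sub = aligned.data[:, lap_mask, :]
        if sub.shape[1] == 0:
            raise ValueError("no laps of the requested type")

    def _z(traces2d: np.ndarray) -> np.ndarray:
        base = traces2d[:, :N_BASELINE_BINS]
        mu = base.mean(axis=1, keepdims=True)
        sd = base.std(axis=1, ddof=ddof, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (traces2d - mu) / sd
        z[np.ravel(sd == 0)] = np.nan
        return z

    if per_lap:
        z_laps = np.stack([_z(sub[:, j, :]) for j in range(sub.shape[1])], axis=1)
        return np.nanmean(z_laps, axis=1)
    return _z(sub.mean(axis=1))


def response_magnitude(zavg: np.ndarray) -> np.ndarray:
    """Mean z over the first 500 ms after threat-site entry (bins 11-15)."""
    zavg = np.atleast_2d(zavg)
    return zavg[:, RESPONSE_BINS].mean(axis=1)


def classify_outcome_responders(
    magnitudes: pd.DataFrame, threshold: float = 2.0, include_decreases: bool = False
) -> pd.DataFrame:
    """Flag outcome responders per lap type: magnitude strictly > threshold.

    ``magnitudes``: cells x lap-type frame of response magnitudes (computed
    on LED-free laps for threat types).  With ``include_decreases`` the
    symmetric criterion magnitude < -threshold flags suppressed responders
    in companion ``<type>_down`` columns.
    """
    flags = magnitudes.gt(threshold)
    if include_decreases:
        down = magnitudes.lt(-threshold)
        down.columns = [f"{c}_down" for c in magnitudes.columns]
        flags = pd.concat([flags, down], axis=1)
    return flags


def led_effect_distribution(magnitudes: pd.DataFrame) -> pd.DataFrame:
    """Per-cell outcome-evoked change relative to omission laps.

    Requires columns 'omission', 'puff', 'puff_led'; returns per-cell
    ``puff_minus_omission`` and ``puff_led_minus_omission``.  Cells missing
    any lap type (NaN) are excluded.
    """
    for col in ("omission", "puff", "puff_led"):
        if col not in magnitudes.columns:
            raise ValueError(f"missing lap type {col!r}")
    out = pd.DataFrame(
        {
            "puff_minus_omission": magnitudes["puff"] - magnitudes["omission"],
            "puff_led_minus_omission": magnitudes["puff_led"] - magnitudes["omission"],
        }
    )
    return out.dropna()


def compare_led_effects(group_a: np.ndarray, group_b: np.ndarray):
    """Two-sample KS test between per-cell evoked-change distributions."""
    res = sps.ks_2samp(group_a, group_b)
    return float(res.statistic), float(res.pvalue)


def differential_activity(magnitudes: pd.DataFrame) -> pd.DataFrame:
    """Surprising-minus-expected response magnitude per outcome.

    Requires columns 'threat_surprising', 'threat_expected',
    'omission_surprising', 'omission_expected'; returns per-cell
    ``d_threat`` and ``d_omission`` (NaN when any constituent is NaN).
    """
    need = ("threat_surprising", "threat_expected", "omission_surprising", "omission_expected")
    for col in need:
        if col not in magnitudes.columns:
            raise ValueError(f"missing lap type {col!r}")
    return pd.DataFrame(
        {
            "d_threat": magnitudes["threat_surprising"] - magnitudes["threat_expected"],
            "d_omission": magnitudes["omission_surprising"] - magnitudes["omission_expected"],
        }
    )


def classify_pe_type(diff: pd.DataFrame, threshold: float = 2.0) -> pd.DataFrame:
    """Classify cells by expectation-dependent differential activity.

    Each of d_threat / d_omission is thresholded at > +2 (Up) or < -2
    (Down).  Both significant -> one of Up-Up / Up-Down / Down-Up /
    Down-Down (threat direction first); exactly one -> Threat-only /
    Omission-only; neither -> 'none'.  Up-Down and Down-Up cells reverse
    response direction between surprising threats and omissions (signed
    prediction errors); Up-Up and Down-Down respond in the same direction
    (unsigned).  NaN differentials give label 'none' with undefined=True.
    """

    def _dir(v: float) -> str | None:
        if np.isnan(v):
            return None
        if v > threshold:
            return "Up"
        if v < -threshold:
            return "Down"
        return None

    rows = []
    for idx, r in diff.iterrows():
        dt, do = _dir(r["d_threat"]), _dir(r["d_omission"])
        undefined = bool(np.isnan(r["d_threat"]) or np.isnan(r["d_omission"]))
        if dt and do:
            label = f"{dt}-{do}"
        elif dt:
            label = "Threat-only"
        elif do:
            label = "Omission-only"
        else:
            label = "none"
        rows.append(
            {
                "cell": idx,
                "d_threat": r["d_threat"],
                "d_omission": r["d_omission"],
                "label": label,
                "signed_PE": label in SIGNED_LABELS,
                "unsigned_PE": label in UNSIGNED_LABELS,
                "undefined": undefined,
            }
        )
    return pd.DataFrame(rows).set_index("cell")


def pe_proportions(
    labels: pd.Series, n_cells: int | None = None, alpha: float = 0.05
) -> pd.DataFrame:
    """Proportion of cells per differential-activity category with exact
    (Clopper-Pearson) confidence limits at the given alpha."""
    if n_cells is None:
        n_cells = len(labels)
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rows = []
    counts = labels.value_counts()
    for label in PE_LABELS:
        k = int(counts.get(label, 0))
        lo, hi = _clopper_pearson(k, n_cells, alpha)
        rows.append(
            {"label": label, "count": k, "n": n_cells, "proportion": k / n_cells, "ci_low": lo, "ci_high": hi}
        )
    return pd.DataFrame(rows).set_index("label")


def _clopper_pearson(k: int, n: int, alpha: float) -> tuple[float, float]:
    lo = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(sps.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def compare_proportions_binomial(k_a: int, n_a: int, k_b: int, n_b: int) -> float:
    """Two-sided exact binomial test of group A's count against group B's
    proportion taken as the null rate."""
    if n_b == 0:
        raise ValueError("empty reference group")
    return float(sps.binomtest(k_a, n_a, p=k_b / n_b, alternative="two-sided").pvalue)
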