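"""Inferential statistics shared by the behavioral and neural analyses.

Repeated-measures and mixed (split-plot) ANOVA are implemented from the
classical univariate sums-of-squares decomposition, with Mauchly's
sphericity test and Greenhouse-Geisser df correction applied to
within-subject effects when sphericity is violated, and Tukey HSD post hoc
comparisons on the repeated-measures error term.  Elementary tests
(unpaired t, two-sample Kolmogorov-Smirnov, 2x2 chi-square without
continuity correction, exact binomial, Pearson correlation) wrap scipy.

Split-plot decomposition (one between-subject factor A with groups g of
size n_g; within factors W1 (p levels) and optionally W2 (q levels), one
observation per subject per within cell):

  between-subject stratum:  SS_A             vs  SS_subjects(A)
  W1 stratum:               SS_W1, SS_AxW1   vs  SS_W1 x subj(A)
  W2 stratum:               SS_W2, SS_AxW2   vs  SS_W2 x subj(A)
  W1W2 stratum:             SS_W1W2, SS_AxW1W2 vs residual

All sums of squares are computed from marginal observation means
(weighted-means solution, identical to R's ``aov`` with an ``Error``
stratum for these designs).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaTable",
    "one_way_rm_anova",
    "mixed_anova",
    "tukey_rm_posthoc",
    "mauchly_test",
    "gg_epsilon",
    "unpaired_t",
    "ks_two_sample",
    "chi_square_2x2",
    "binomial_test",
    "pearson_r",
]


@dataclass
class AnovaEffect:
    effect: str
    ss: float
    df: float
    ms: float
    f: float | None
    p: float | None
    df_corrected: float | None = None
    p_corrected: float | None = None
    epsilon: float | None = None
    sphericity_p: float | None = None
    correction_applied: bool = False


def _f_ratio(ms_num: float, ms_err: float) -> float:
    """F statistic; a zero error mean square with zero effect is F = 0."""
    if ms_err > 0:
        return float(ms_num / ms_err)
    return 0.0 if ms_num == 0 else float("inf")


class AnovaTable:
    """Ordered collection of ANOVA effects with a tidy-frame view."""

    def __init__(self, effects: list[AnovaEffect]):
        self.effects = effects

    def __getitem__(self, name: str) -> AnovaEffect:
        for e in self.effects:
            if e.effect == name:
                return e
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self.effects]).set_index("effect")

    def __repr__(self) -> str:
        return repr(self.to_frame().round(4))


# ---------------------------------------------------------------------------
# Sphericity


def _within_pivot(df: pd.DataFrame, subject: str, within: str, value: str) -> np.ndarray:
    wide = df.pivot_table(index=subject, columns=within, values=value, aggfunc="mean")
    if wide.isna().any().any():
        raise ValueError("missing within-subject cells; design must be complete")
    return wide.to_numpy()


def gg_epsilon(data: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the subjects x levels matrix.

    epsilon = tr(CSC')^2 / ((k-1) * tr((CSC')^2)) for the double-centered
    covariance; bounded to [1/(k-1), 1].
    """
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    s = np.cov(data, rowvar=False, ddof=1)
    # double-center
    s_c = s - s.mean(axis=0, keepdims=True) - s.mean(axis=1, keepdims=True) + s.mean()
    num = np.trace(s_c) ** 2
    den = (k - 1) * np.sum(s_c * s_c)
    eps = float(num / den) if den > 0 else 1.0
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def mauchly_test(data: np.ndarray) -> tuple[float, float]:
    """Mauchly's test of sphericity on a subjects x levels matrix.

    Returns (W, p) via the standard chi-square approximation on
    orthonormal-contrast covariance.  With k == 2 levels sphericity holds
    trivially (W = 1, p = 1).
    """
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    if k <= 2:
        return 1.0, 1.0
    if n <= k - 1:
        # contrast covariance is singular; cannot test, assume violation risk
        return np.nan, np.nan
    # orthonormal contrasts: basis of the space orthogonal to the unit vector
    c = np.linalg.qr(np.eye(k) - 1.0 / k)[0][:, : k - 1]
    s = np.cov(data @ c, rowvar=False, ddof=1)
    eig = np.linalg.eigvalsh(s)
    if np.any(eig <= 0):
        return 0.0, 0.0
    d = k - 1
    w = float(np.prod(eig) / (np.mean(eig) ** d))
    # chi-square approximation with the standard second-order term
    f_corr = 1.0 - (2 * d * d + d + 2) / (6.0 * d * (n - 1))
    w2 = (
        (d + 2) * (d - 1) * (d - 2) * (2 * d**3 + 6 * d**2 + 3 * k + 2)
        / (288.0 * ((n - 1) * d * f_corr) ** 2)
    )
    chi2 = -(n - 1) * f_corr * np.log(w)
    dof = d * (d + 1) / 2 - 1
    p1 = float(sps.chi2.sf(chi2, dof))
    p2 = float(sps.chi2.sf(chi2, dof + 4))
    return w, p1 + w2 * (p2 - p1)


def _apply_gg(effect: AnovaEffect, error: AnovaEffect, pivot: np.ndarray, alpha: float) -> None:
    """Attach sphericity diagnostics and GG-corrected p when violated."""
    w, p_sph = mauchly_test(pivot)
    eps = gg_epsilon(pivot)
    effect.epsilon = eps
    effect.sphericity_p = p_sph
    effect.df_corrected = effect.df * eps
    effect.p_corrected = float(sps.f.sf(effect.f, effect.df * eps, error.df * eps))
    # the corrected p supersedes the uncorrected one only on violation
    effect.correction_applied = bool(np.isfinite(p_sph) and p_sph < alpha)


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA


def one_way_rm_anova(
    df: pd.DataFrame,
    dv: str = "value",
    within: str = "level",
    subject: str = "subject",
    sphericity_alpha: float = 0.05,
) -> AnovaTable:
    """One-way repeated-measures ANOVA (balanced complete design).

    Standard within-subject decomposition: SS_total over subjects x levels
    splits into subjects, treatment, and subject-x-treatment error.  Mauchly
    p < ``sphericity_alpha`` triggers the Greenhouse-Geisser correction
    (corrected df and p reported alongside the uncorrected ones).
    """
    y = _within_pivot(df, subject, within, dv)
    n, k = y.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 levels")
    grand = y.mean()
    ss_subj = k * np.sum((y.mean(axis=1) - grand) ** 2)
    ss_treat = n * np.sum((y.mean(axis=0) - grand) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    ss_err = ss_total - ss_subj - ss_treat
    df_treat, df_err = k - 1, (n - 1) * (k - 1)
    ms_treat, ms_err = ss_treat / df_treat, ss_err / df_err
    f = _f_ratio(ms_treat, ms_err)
    p = float(sps.f.sf(f, df_treat, df_err))
    treat = AnovaEffect(within, ss_treat, df_treat, ms_treat, f, p)
    err = AnovaEffect("error", ss_err, df_err, ms_err, None, None)
    _apply_gg(treat, err, y, sphericity_alpha)
    return AnovaTable(
        [
            AnovaEffect("subject", ss_subj, n - 1, ss_subj / (n - 1), None, None),
            treat,
            err,
        ]
    )


def tukey_rm_posthoc(
    df: pd.DataFrame, dv: str = "value", within: str = "level", subject: str = "subject"
) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons after one-way RM ANOVA.

    Uses the RM error mean square and the studentized-range distribution
    with (n-1)(k-1) df.
    """
    y = _within_pivot(df, subject, within, dv)
    n, k = y.shape
    table = one_way_rm_anova(df, dv, within, subject)
    ms_err, df_err = table["error"].ms, table["error"].df
    levels = sorted(df[within].unique())
    means = {lev: y[:, i].mean() for i, lev in enumerate(levels)}
    rows = []
    for a, b in itertools.combinations(levels, 2):
        diff = means[a] - means[b]
        se = np.sqrt(ms_err / n)
        q = abs(diff) / se
        p = float(sps.studentized_range.sf(q, k, df_err))
        rows.append({"A": a, "B": b, "diff": diff, "q": q, "p_tukey": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Mixed (split-plot) ANOVA


def mixed_anova(
    df: pd.DataFrame,
    dv: str = "value",
    between: str = "group",
    within: str | list[str] = "session",
    subject: str = "subject",
    sphericity_alpha: float = 0.05,
) -> AnovaTable:
    """Mixed-design ANOVA: one between-subject factor, one or two within.

    Between-group sizes may differ; the within design must be complete per
    subject (one observation per within cell; replicates are averaged).
    Each within-subject effect is tested against its own subject-interaction
    error term, with Mauchly/Greenhouse-Geisser handling per within factor.
    A subject appearing in more than one group is an error.
    """
    within_factors = [within] if isinstance(within, str) else list(within)
    if not 1 <= len(within_factors) <= 2:
        raise ValueError("one or two within factors supported")
    gmap = df.groupby(subject)[between].nunique()
    if (gmap > 1).any():
        raise ValueError("a subject appears in multiple groups")

    cell_cols = [subject, between] + within_factors
    data = df.groupby(cell_cols, observed=True)[dv].mean().reset_index()
    wide = data.pivot_table(index=[subject, between], columns=within_factors, values=dv)
    if wide.isna().any().any():
        raise ValueError("incomplete within-subject design (no imputation)")

    y = wide.to_numpy()  # (N subjects, p*q cells), cells in within-factor order
    subj_group = wide.index.get_level_values(1).to_numpy()
    groups = pd.unique(subj_group)
    n_g = {g: int(np.sum(subj_group == g)) for g in groups}
    n_subj, k_cells = y.shape
    if isinstance(wide.columns, pd.MultiIndex):
        lv1 = wide.columns.get_level_values(0)
        lv2 = wide.columns.get_level_values(1)
        p_levels = pd.unique(lv1)
        q_levels = pd.unique(lv2)
    else:
        lv1 = wide.columns
        lv2 = None
        p_levels = pd.unique(lv1)
        q_levels = [None]
    p, q = len(p_levels), len(q_levels)
    if p * q != k_cells:
        raise ValueError("within design not fully crossed")

    grand = y.mean()
    subj_means = y.mean(axis=1)
    group_means = {g: subj_means[subj_group == g].mean() for g in groups}

    # between-subject stratum
    ss_between_subj = k_cells * np.sum((subj_means - grand) ** 2)
    ss_a = k_cells * sum(n_g[g] * (group_means[g] - grand) ** 2 for g in groups)
    ss_s_a = ss_between_subj - ss_a
    df_a, df_s_a = len(groups) - 1, n_subj - len(groups)

    def cell_index(i: int, j: int) -> np.ndarray:
        if lv2 is None:
            return np.asarray(lv1 == p_levels[i])
        return np.asarray((lv1 == p_levels[i]) & (lv2 == q_levels[j]))

    # marginal means over observations
    m_w1 = np.array([y[:, np.asarray(lv1 == lev)].mean() for lev in p_levels])
    m_gw1 = {g: np.array([y[np.ix_(subj_group == g, np.asarray(lv1 == lev))].mean() for lev in p_levels]) for g in groups}
    m_sw1 = np.stack([y[:, np.asarray(lv1 == lev)].mean(axis=1) for lev in p_levels], axis=1)  # (N, p)

    effects: list[AnovaEffect] = []
    ms_a = ss_a / df_a
    ms_s_a = ss_s_a / df_s_a
    f_a = _f_ratio(ms_a, ms_s_a)
    effects.append(AnovaEffect(between, ss_a, df_a, ms_a, f_a, float(sps.f.sf(f_a, df_a, df_s_a))))
    effects.append(AnovaEffect(f"subjects({between})", ss_s_a, df_s_a, ms_s_a, None, None))

    def within_stratum(name, levels, m_lev, m_glev, m_slev, mult):
        """SS for a within main effect, its group interaction, and error."""
        ss_w = mult * n_subj * np.sum((m_lev - grand) ** 2)
        ss_aw = mult * sum(
            n_g[g] * np.sum((m_glev[g] - group_means[g] - m_lev + grand) ** 2) for g in groups
        )
        dev = np.zeros_like(m_slev)
        for si in range(n_subj):
            g = subj_group[si]
            dev[si] = m_slev[si] - subj_means[si] - m_glev[g] + group_means[g]
        ss_ws = mult * np.sum(dev**2)
        kl = len(levels)
        df_w, df_aw, df_ws = kl - 1, (len(groups) - 1) * (kl - 1), (n_subj - len(groups)) * (kl - 1)
        ms_w, ms_ws = ss_w / df_w, ss_ws / df_ws
        ms_aw = ss_aw / df_aw if df_aw else np.nan
        f_w = _f_ratio(ms_w, ms_ws)
        eff_w = AnovaEffect(name, ss_w, df_w, ms_w, f_w, float(sps.f.sf(f_w, df_w, df_ws)))
        err = AnovaEffect(f"{name} x subjects({between})", ss_ws, df_ws, ms_ws, None, None)
        out = [eff_w]
        if df_aw:
            f_aw = _f_ratio(ms_aw, ms_ws)
            eff_aw = AnovaEffect(
                f"{between} x {name}", ss_aw, df_aw, ms_aw, f_aw, float(sps.f.sf(f_aw, df_aw, df_ws))
            )
            out.append(eff_aw)
        out.append(err)
        # GG on the subject x level means of this factor
        _apply_gg(eff_w, err, m_slev, sphericity_alpha)
        if df_aw:
            out[1].epsilon = eff_w.epsilon
            out[1].sphericity_p = eff_w.sphericity_p
            if eff_w.correction_applied:
                out[1].correction_applied = True
                out[1].df_corrected = df_aw * eff_w.epsilon
                out[1].p_corrected = float(
                    sps.f.sf(out[1].f, df_aw * eff_w.epsilon, df_ws * eff_w.epsilon)
                )
        return out, ss_w + ss_aw + ss_ws

    w1_name = within_factors[0]
    stratum1, ss_str1 = within_stratum(w1_name, p_levels, m_w1, m_gw1, m_sw1, mult=q)
    effects.extend(stratum1)
    used = ss_between_subj + ss_str1

    if lv2 is not None:
        w2_name = within_factors[1]
        m_w2 = np.array([y[:, np.asarray(lv2 == lev)].mean() for lev in q_levels])
        m_gw2 = {
            g: np.array([y[np.ix_(subj_group == g, np.asarray(lv2 == lev))].mean() for lev in q_levels])
            for g in groups
        }
        m_sw2 = np.stack([y[:, np.asarray(lv2 == lev)].mean(axis=1) for lev in q_levels], axis=1)
        stratum2, ss_str2 = within_stratum(w2_name, q_levels, m_w2, m_gw2, m_sw2, mult=p)
        effects.extend(stratum2)
        used += ss_str2

        # W1 x W2 stratum
        m_cell = np.array([[y[:, cell_index(i, j)].mean() for j in range(q)] for i in range(p)])
        m_gcell = {
            g: np.array(
                [[y[np.ix_(subj_group == g, cell_index(i, j))].mean() for j in range(q)] for i in range(p)]
            )
            for g in groups
        }
        ss_w12 = n_subj * np.sum(
            (m_cell - m_w1[:, None] - m_w2[None, :] + grand) ** 2
        )
        ss_aw12 = sum(
            n_g[g]
            * np.sum(
                (
                    m_gcell[g]
                    - m_gw1[g][:, None]
                    - m_gw2[g][None, :]
                    + group_means[g]
                    - (m_cell - m_w1[:, None] - m_w2[None, :] + grand)
                )
                ** 2
            )
            for g in groups
        )
        ss_total = np.sum((y - grand) ** 2)
        ss_res = ss_total - used - ss_w12 - ss_aw12
        df_w12 = (p - 1) * (q - 1)
        df_aw12 = (len(groups) - 1) * df_w12
        df_res = (n_subj - len(groups)) * df_w12
        ms_w12, ms_res = ss_w12 / df_w12, ss_res / df_res
        f_w12 = _f_ratio(ms_w12, ms_res)
        eff_w12 = AnovaEffect(
            f"{w1_name} x {w2_name}", ss_w12, df_w12, ms_w12, f_w12, float(sps.f.sf(f_w12, df_w12, df_res))
        )
        err12 = AnovaEffect(
            f"{w1_name} x {w2_name} x subjects({between})", ss_res, df_res, ss_res / df_res, None, None
        )
        effects.append(eff_w12)
        if df_aw12:
            ms_aw12 = ss_aw12 / df_aw12
            f_aw12 = _f_ratio(ms_aw12, ms_res)
            effects.append(
                AnovaEffect(
                    f"{between} x {w1_name} x {w2_name}",
                    ss_aw12,
                    df_aw12,
                    ms_aw12,
                    f_aw12,
                    float(sps.f.sf(f_aw12, df_aw12, df_res)),
                )
            )
        effects.append(err12)
        # interaction-cell sphericity uses the p*q subject cell matrix
        _apply_gg(eff_w12, err12, y, sphericity_alpha)

    return AnovaTable(effects)


# ---------------------------------------------------------------------------
# Elementary tests


def unpaired_t(a, b, equal_var: bool = True) -> tuple[float, float]:
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError("zero variance in both samples")
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def ks_two_sample(a, b) -> tuple[float, float]:
    res = sps.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)


def chi_square_2x2(table, correction: bool = False) -> tuple[float, float]:
    """Chi-square test on a 2x2 table, 1 df, no Yates correction by default."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("table must be 2x2")
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if np.any(expected == 0):
        raise ValueError("expected cell count of zero")
    chi2, p, _, _ = sps.chi2_contingency(table, correction=correction)
    return float(chi2), float(p)


def binomial_test(k: int, n: int, p: float = 0.5) -> float:
    """Exact two-sided binomial p-value (summed tail probabilities)."""
    return float(sps.binomtest(k, n, p, alternative="two-sided").pvalue)


def pearson_r(x, y) -> tuple[float, float]:
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input to Pearson correlation")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
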