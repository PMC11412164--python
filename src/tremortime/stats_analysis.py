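"""Behavioural statistics for the tremor bisection experiments.

Implements the within-subject analyses applied to the BP/CV/RT summaries:

* one- and two-way repeated-measures ANOVA with partial eta squared, each
  effect tested against its own subject-by-effect interaction error term
  (classical balanced decomposition, no sphericity correction by default --
  a Greenhouse-Geisser option is available);
* linear contrasts over ordered factor levels with one-sample t and
  Cohen's d on the per-subject contrast scores;
* simple main effects of one factor within each level of a moderator;
* the tremor-direction bin control (0-60, 61-120, 121-180 degrees);
* per-subject CV-versus-frequency slopes and the between-group
  Mann-Whitney comparison with rank-biserial effect size.

Input tables are long-format DataFrames with one value per subject x cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "ContrastResult",
    "MannWhitneyResult",
    "rm_anova",
    "rm_anova_one_way",
    "linear_contrast",
    "simple_main_effects",
    "direction_bins",
    "per_subject_slopes",
    "slope_comparison",
    "between_group_test",
]


@dataclass(frozen=True)
class AnovaResult:
    """One ANOVA effect: F(df_effect, df_error), p, partial eta squared."""

    effect: str
    F: float
    df_effect: int
    df_error: int
    p: float
    partial_eta_sq: float


@dataclass(frozen=True)
class ContrastResult:
    t: float
    df: int
    p: float
    cohen_d: float
    mean_score: float


@dataclass(frozen=True)
class MannWhitneyResult:
    U: float
    p: float
    rank_biserial: float
    method: str


def _pivot(table: pd.DataFrame, dv: str, subject: str, within: Sequence[str]) -> np.ndarray:
    """Balanced subject x cells array, erroring on missing/duplicated cells."""
    wide = table.pivot_table(
        index=subject, columns=list(within), values=dv, aggfunc="mean"
    )
    counts = table.groupby([subject, *within])[dv].size()
    if (counts != 1).any():
        raise ValueError("design must have exactly one value per subject per cell")
    if wide.isna().any().any():
        raise ValueError("missing cells in repeated-measures table (no imputation)")
    return wide


def _gg_epsilon(y: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the subject x level data matrix."""
    k = y.shape[1]
    s = np.cov(y, rowvar=False)
    mean_diag = np.trace(s) / k
    grand = s.mean()
    row_means = s.mean(axis=1)
    num = (k * (mean_diag - grand)) ** 2
    den = (k - 1) * (np.sum(s**2) - 2 * k * np.sum(row_means**2) + k**2 * grand**2)
    return float(num / den) if den > 0 else 1.0


def rm_anova(
    table: pd.DataFrame,
    dv: str,
    subject: str,
    within: Sequence[str],
    gg_correction: bool = False,
) -> list[AnovaResult]:
    """Repeated-measures ANOVA on a complete balanced within-subject design.

    ``within`` lists one or two factor columns.  For two factors the
    decomposition yields main effects A and B and the interaction A x B,
    each with its own subject-by-effect error term; partial eta squared is
    SS_effect / (SS_effect + SS_error).  dfs are reported uncorrected
    unless ``gg_correction`` is set, in which case Greenhouse-Geisser
    epsilon rescales dfs for the p value (F unchanged).
    """
    within = list(within)
    if len(within) == 1:
        return [
            rm_anova_one_way(table, dv, subject, within[0], gg_correction=gg_correction)
        ]
    if len(within) != 2:
        raise ValueError("within must name one or two factors")
    fa, fb = within
    wide = _pivot(table, dv, subject, within)
    a_levels = wide.columns.get_level_values(0).unique()
    b_levels = wide.columns.get_level_values(1).unique()
    n_s, n_a, n_b = wide.shape[0], len(a_levels), len(b_levels)
    # data cube subjects x A x B
    y = wide.to_numpy().reshape(n_s, n_a, n_b)
    grand = y.mean()
    subj_m = y.mean(axis=(1, 2))
    a_m = y.mean(axis=(0, 2))
    b_m = y.mean(axis=(0, 1))
    ab_m = y.mean(axis=0)
    as_m = y.mean(axis=2)  # subjects x A
    bs_m = y.mean(axis=1)  # subjects x B

    ss_a = n_s * n_b * np.sum((a_m - grand) ** 2)
    ss_b = n_s * n_a * np.sum((b_m - grand) ** 2)
    ss_ab = n_s * np.sum((ab_m - a_m[:, None] - b_m[None, :] + grand) ** 2)
    ss_s = n_a * n_b * np.sum((subj_m - grand) ** 2)
    ss_as = n_b * np.sum(
        (as_m - a_m[None, :] - subj_m[:, None] + grand) ** 2
    )
    ss_bs = n_a * np.sum(
        (bs_m - b_m[None, :] - subj_m[:, None] + grand) ** 2
    )
    ss_tot = np.sum((y - grand) ** 2)
    ss_abs = ss_tot - ss_a - ss_b - ss_ab - ss_s - ss_as - ss_bs

    specs = [
        (fa, ss_a, n_a - 1, ss_as, (n_a - 1) * (n_s - 1), y.mean(axis=2)),
        (fb, ss_b, n_b - 1, ss_bs, (n_b - 1) * (n_s - 1), y.mean(axis=1)),
        (
            f"{fa}:{fb}",
            ss_ab,
            (n_a - 1) * (n_b - 1),
            ss_abs,
            (n_a - 1) * (n_b - 1) * (n_s - 1),
            y.reshape(n_s, n_a * n_b),
        ),
    ]
    return [_effect_result(*spec, gg_correction) for spec in specs]


def _effect_result(name, ss_eff, df_eff, ss_err, df_err, y_mat, gg_correction):
    ms_eff = ss_eff / df_eff
    ms_err = ss_err / df_err if df_err > 0 else np.nan
    f = ms_eff / ms_err if ms_err > 0 else 0.0
    eps = _gg_epsilon(y_mat) if gg_correction else 1.0
    p = float(sps.f.sf(f, df_eff * eps, df_err * eps)) if ms_err > 0 else 1.0
    pes = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
    return AnovaResult(
        effect=name,
        F=float(f),
        df_effect=int(df_eff),
        df_error=int(df_err),
        p=p,
        partial_eta_sq=float(pes),
    )


def rm_anova_one_way(
    table: pd.DataFrame,
    dv: str,
    subject: str,
    within: str,
    gg_correction: bool = False,
) -> AnovaResult:
    """One-factor repeated-measures ANOVA (degenerate case of :func:`rm_anova`)."""
    wide = _pivot(table, dv, subject, [within])
    y = wide.to_numpy()
    n_s, n_l = y.shape
    grand = y.mean()
    lvl_m = y.mean(axis=0)
    subj_m = y.mean(axis=1)
    ss_eff = n_s * np.sum((lvl_m - grand) ** 2)
    ss_s = n_l * np.sum((subj_m - grand) ** 2)
    ss_tot = np.sum((y - grand) ** 2)
    ss_err = ss_tot - ss_eff - ss_s
    return _effect_result(
        within, ss_eff, n_l - 1, ss_err, (n_l - 1) * (n_s - 1), y, gg_correction
    )


def linear_contrast(
    table: pd.DataFrame,
    dv: str,
    subject: str,
    within: str,
    weights: Sequence[float] | None = None,
) -> ContrastResult:
    """Linear trend over ordered levels, tested on per-subject contrast scores.

    Levels are sorted and given equally spaced centred weights (-1, 0, 1
    for three levels) unless ``weights`` is supplied.  Each subject's score
    is the weighted sum of their level means; a one-sample t-test against 0
    follows, with Cohen's d = mean(score) / SD(score).
    """
    wide = _pivot(table, dv, subject, [within]).sort_index(axis=1)
    k = wide.shape[1]
    if k < 2:
        raise ValueError("need >= 2 levels for a contrast")
    if weights is None:
        w = np.arange(k, dtype=float) - (k - 1) / 2.0
    else:
        w = np.asarray(weights, dtype=float)
        if w.size != k:
            raise ValueError("weights length must match number of levels")
    scores = wide.to_numpy() @ w
    sd = scores.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance contrast scores")
    n = scores.size
    t = scores.mean() / (sd / np.sqrt(n))
    p = float(2 * sps.t.sf(abs(t), n - 1))
    return ContrastResult(
        t=float(t), df=n - 1, p=p, cohen_d=float(scores.mean() / sd),
        mean_score=float(scores.mean()),
    )


def simple_main_effects(
    table: pd.DataFrame,
    dv: str,
    subject: str,
    simple_factor: str,
    moderator: str,
    gg_correction: bool = False,
) -> pd.DataFrame:
    """One-way rm-ANOVA of ``simple_factor`` within each ``moderator`` level."""
    rows = []
    for lvl, g in table.groupby(moderator):
        res = rm_anova_one_way(g, dv, subject, simple_factor, gg_correction)
        rows.append(
            {
                moderator: lvl,
                "effect": res.effect,
                "F": res.F,
                "df_effect": res.df_effect,
                "df_error": res.df_error,
                "p": res.p,
                "partial_eta_sq": res.partial_eta_sq,
            }
        )
    return pd.DataFrame(rows)


#: tremor-direction control bins: [0, 60] / (60, 120] / (120, 180) degrees
_DIRECTION_EDGES = (60.0, 120.0)


def direction_bins(trials: pd.DataFrame, column: str = "direction_deg") -> pd.DataFrame:
    """Annotate trials with the tremor-direction bin (1, 2 or 3).

    Bin 1 covers [0, 60], bin 2 (60, 120], bin 3 (120, 180); the printed
    integer-degree bins (0-60 / 61-120 / 121-180) are extended to
    continuous directions with half-open upper intervals.
    """
    d = trials[column].to_numpy(dtype=float)
    if np.any(d < 0) or np.any(d >= 180):
        raise ValueError("direction_deg must lie in [0, 180)")
    bins = np.where(d <= _DIRECTION_EDGES[0], 1, np.where(d <= _DIRECTION_EDGES[1], 2, 3))
    out = trials.copy()
    out["direction_bin"] = bins
    return out


def per_subject_slopes(
    table: pd.DataFrame,
    dv: str,
    subject: str,
    within: str,
    level_coding: dict | None = None,
) -> pd.DataFrame:
    """OLS slope of ``dv`` across ordered levels, one per subject.

    Levels are coded 1, 2, 3, ... by sorted order unless ``level_coding``
    maps level values to codes explicitly.
    """
    wide = _pivot(table, dv, subject, [within]).sort_index(axis=1)
    levels = wide.columns.to_numpy()
    if level_coding is None:
        x = np.arange(1, len(levels) + 1, dtype=float)
    else:
        x = np.array([level_coding[l] for l in levels], dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 levels for a slope")
    xc = x - x.mean()
    slopes = (wide.to_numpy() @ xc) / np.sum(xc**2)
    return pd.DataFrame({subject: wide.index, "slope": slopes}).set_index(subject)


def slope_comparison(
    slopes_a: Sequence[float],
    slopes_b: Sequence[float],
    exact_max_n: int = 20,
) -> MannWhitneyResult:
    """Mann-Whitney U between two independent slope samples.

    ``U`` is the statistic of the first sample.  The exact null
    distribution is used when both groups have at most ``exact_max_n``
    observations and no ties; otherwise the tie-corrected normal
    approximation.  Rank-biserial correlation is ``1 - 2U/(n1*n2)``: +1
    when every first-group value ranks below the second group, -1 in the
    opposite case, 0 under complete overlap.
    """
    a = np.asarray(slopes_a, dtype=float)
    b = np.asarray(slopes_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = (
        "exact" if (a.size <= exact_max_n and b.size <= exact_max_n and not has_ties)
        else "asymptotic"
    )
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u = float(res.statistic)
    rb = 1.0 - 2.0 * u / (a.size * b.size)
    return MannWhitneyResult(U=u, p=float(res.pvalue), rank_biserial=rb, method=method)


def between_group_test(values_a, values_b) -> MannWhitneyResult:
    """Between-group comparison of subject-level summaries (e.g. mean CV).

    A nonparametric stand-in for the cross-modal main effect: the two
    modalities are independent groups, so their subject means are compared
    with the same Mann-Whitney machinery as the slopes.
    """
    return slope_comparison(values_a, values_b)
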