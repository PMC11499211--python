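"""Group-level statistics: frequency profiles and mixed repeated-measures ANOVA.

The study design is a balanced split-plot: housing condition (control vs
LBN) is the between-subjects factor, postpartum day the within-subjects
factor, with each dam observed on every day.  Responses are per-(dam, day)
scan counts of one behavior code, or per-(dam, day) transition counts, taken
per phase (light = mean of the two light periods; dark = the single dark
period).

The ANOVA is the classical univariate mixed-model decomposition:

* housing is tested against subjects-within-groups
  (df = g-1, g(n-1));
* day and day x housing are tested against day x subjects-within-groups
  (df = d-1 and (g-1)(d-1), each over (d-1) g(n-1)).

No sphericity correction is applied by default (Greenhouse-Geisser epsilon
is available as an option), matching designs reported with uncorrected df.
Post hoc group contrasts within each day use the pooled between-subject
error and a Sidak multiplicity adjustment over the days compared.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .ethogram import CODES, Dataset
from .transitions import PHASE_PERIODS, transition_count

__all__ = [
    "ResponseTable",
    "AnovaTable",
    "response_table",
    "mixed_anova",
    "sidak_posthoc",
    "summarize",
]

logger = logging.getLogger(__name__)

RESPONSES = CODES + ("transitions",)


@dataclass(frozen=True)
class ResponseTable:
    """Balanced per-(dam, day) response values with group labels.

    ``values`` is a wide DataFrame (index: dam_id, columns: ppd ints);
    ``groups`` maps each dam to its housing condition.  Completeness (no
    missing cells) is required by the repeated-measures decomposition and is
    validated at construction.
    """

    values: pd.DataFrame
    groups: pd.Series
    response: str
    phase: str

    def __post_init__(self) -> None:
        missing = [
            (dam, int(ppd))
            for dam in self.values.index
            for ppd in self.values.columns
            if pd.isna(self.values.at[dam, ppd])
        ]
        if missing:
            raise ValueError(f"unbalanced response table; missing cells: {missing}")
        if not set(self.values.index) <= set(self.groups.index):
            raise ValueError("every dam needs a group label")

    @property
    def n_days(self) -> int:
        return self.values.shape[1]

    def group_levels(self) -> list[str]:
        return sorted(self.groups.loc[self.values.index].unique())

    def by_group(self) -> dict[str, pd.DataFrame]:
        labels = self.groups.loc[self.values.index]
        return {g: self.values.loc[labels == g] for g in self.group_levels()}


def _session_value(codes, response: str, l_policy: str) -> float:
    if response == "transitions":
        return float(transition_count(codes, scope="all"))
    return float(sum(c == response for c in codes))


def response_table(
    dataset: Dataset,
    response: str,
    phase: str,
    l_policy: str = "bridge",
) -> ResponseTable:
    """Extract one balanced response per (dam, ppd) for a phase.

    ``response`` is a behavior code (scan-count response) or
    ``"transitions"`` (the all-codes transition count).  Light-phase values
    average the AM and PM sessions; dark-phase values come from the single
    dark session.  Missing sessions make the design unbalanced and raise
    with the full list of missing cells.
    """
    if response not in RESPONSES:
        raise ValueError(f"unknown response {response!r}, expected one of {RESPONSES}")
    if phase not in PHASE_PERIODS:
        raise ValueError(f"unknown phase {phase!r}")
    periods = PHASE_PERIODS[phase]
    dams = dataset.dam_ids()
    ppds = dataset.ppds()
    missing = [
        (dam, ppd, period)
        for dam in dams
        for ppd in ppds
        for period in periods
        if not dataset.has_session(dam, ppd, period)
    ]
    if missing:
        raise ValueError(f"unbalanced dataset; missing sessions: {missing}")
    values = pd.DataFrame(index=pd.Index(dams, name="dam_id"),
                          columns=pd.Index(ppds, name="ppd"), dtype=float)
    for dam in dams:
        for ppd in ppds:
            vals = [
                _session_value(dataset.session(dam, ppd, p).codes, response, l_policy)
                for p in periods
            ]
            values.at[dam, ppd] = float(np.mean(vals))
    groups = pd.Series(dataset.dam_groups, name="group").loc[dams]
    return ResponseTable(values=values, groups=groups, response=response, phase=phase)


@dataclass(frozen=True)
class AnovaTable:
    """Mixed-ANOVA F tests and the underlying sums of squares.

    ``effects`` has one row per factor (housing, day, interaction) with
    F, df1, df2 and p; ``ss`` holds the full decomposition including the two
    error terms (subjects-within-groups and day x subjects-within-groups).
    """

    effects: pd.DataFrame
    ss: dict[str, float]
    response: str = ""
    phase: str = ""

    def __getitem__(self, factor: str) -> pd.Series:
        return self.effects.loc[factor]


def _f_test(ss_effect, df_effect, ss_error, df_error):
    ms_error = ss_error / df_error
    ms_effect = ss_effect / df_effect
    if ms_error == 0.0:
        # Degenerate data (e.g. all responses identical): report F = 0, p = 1
        # when there is no effect variance either, otherwise an infinite F.
        if ms_effect == 0.0:
            logger.warning("zero error and effect sums of squares; reporting F=0, p=1")
            return 0.0, 1.0
        logger.warning("zero error sum of squares with nonzero effect; reporting F=inf, p=0")
        return float("inf"), 0.0
    f = ms_effect / ms_error
    p = float(sps.f.sf(f, df_effect, df_error))
    return float(f), p


def mixed_anova(
    table: ResponseTable, sphericity_correction: bool = False
) -> AnovaTable:
    """Two-way mixed (split-plot) RM ANOVA on a balanced response table.

    Between factor: housing group; within factor: postpartum day; subjects
    (dams) nested in groups.  Requires a balanced design with at least two
    dams per group and an equal number per group.

    With ``sphericity_correction=True`` the day and interaction p-values are
    recomputed with Greenhouse-Geisser adjusted df (F is unchanged).
    """
    by_group = table.by_group()
    levels = list(by_group)
    g = len(levels)
    if g < 2:
        raise ValueError("mixed_anova requires at least two groups")
    sizes = {lev: df.shape[0] for lev, df in by_group.items()}
    if len(set(sizes.values())) != 1:
        raise ValueError(f"unbalanced group sizes {sizes}; balanced design required")
    n = next(iter(sizes.values()))
    if n < 2:
        raise ValueError("each group needs at least two dams")
    d = table.n_days

    y = np.stack([by_group[lev].to_numpy(dtype=float) for lev in levels])  # (g, n, d)
    grand = y.mean()
    subj_means = y.mean(axis=2)          # (g, n)
    group_means = y.mean(axis=(1, 2))    # (g,)
    day_means = y.mean(axis=(0, 1))      # (d,)
    cell_means = y.mean(axis=1)          # (g, d)

    ss_total = float(((y - grand) ** 2).sum())
    ss_between_subj = float(d * ((subj_means - grand) ** 2).sum())
    ss_housing = float(n * d * ((group_means - grand) ** 2).sum())
    ss_subj_within = ss_between_subj - ss_housing
    ss_day = float(g * n * ((day_means - grand) ** 2).sum())
    ss_inter = float(
        n
        * (
            (cell_means - group_means[:, None] - day_means[None, :] + grand) ** 2
        ).sum()
    )
    ss_error = ss_total - ss_between_subj - ss_day - ss_inter
    ss_error = max(ss_error, 0.0)  # guard tiny negative rounding
    ss_subj_within = max(ss_subj_within, 0.0)

    df_housing = (g - 1, g * (n - 1))
    df_day = (d - 1, (d - 1) * g * (n - 1))
    df_inter = ((g - 1) * (d - 1), (d - 1) * g * (n - 1))

    f_h, p_h = _f_test(ss_housing, df_housing[0], ss_subj_within, df_housing[1])
    f_d, p_d = _f_test(ss_day, df_day[0], ss_error, df_day[1])
    f_i, p_i = _f_test(ss_inter, df_inter[0], ss_error, df_inter[1])

    if sphericity_correction:
        eps = _greenhouse_geisser_epsilon(y)
        if np.isfinite(f_d):
            p_d = float(sps.f.sf(f_d, eps * df_day[0], eps * df_day[1]))
        if np.isfinite(f_i):
            p_i = float(sps.f.sf(f_i, eps * df_inter[0], eps * df_inter[1]))

    effects = pd.DataFrame(
        {
            "F": [f_h, f_d, f_i],
            "df1": [df_housing[0], df_day[0], df_inter[0]],
            "df2": [df_housing[1], df_day[1], df_inter[1]],
            "p": [p_h, p_d, p_i],
        },
        index=pd.Index(["housing", "day", "interaction"], name="factor"),
    )
    ss = {
        "total": ss_total,
        "housing": ss_housing,
        "subjects_within_groups": ss_subj_within,
        "day": ss_day,
        "interaction": ss_inter,
        "day_x_subjects_within_groups": ss_error,
    }
    return AnovaTable(effects=effects, ss=ss, response=table.response, phase=table.phase)


def _greenhouse_geisser_epsilon(y: np.ndarray) -> float:
    """GG epsilon from the pooled within-group covariance of the day profiles."""
    g, n, d = y.shape
    resid = y - y.mean(axis=1, keepdims=True)
    pooled = sum(resid[i].T @ resid[i] for i in range(g)) / (g * (n - 1))
    centered = pooled - pooled.mean(axis=0) - pooled.mean(axis=1)[:, None] + pooled.mean()
    num = np.trace(centered) ** 2
    den = (d - 1) * (centered**2).sum()
    if den == 0:
        return 1.0
    return float(np.clip(num / den, 1.0 / (d - 1), 1.0))


def sidak_posthoc(table: ResponseTable, anova: AnovaTable | None = None) -> pd.DataFrame:
    """Per-day group contrasts with Sidak-adjusted p-values.

    For each postpartum day the two group means are compared with a t
    statistic whose error is the pooled between-subject mean square from the
    mixed ANOVA (df = g(n-1)); raw two-sided p-values are adjusted as
    p_adj = 1 - (1 - p)^m with m = number of days in the family.
    """
    if anova is None:
        anova = mixed_anova(table)
    by_group = table.by_group()
    levels = list(by_group)
    if len(levels) != 2:
        raise ValueError("sidak_posthoc compares exactly two groups")
    a, b = levels
    n_a, n_b = by_group[a].shape[0], by_group[b].shape[0]
    df_err = anova["housing"]["df2"]
    ms_err = anova.ss["subjects_within_groups"] / df_err
    m = table.n_days
    rows = []
    for ppd in table.values.columns:
        mean_a = float(by_group[a][ppd].mean())
        mean_b = float(by_group[b][ppd].mean())
        diff = mean_b - mean_a
        se = np.sqrt(ms_err * (1.0 / n_a + 1.0 / n_b))
        if se == 0:
            t = 0.0 if diff == 0 else np.inf * np.sign(diff)
        else:
            t = diff / se
        p_raw = float(2.0 * sps.t.sf(abs(t), df_err)) if np.isfinite(t) else 0.0
        p_adj = float(1.0 - (1.0 - p_raw) ** m)
        rows.append(
            {
                "ppd": int(ppd),
                "contrast": f"{b} - {a}",
                "diff": diff,
                "t": float(t),
                "df": float(df_err),
                "p_raw": p_raw,
                "p_adj": p_adj,
            }
        )
    return pd.DataFrame(rows)


def summarize(table: ResponseTable) -> pd.DataFrame:
    """Mean and SEM per (group, day); SEM = sample SD / sqrt(n), n >= 2."""
    rows = []
    for group, df in table.by_group().items():
        n = df.shape[0]
        if n < 2:
            raise ValueError(f"group {group!r} needs at least two dams for a SEM")
        for ppd in df.columns:
            vals = df[ppd].to_numpy(dtype=float)
            rows.append(
                {
                    "group": group,
                    "ppd": int(ppd),
                    "mean": float(vals.mean()),
                    "sem": float(vals.std(ddof=1) / np.sqrt(n)),
                    "n": n,
                }
            )
    return pd.DataFrame(rows)
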