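"""Statistical layer: repeated-measures ANOVA, pairwise comparisons and the
percent-change arithmetic used in condition reports.

The study design is fully within-subjects: one value per participant per
phone condition (gait values are the mean over the three repetitions, gaze
values come from the single selected trial).  The omnibus test is a one-way
repeated-measures ANOVA with partial eta squared as effect size; post-hoc
comparisons are Bonferroni-corrected paired t-tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from stepgaze.trial_io import CONDITIONS

__all__ = [
    "StatsResult",
    "PairwiseResult",
    "average_repetitions",
    "rm_anova",
    "bonferroni_pairwise",
    "assumption_checks",
    "percent_change",
    "round_half_away",
    "format_percent_change",
    "cohens_d_paired",
    "build_condition_table",
    "repetition_effect_check",
]


@dataclass(frozen=True)
class PairwiseResult:
    pair: tuple[str, str]
    t: float
    df: int
    p_raw: float
    p_adjusted: float
    flagged: bool = False  # zero-variance difference vector


@dataclass
class StatsResult:
    """One-way repeated-measures ANOVA summary for one variable."""

    F: float
    df_effect: int
    df_error: int
    p: float
    partial_eta_sq: float
    pairwise: list[PairwiseResult] = field(default_factory=list)
    levene_p: float | None = None
    ks_p: dict[str, float] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    # Greenhouse-Geisser corrected values, populated on request
    gg_epsilon: float | None = None
    p_gg: float | None = None


def _check_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a subjects x conditions table; drop incomplete rows."""
    if table.shape[1] < 2:
        raise ValueError("need at least 2 conditions")
    complete = table.dropna()
    if complete.shape[0] < 2:
        raise ValueError("need at least 2 complete-case subjects")
    return complete


def average_repetitions(
    trials: pd.DataFrame,
    value: str = "value",
    participant: str = "participant",
    condition: str = "condition",
) -> tuple[pd.DataFrame, list[str]]:
    """Per-participant-condition means over repetitions, as a wide table.

    Returns ``(table, excluded)``: subjects x conditions DataFrame and the
    participants dropped listwise because some condition had no trials.
    Missing repetitions within a cell are simply averaged over what exists.
    """
    means = trials.groupby([participant, condition], sort=True)[value].mean()
    wide = means.unstack(condition)
    excluded = sorted(wide.index[wide.isna().any(axis=1)].astype(str))
    wide = wide.dropna()
    return wide, excluded


def rm_anova(table: pd.DataFrame) -> StatsResult:
    """One-way repeated-measures ANOVA on a subjects x conditions table.

    Within-subjects decomposition: total SS splits into subject, condition
    and error components; ``F = MS_condition / MS_error`` and
    ``partial_eta_sq = SS_condition / (SS_condition + SS_error)``.
    Uncorrected degrees of freedom by default; Greenhouse-Geisser adjusted
    p is available through :func:`greenhouse_geisser`.
    """
    table = _check_table(table)
    x = table.to_numpy(dtype=float)
    n, k = x.shape
    grand = x.mean()
    ss_subject = k * np.sum((x.mean(axis=1) - grand) ** 2)
    ss_cond = n * np.sum((x.mean(axis=0) - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_subject - ss_cond

    df_effect = k - 1
    df_error = (n - 1) * (k - 1)
    ms_cond = ss_cond / df_effect
    ms_err = ss_err / df_error
    flags: list[str] = []
    if ms_err <= 0:
        if ss_cond == 0:
            f_val, p, eta = 0.0, 1.0, 0.0
        else:
            f_val, p, eta = math.inf, 0.0, 1.0
        flags.append("zero error variance: F undefined/degenerate")
    else:
        f_val = ms_cond / ms_err
        p = float(sps.f.sf(f_val, df_effect, df_error))
        eta = ss_cond / (ss_cond + ss_err)
    return StatsResult(
        F=float(f_val),
        df_effect=df_effect,
        df_error=df_error,
        p=float(p),
        partial_eta_sq=float(eta),
        flags=flags,
    )


def greenhouse_geisser(table: pd.DataFrame) -> StatsResult:
    """RM-ANOVA with Greenhouse-Geisser sphericity correction applied."""
    result = rm_anova(table)
    x = _check_table(table).to_numpy(dtype=float)
    n, k = x.shape
    centered = x - x.mean(axis=0, keepdims=True)
    cov = np.cov(centered, rowvar=False)
    mean_var = np.trace(cov) / k
    mean_all = cov.mean()
    row_means = cov.mean(axis=1)
    num = (k * (mean_var - mean_all)) ** 2
    den = (k - 1) * (
        np.sum(cov**2) - 2 * k * np.sum(row_means**2) + k**2 * mean_all**2
    )
    eps = float(num / den) if den > 0 else 1.0
    eps = min(1.0, max(1.0 / (k - 1), eps))
    result.gg_epsilon = eps
    if math.isfinite(result.F):
        result.p_gg = float(
            sps.f.sf(result.F, eps * result.df_effect, eps * result.df_error)
        )
    return result


def bonferroni_pairwise(table: pd.DataFrame) -> list[PairwiseResult]:
    """Paired t-tests on all condition pairs, p multiplied by the number of
    pairs (capped at 1)."""
    table = _check_table(table)
    cols = list(table.columns)
    pairs = list(combinations(cols, 2))
    m = len(pairs)
    out: list[PairwiseResult] = []
    for a, b in pairs:
        diff = table[a].to_numpy(float) - table[b].to_numpy(float)
        n = len(diff)
        if np.allclose(diff.std(ddof=1), 0.0):
            p_raw = 1.0 if np.allclose(diff.mean(), 0.0) else 0.0
            out.append(
                PairwiseResult(
                    pair=(a, b),
                    t=float("nan"),
                    df=n - 1,
                    p_raw=p_raw,
                    p_adjusted=min(1.0, p_raw * m),
                    flagged=True,
                )
            )
            continue
        t_stat, p_raw = sps.ttest_rel(table[a], table[b])
        out.append(
            PairwiseResult(
                pair=(a, b),
                t=float(t_stat),
                df=n - 1,
                p_raw=float(p_raw),
                p_adjusted=float(min(1.0, p_raw * m)),
            )
        )
    return out


def assumption_checks(table: pd.DataFrame) -> tuple[float, dict[str, float]]:
    """Levene's test across conditions; per-condition one-sample KS against a
    normal with the sample's own moments.

    Returns ``(levene_p, {condition: ks_p})``.
    """
    table = _check_table(table)
    groups = [table[c].to_numpy(float) for c in table.columns]
    if any(len(g) < 3 for g in groups):
        raise ValueError("need n >= 3 per condition for assumption checks")
    if all(np.allclose(g.std(ddof=1), groups[0].std(ddof=1)) for g in groups) and all(
        np.allclose(g.std(ddof=1), 0.0) for g in groups
    ):
        levene_p = 1.0
    else:
        _, levene_p = sps.levene(*groups)
    ks: dict[str, float] = {}
    for c in table.columns:
        g = table[c].to_numpy(float)
        sd = g.std(ddof=1)
        if sd == 0:
            ks[str(c)] = float("nan")
        else:
            _, p = sps.kstest(g, "norm", args=(g.mean(), sd))
            ks[str(c)] = float(p)
    return float(levene_p), ks


def percent_change(value_a: float, value_b: float) -> float:
    """Signed percent change of A relative to B: ``100 * (A - B) / B``."""
    if value_b == 0:
        raise ZeroDivisionError("reference value is zero")
    return 100.0 * (value_a - value_b) / value_b


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (report convention)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def format_percent_change(value_a: float, value_b: float) -> int:
    """Reported percent-change magnitude: nearest integer, half away from 0."""
    return round_half_away(abs(percent_change(value_a, value_b)))


def cohens_d_paired(a: Sequence[float], b: Sequence[float]) -> float:
    """Paired-samples Cohen's d: mean difference over SD of differences."""
    diff = np.asarray(a, float) - np.asarray(b, float)
    sd = diff.std(ddof=1)
    if sd == 0:
        return float("nan")
    return float(diff.mean() / sd)


def build_condition_table(
    tables: Mapping[str, pd.DataFrame],
    conditions: Sequence[str] = CONDITIONS,
    absent: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Condition summary: ``mean (SD)`` per condition plus ANOVA p and eta^2.

    ``tables`` maps variable name to its subjects x conditions table;
    ``absent`` maps variable name to conditions where the variable does not
    exist (reported as '-', e.g. the phone AOI without a phone in view).
    A single-participant table gets flagged SDs rather than statistics.
    """
    absent = dict(absent or {})
    rows = []
    for name, table in tables.items():
        row: dict[str, object] = {"variable": name}
        skip = set(absent.get(name, ()))
        present_cols = [c for c in conditions if c in table.columns and c not in skip]
        for cond in conditions:
            if cond in skip or cond not in table.columns:
                row[cond] = "-"
                continue
            vals = table[cond].dropna().to_numpy(float)
            mean = vals.mean()
            sd = vals.std(ddof=1) if len(vals) > 1 else 0.0
            row[cond] = f"{mean:.2f} ({sd:.2f})"
        sub = table[present_cols].dropna()
        if sub.shape[0] >= 2 and len(present_cols) >= 2:
            res = rm_anova(sub)
            row["p"] = res.p
            row["partial_eta_sq"] = res.partial_eta_sq
            sig = [
                f"{pr.pair[0]} vs {pr.pair[1]}"
                for pr in bonferroni_pairwise(sub)
                if pr.p_adjusted < 0.05
            ]
            row["significant_pairs"] = "; ".join(sig)
        else:
            row["p"] = float("nan")
            row["partial_eta_sq"] = float("nan")
            row["significant_pairs"] = "insufficient data"
        rows.append(row)
    return pd.DataFrame(rows).set_index("variable")


def repetition_effect_check(durations: pd.DataFrame) -> StatsResult:
    """RM-ANOVA over trial position (e.g. first/mid/last trial durations)."""
    return rm_anova(durations)
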