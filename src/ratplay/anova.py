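"""Balanced one-way repeated-measures ANOVA with Bonferroni pairwise tests.

Used for three questions: whether some animals in a group are consistently
more popular than others (within factor = target animal, 6 levels, subjects
= the 5 rater slots x 4 days = 20 repeated units, so df = (5, 95)); whether
a given animal's popularity changes from day to day (within factor = day);
and whether groups differ in total play output (within factor = group,
subjects = days, df = (7, 21) at the 8-group x 4-day design).

Sums of squares are computed directly from the balanced-table identities so
that degenerate inputs (zero between-level variance) yield F = 0 instead of
0/0; no sphericity correction is applied by default, matching how such
designs are conventionally reported, with Greenhouse-Geisser available as
an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .events import ValidationError


@dataclass
class RMAnovaResult:
    """One-way within-subjects ANOVA summary.

    ``pairwise`` holds Bonferroni-adjusted paired comparisons between factor
    levels; the family size ``m`` (number of level pairs) is recorded on
    every row.
    """

    factor: str
    df_factor: int
    df_error: int
    F: float
    p: float
    n_subjects: int
    levels: tuple
    pairwise: pd.DataFrame = field(default_factory=pd.DataFrame)
    gg_epsilon: float | None = None

    def __str__(self):
        return (f"F({self.df_factor},{self.df_error}) = {self.F:.3f}, "
                f"p = {self.p:.4g}")


def rm_anova(data: pd.DataFrame, subject: str, within: str, value: str,
             pairwise: bool = True,
             greenhouse_geisser: bool = False) -> RMAnovaResult:
    """Balanced one-way repeated-measures ANOVA on a long-format table.

    Every subject must appear exactly once at every level of ``within``;
    an unbalanced table raises :class:`ValidationError` naming the first
    offending (subject, level) cell.
    """
    wide = data.pivot_table(index=subject, columns=within, values=value,
                            aggfunc="count")
    bad = wide.isna() | (wide != 1)
    if bad.to_numpy().any():
        subj_idx, lev_idx = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"unbalanced design at subject {wide.index[subj_idx]!r}, "
            f"{within} = {wide.columns[lev_idx]!r}")
    table = data.pivot(index=subject, columns=within, values=value)
    y = table.to_numpy(dtype=float)
    n, k = y.shape
    if n < 2 or k < 2:
        raise ValidationError("need >= 2 subjects and >= 2 levels")

    grand = y.mean()
    ss_factor = n * ((y.mean(axis=0) - grand) ** 2).sum()
    ss_subject = k * ((y.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((y - grand) ** 2).sum()
    ss_error = max(ss_total - ss_factor - ss_subject, 0.0)

    df_factor, df_error = k - 1, (k - 1) * (n - 1)
    eps = None
    if greenhouse_geisser:
        eps = _gg_epsilon(y)
        df_factor_f = df_factor * eps
        df_error_f = df_error * eps
    else:
        df_factor_f, df_error_f = float(df_factor), float(df_error)

    ms_factor = ss_factor / df_factor
    ms_error = ss_error / df_error
    if ms_factor == 0.0:
        f_stat, p = 0.0, 1.0
    elif ms_error == 0.0:
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = ms_factor / ms_error
        p = float(stats.f.sf(f_stat, df_factor_f, df_error_f))

    pw = _pairwise_bonferroni(table) if pairwise else pd.DataFrame()
    return RMAnovaResult(factor=within, df_factor=df_factor,
                         df_error=df_error, F=float(f_stat), p=p,
                         n_subjects=n, levels=tuple(table.columns),
                         pairwise=pw, gg_epsilon=eps)


def _gg_epsilon(y: np.ndarray) -> float:
    """Greenhouse-Geisser sphericity epsilon from the sample covariance."""
    k = y.shape[1]
    s = np.cov(y, rowvar=False)
    mean_diag = np.trace(s) / k
    mean_all = s.mean()
    num = (k * (mean_diag - mean_all)) ** 2
    den = (k - 1) * ((s ** 2).sum() - 2 * k * (s.mean(axis=1) ** 2).sum()
                     + k ** 2 * mean_all ** 2)
    return float(num / den) if den > 0 else 1.0


def _pairwise_bonferroni(table: pd.DataFrame) -> pd.DataFrame:
    levels = list(table.columns)
    m = len(levels) * (len(levels) - 1) // 2
    rows = []
    for a, b in combinations(levels, 2):
        diff = table[a].to_numpy(dtype=float) - table[b].to_numpy(dtype=float)
        if np.allclose(diff.std(ddof=1), 0.0):
            t_val, p_raw = (0.0, 1.0) if np.allclose(diff.mean(), 0.0) \
                else (float("inf"), 0.0)
        else:
            t_val, p_raw = stats.ttest_rel(table[a], table[b])
        rows.append({"level_a": a, "level_b": b, "t": float(t_val),
                     "p_raw": float(p_raw),
                     "p_adj": min(1.0, float(p_raw) * m), "m": m})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# study-specific wrappers


def popularity_anova(pop: pd.DataFrame, group_id: int,
                     **kwargs) -> RMAnovaResult:
    """Is some animal of a group consistently more popular than others?

    ``pop`` is the long popularity table (group_id, day, rater, target, pct).
    Within factor: target identity (k levels).  Repeated units: each of the
    ``k - 1`` rater slots on each day.  Because a target cannot rate itself,
    raters are mapped to slots by label order among the target's partners,
    giving a balanced k x ((k-1) x n_days) table and df = (5, 95) at the
    six-animal, four-day design.
    """
    sub = pop[pop["group_id"] == group_id].copy()
    if sub.empty:
        raise ValidationError(f"no popularity rows for group {group_id}")

    def slot(row):
        others = sorted(set(sub["rater"]) - {row["target"]})
        return others.index(row["rater"]) + 1

    sub["slot"] = sub.apply(slot, axis=1)
    sub["unit"] = ("s" + sub["slot"].astype(str) + "_d"
                   + sub["day"].astype(str))
    return rm_anova(sub, subject="unit", within="target", value="pct",
                    **kwargs)


def daily_popularity_anova(pop: pd.DataFrame, group_id: int, target: str,
                           **kwargs) -> RMAnovaResult:
    """Does the play directed toward one animal change from day to day?

    Within factor: day; subjects: the animal's k-1 raters.
    """
    sub = pop[(pop["group_id"] == group_id) & (pop["target"] == target)]
    if sub.empty:
        raise ValidationError(
            f"no popularity rows for group {group_id} target {target!r}")
    return rm_anova(sub, subject="rater", within="day", value="pct", **kwargs)


def group_totals_anova(totals: pd.DataFrame, **kwargs) -> RMAnovaResult:
    """Do groups differ in total play output across days?

    ``totals`` has columns (group_id, day, total_attacks); within factor:
    group, subjects: days, so df = (G-1, (G-1)(D-1)) = (7, 21) at the
    8-group x 4-day design.
    """
    needed = {"group_id", "day", "total_attacks"}
    if not needed <= set(totals.columns):
        raise ValidationError(f"totals table needs columns {sorted(needed)}")
    return rm_anova(totals, subject="day", within="group_id",
                    value="total_attacks", **kwargs)


def anova_results_frame(results: dict[str, RMAnovaResult]) -> pd.DataFrame:
    rows = []
    for name, res in results.items():
        rows.append({"test": name, "factor": res.factor,
                     "df_factor": res.df_factor, "df_error": res.df_error,
                     "F": res.F, "p": res.p, "n_subjects": res.n_subjects})
    return pd.DataFrame(rows)
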