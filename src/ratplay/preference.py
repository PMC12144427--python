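"""Partner-preference scores and related per-animal metrics.

The central statistic is the observed-over-expected preference index for a
directed dyad::

    I_ij = B_ij / (B_i / (k - 1))

where ``B_ij`` is the number of nape attacks i initiated on j, ``B_i`` the
total attacks i initiated and ``k`` the group size.  Under equal use of all
``k - 1`` partners every index is 1; ``I >= 2`` marks a strong preference
and ``I <= 0.25`` avoidance (fewer interactions than expected by chance).
By construction the index averages exactly 1 over an initiator's partners
whenever ``B_i > 0``.

The module also implements play symmetry (1 minus the normalised absolute
difference of the two directed counts of a dyad), popularity (percentage of
each rater's play received by each target), daily z-scores of play output,
day-to-day favourite/least-favourite rank-change stability, tube-test
dominance ranking, and the partner-availability correction that restricts
counts to attacks launched when every partner was free.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .events import AttackEvent, CountMatrix, ProportionMatrix, ValidationError

#: Classification thresholds for the preference index.
STRONG_THRESHOLD = 2.0
AVOIDED_THRESHOLD = 0.25
CHANCE = 1.0

#: z-score magnitude flagged as significantly above/below the daily mean.
Z_CUTOFF = 1.96


def classify_index(index: float, strong: float = STRONG_THRESHOLD,
                   avoided: float = AVOIDED_THRESHOLD) -> str:
    """Map an index value to its preference class.

    ``strong_preferred`` at ``I >= strong``; ``preferred`` for ``I > 1``
    below that; ``avoided`` at ``I <= avoided``; otherwise ``chance``.
    """
    if index >= strong:
        return "strong_preferred"
    if index > CHANCE:
        return "preferred"
    if index <= avoided:
        return "avoided"
    return "chance"


def thompson_index(counts: CountMatrix, strong: float = STRONG_THRESHOLD,
                   avoided: float = AVOIDED_THRESHOLD) -> pd.DataFrame:
    """Preference index table for every directed dyad of one group-day.

    Returns columns (group_id, day, initiator, recipient, count, index,
    classification, undefined).  Initiators that never attacked (B_i = 0)
    get NaN indices flagged ``undefined``.
    """
    if counts.k < 2:
        raise ValidationError("need k >= 2 for preference indices")
    totals = counts.row_totals
    rows = []
    for i, a in enumerate(counts.labels):
        for j, b in enumerate(counts.labels):
            if i == j:
                continue
            if totals[i] == 0:
                idx, cls, undef = float("nan"), "undefined", True
            else:
                idx = counts.counts[i, j] * (counts.k - 1) / totals[i]
                cls, undef = classify_index(idx, strong, avoided), False
            rows.append({"group_id": counts.group_id, "day": counts.day,
                         "initiator": a, "recipient": b,
                         "count": int(counts.counts[i, j]),
                         "index": idx, "classification": cls,
                         "undefined": undef})
    return pd.DataFrame(rows)


def symmetry(counts: CountMatrix, a: str, b: str) -> float:
    """Play symmetry of the unordered dyad (a, b).

    ``1 - |B_ab - B_ba| / (B_ab + B_ba)``: 1 = perfectly reciprocal,
    0 = entirely one-sided.  NaN when the dyad never played.
    """
    i, j = counts.labels.index(a), counts.labels.index(b)
    x, y = int(counts.counts[i, j]), int(counts.counts[j, i])
    total = x + y
    if total == 0:
        return float("nan")
    return 1.0 - abs(x - y) / total


def symmetry_table(counts: CountMatrix) -> pd.DataFrame:
    """Symmetry for all unordered dyads; zero-play dyads flagged undefined."""
    rows = []
    for i in range(counts.k):
        for j in range(i + 1, counts.k):
            a, b = counts.labels[i], counts.labels[j]
            s = symmetry(counts, a, b)
            rows.append({"group_id": counts.group_id, "day": counts.day,
                         "animal_a": a, "animal_b": b, "symmetry": s,
                         "undefined": bool(np.isnan(s))})
    return pd.DataFrame(rows)


def popularity(props: ProportionMatrix) -> pd.DataFrame:
    """Percent of each rater's play received by each target.

    One row per (rater, target) ordered pair; a rater's percentages over its
    ``k - 1`` targets sum to 100 whenever the rater initiated any play.
    """
    rows = []
    for i, rater in enumerate(props.labels):
        for j, target in enumerate(props.labels):
            if i == j:
                continue
            rows.append({
                "group_id": props.group_id, "day": props.day,
                "rater": rater, "target": target,
                "pct": float(props.proportions[i, j] * 100.0),
                "rater_silent": bool(props.zero_rows[i]),
            })
    return pd.DataFrame(rows)


def daily_zscores(counts: CountMatrix, z_cutoff: float = Z_CUTOFF
                  ) -> pd.DataFrame:
    """z-score of each animal's total play initiated on one group-day.

    Uses the sample SD across the group's animals (ddof = 1).  A day where
    every animal initiated the same number of attacks has zero SD: the
    deviations are all zero, so z = 0, but significance cannot be assessed
    and the rows are flagged undefined.  ``|z| >= z_cutoff`` is flagged as
    significantly above/below the daily mean.
    """
    totals = counts.row_totals.astype(float)
    if counts.k < 2:
        raise ValidationError("need >= 2 animals for z-scores")
    mean = totals.mean()
    sd = totals.std(ddof=1)
    rows = []
    for a, t in zip(counts.labels, totals):
        if sd == 0:
            z, flag, undef = 0.0, "undefined", True
        else:
            z = (t - mean) / sd
            undef = False
            if z >= z_cutoff:
                flag = "above"
            elif z <= -z_cutoff:
                flag = "below"
            else:
                flag = "ns"
        rows.append({"group_id": counts.group_id, "day": counts.day,
                     "animal_id": a, "initiated": int(t), "z": z,
                     "flag": flag, "undefined": undef})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# preference stability


def partner_ranks(props: ProportionMatrix) -> pd.DataFrame:
    """Rank each initiator's partners 1 (favourite) .. k-1 (least favourite)
    by proportion of play directed at them; ties broken by recipient label
    (flagged)."""
    rows = []
    for i, a in enumerate(props.labels):
        partners = [(props.labels[j], float(props.proportions[i, j]))
                    for j in range(props.k) if j != i]
        ordered = sorted(partners, key=lambda t: (-t[1], t[0]))
        values = [v for _, v in ordered]
        tied = len(set(values)) != len(values)
        for rank, (b, v) in enumerate(ordered, start=1):
            rows.append({"group_id": props.group_id, "day": props.day,
                         "initiator": a, "recipient": b, "proportion": v,
                         "rank": rank, "tied": tied})
    return pd.DataFrame(rows)


def rank_change(day_props: Mapping[int, ProportionMatrix],
                day_pairs: Sequence[tuple[int, int]] = ((1, 3), (3, 5), (5, 8))
                ) -> pd.DataFrame:
    """Day-to-day stability of the favourite and least favourite partner.

    For each animal and consecutive scored-day pair, the favourite change is
    yesterday's rank of today's favourite minus 1, and the least-favourite
    change is ``k - 1`` minus yesterday's rank of today's least favourite.
    0 = same partner both days; ``k - 2`` (= 4 for groups of six) = complete
    reversal.
    """
    ranks = {day: partner_ranks(pm) for day, pm in day_props.items()}
    rows = []
    for prev_day, day in day_pairs:
        if prev_day not in ranks or day not in ranks:
            raise ValidationError(
                f"missing day {prev_day if prev_day not in ranks else day} "
                "for rank-change computation")
        prev_df, cur_df = ranks[prev_day], ranks[day]
        kminus1 = cur_df.groupby("initiator")["rank"].max().iloc[0]
        for a, sub in cur_df.groupby("initiator"):
            prev_sub = prev_df[prev_df["initiator"] == a]
            prev_rank = dict(zip(prev_sub["recipient"], prev_sub["rank"]))
            favorite = sub.loc[sub["rank"] == 1, "recipient"].iloc[0]
            least = sub.loc[sub["rank"] == kminus1, "recipient"].iloc[0]
            rows.append({
                "group_id": sub["group_id"].iloc[0], "day_prev": prev_day,
                "day": day, "animal_id": a,
                "favorite_change": int(prev_rank[favorite] - 1),
                "least_favorite_change": int(kminus1 - prev_rank[least]),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dominance


def tube_rank(trials: pd.DataFrame) -> pd.DataFrame:
    """Win tallies and dominance ranks from tube-test trials of one group.

    Each win scores one point; ties score nothing.  Ranks are assigned by
    descending tally (1 = most dominant); equal tallies are broken by
    animal_id order and flagged ``tied``.
    """
    required = {"animal_a", "animal_b", "outcome"}
    if not required <= set(trials.columns):
        raise ValidationError(f"tube trials need columns {sorted(required)}")
    animals = sorted(set(trials["animal_a"]) | set(trials["animal_b"]))
    pairs_seen = {tuple(sorted(p))
                  for p in zip(trials["animal_a"], trials["animal_b"])}
    for i, a in enumerate(animals):
        for b in animals[i + 1:]:
            if (a, b) not in pairs_seen:
                raise ValidationError(f"missing tube-test pair ({a}, {b})")
    wins = {a: 0 for a in animals}
    for t in trials.itertuples():
        if t.outcome == "win_a":
            wins[t.animal_a] += 1
        elif t.outcome == "win_b":
            wins[t.animal_b] += 1
        elif t.outcome != "tie":
            raise ValidationError(f"bad tube outcome {t.outcome!r}")
    ordered = sorted(animals, key=lambda a: (-wins[a], a))
    tallies = [wins[a] for a in ordered]
    rows = []
    for rank, a in enumerate(ordered, start=1):
        rows.append({"animal_id": a, "wins": wins[a], "rank": rank,
                     "tied": tallies.count(wins[a]) > 1})
    group_id = trials["group_id"].iloc[0] if "group_id" in trials else None
    df = pd.DataFrame(rows)
    if group_id is not None:
        df.insert(0, "group_id", group_id)
    return df


# ---------------------------------------------------------------------------
# partner-availability correction


@dataclass
class AvailabilityResult:
    """Availability-corrected counts for the classified (focal) dyads.

    ``fraction_retained`` is the share of the original attacks launched when
    all partners were free.  ``table`` has one row per focal dyad with its
    adjusted count, the initiator's median adjusted count across partners,
    and whether the dyad still sits on the predicted side of that median
    (above for preferred, below for avoided; ties at the median count as
    failures and are flagged).
    """

    fraction_retained: float
    table: pd.DataFrame
    adjusted: dict[tuple[int, int], CountMatrix]


def availability_adjusted_counts(events: Iterable[AttackEvent],
                                 focal_dyads: pd.DataFrame,
                                 labels: Sequence[str]) -> AvailabilityResult:
    """Restrict attack counts to moments when all partners were available.

    ``focal_dyads`` must carry columns (group_id, day, initiator, recipient,
    classification) for the strong_preferred / avoided dyads to audit.
    """
    events = list(events)
    n_total = len(events)
    kept = [ev for ev in events if ev.all_available]
    fraction = len(kept) / n_total if n_total else 0.0

    labels = tuple(labels)
    index = {a: i for i, a in enumerate(labels)}
    adjusted: dict[tuple[int, int], np.ndarray] = {}
    for ev in kept:
        key = (ev.group_id, ev.day)
        mat = adjusted.setdefault(
            key, np.zeros((len(labels), len(labels)), dtype=np.int64))
        mat[index[ev.initiator], index[ev.recipient]] += 1

    matrices = {key: CountMatrix(key[0], key[1], labels, mat)
                for key, mat in adjusted.items()}

    rows = []
    for rec in focal_dyads.itertuples():
        key = (rec.group_id, rec.day)
        mat = adjusted.get(
            key, np.zeros((len(labels), len(labels)), dtype=np.int64))
        i = index[rec.initiator]
        partner_counts = np.delete(mat[i], i)
        med = float(np.median(partner_counts))
        count = int(mat[i, index[rec.recipient]])
        if rec.classification == "strong_preferred":
            success = count > med
        elif rec.classification == "avoided":
            success = count < med
        else:
            raise ValidationError(
                f"focal dyad with class {rec.classification!r}; expected "
                "strong_preferred or avoided")
        rows.append({"group_id": rec.group_id, "day": rec.day,
                     "initiator": rec.initiator, "recipient": rec.recipient,
                     "classification": rec.classification,
                     "adjusted_count": count, "median_adjusted": med,
                     "at_median": count == med, "success": bool(success)})
    table = pd.DataFrame(rows, columns=[
        "group_id", "day", "initiator", "recipient", "classification",
        "adjusted_count", "median_adjusted", "at_median", "success"])
    return AvailabilityResult(fraction_retained=fraction, table=table,
                              adjusted=matrices)
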