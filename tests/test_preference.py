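"""Preference index, symmetry, popularity, z-scores, stability, dominance,
availability correction."""

import numpy as np
import pandas as pd
import pytest

from ratplay.events import CountMatrix, ValidationError, to_proportions
from ratplay.preference import (availability_adjusted_counts, daily_zscores,
                                partner_ranks, popularity, rank_change,
                                symmetry, symmetry_table, thompson_index,
                                tube_rank)

from conftest import LABELS, make_event, random_count_matrix


def matrix_with_row(row, k=6):
    counts = np.zeros((k, k), int)
    counts[0, 1:] = row
    return CountMatrix(1, 1, LABELS[:k], counts)


class TestThompsonIndex:
    def test_uniform_play_is_chance(self):
        ti = thompson_index(matrix_with_row([10, 10, 10, 10, 10]))
        a_rows = ti[ti.initiator == "A"]
        assert np.allclose(a_rows["index"], 1.0)
        assert (a_rows["classification"] == "chance").all()

    def test_worked_arithmetic_at_thresholds(self):
        """20 of 50 attacks on one partner of five -> I = 2.0 (strong);
        2 of 50 -> I = 0.2 (avoided)."""
        ti = thompson_index(matrix_with_row([20, 10, 10, 8, 2]))
        a = ti[ti.initiator == "A"].set_index("recipient")
        assert a.loc["B", "index"] == pytest.approx(2.0)
        assert a.loc["B", "classification"] == "strong_preferred"
        assert a.loc["F", "index"] == pytest.approx(0.2)
        assert a.loc["F", "classification"] == "avoided"
        assert a.loc["C", "classification"] == "chance"

    def test_boundary_classifications(self):
        # I exactly 2 is strong; exactly 0.25 avoided; exactly 1 chance
        ti = thompson_index(matrix_with_row([8, 1, 4, 2, 1]))  # B_i=16
        a = ti[ti.initiator == "A"].set_index("recipient")
        assert a.loc["B", "index"] == pytest.approx(2.5)
        ti2 = thompson_index(matrix_with_row([2, 10, 12, 8, 8]))  # B_i=40
        a2 = ti2[ti2.initiator == "A"].set_index("recipient")
        assert a2.loc["B", "index"] == pytest.approx(0.25)
        assert a2.loc["B", "classification"] == "avoided"

    def test_per_initiator_mean_is_exactly_one(self, rng):
        for _ in range(100):
            cm = random_count_matrix(rng)
            ti = thompson_index(cm)
            for a, sub in ti.groupby("initiator"):
                if sub["undefined"].any():
                    continue
                assert abs(sub["index"].mean() - 1.0) < 1e-12

    def test_silent_initiator_flagged(self):
        ti = thompson_index(matrix_with_row([0, 0, 0, 0, 0]))
        a = ti[ti.initiator == "A"]
        assert a["undefined"].all()
        assert a["index"].isna().all()

    def test_k_below_two_rejected(self):
        with pytest.raises(ValidationError):
            thompson_index(CountMatrix(1, 1, ("A",), np.zeros((1, 1), int)))


class TestSymmetry:
    @pytest.mark.parametrize("x, y, expected", [
        (10, 10, 1.0), (10, 0, 0.0), (15, 5, 0.5)])
    def test_closed_form_cases(self, x, y, expected):
        counts = np.zeros((6, 6), int)
        counts[0, 1], counts[1, 0] = x, y
        cm = CountMatrix(1, 1, LABELS, counts)
        assert symmetry(cm, "A", "B") == pytest.approx(expected)

    def test_symmetric_in_dyad_order(self, rng):
        for _ in range(100):
            cm = random_count_matrix(rng)
            for a in LABELS:
                for b in LABELS:
                    if a < b:
                        assert symmetry(cm, a, b) == symmetry(cm, b, a)

    def test_zero_play_dyad_flagged(self):
        cm = matrix_with_row([5, 0, 0, 0, 0])
        tab = symmetry_table(cm).set_index(["animal_a", "animal_b"])
        assert tab.loc[("C", "D"), "undefined"]
        assert np.isnan(tab.loc[("C", "D"), "symmetry"])
        assert not tab.loc[("A", "B"), "undefined"]


class TestPopularity:
    def test_uniform_rater(self):
        pop = popularity(to_proportions(matrix_with_row([2, 2, 2, 2, 2])))
        a = pop[pop.rater == "A"]
        assert np.allclose(a["pct"], 20.0)

    def test_single_target_rater(self):
        pop = popularity(to_proportions(matrix_with_row([7, 0, 0, 0, 0])))
        a = pop[pop.rater == "A"].set_index("target")
        assert a.loc["B", "pct"] == 100.0
        assert (a.drop("B")["pct"] == 0.0).all()

    def test_percentages_sum_to_100(self, rng):
        for _ in range(30):
            cm = random_count_matrix(rng)
            pop = popularity(to_proportions(cm))
            sums = pop.groupby("rater")["pct"].sum()
            silent = pop.groupby("rater")["rater_silent"].first()
            assert np.allclose(sums[~silent], 100.0, atol=1e-9)


class TestDailyZScores:
    def test_all_equal_gives_zero_flagged(self):
        counts = np.full((6, 6), 2, int)
        np.fill_diagonal(counts, 0)
        z = daily_zscores(CountMatrix(1, 1, LABELS, counts))
        assert (z["z"] == 0.0).all()
        assert z["undefined"].all()

    def test_outlier_hand_oracle(self):
        """Totals (10,10,10,10,10,22): mean 12, sample SD sqrt(24), so the
        outlier's z is 10/sqrt(24) ~ 2.0412 and uniquely maximal."""
        counts = np.zeros((6, 6), int)
        for i, total in enumerate([10, 10, 10, 10, 10, 22]):
            j = (i + 1) % 6
            counts[i, j] = total
        z = daily_zscores(CountMatrix(1, 1, LABELS, counts))
        zf = z.set_index("animal_id")["z"]
        assert zf["F"] == pytest.approx(10 / np.sqrt(24))
        assert zf["F"] > zf.drop("F").max()
        assert z.set_index("animal_id").loc["F", "flag"] == "above"

    def test_centering_identity(self, rng):
        for _ in range(20):
            cm = random_count_matrix(rng)
            z = daily_zscores(cm)
            if not z["undefined"].any():
                assert abs(z["z"].sum()) < 1e-9


def day_matrix(rows_by_initiator):
    """Counts from {initiator: {recipient: count}}."""
    counts = np.zeros((6, 6), int)
    for a, row in rows_by_initiator.items():
        for b, c in row.items():
            counts[LABELS.index(a), LABELS.index(b)] = c
    return CountMatrix(1, 1, LABELS, counts)


class TestRankChange:
    def props_for_favorites(self, order):
        """Proportions where A's partners rank in the given order."""
        weights = {b: 60 - 10 * i for i, b in enumerate(order)}
        cm = day_matrix({"A": weights,
                         **{b: {"A": 5} for b in LABELS[1:]}})
        return to_proportions(cm)

    def test_worked_examples(self):
        """Same favourite -> 0; yesterday's rank-2 -> 1; yesterday's
        least favourite -> 4."""
        base = self.props_for_favorites(["B", "C", "D", "E", "F"])
        same = self.props_for_favorites(["B", "C", "D", "E", "F"])
        swap = self.props_for_favorites(["C", "B", "D", "E", "F"])
        flip = self.props_for_favorites(["F", "C", "D", "E", "B"])
        for today, expected in ((same, 0), (swap, 1), (flip, 4)):
            rc = rank_change({1: base, 3: today}, day_pairs=((1, 3),))
            a = rc[rc.animal_id == "A"].iloc[0]
            assert a["favorite_change"] == expected

    def test_least_favorite_change(self):
        base = self.props_for_favorites(["B", "C", "D", "E", "F"])
        flip = self.props_for_favorites(["F", "C", "D", "E", "B"])
        rc = rank_change({1: base, 3: flip}, day_pairs=((1, 3),))
        # today's least favourite (B) was yesterday's favourite (rank 1)
        assert rc[rc.animal_id == "A"].iloc[0]["least_favorite_change"] == 4

    def test_changes_bounded(self, rng):
        for _ in range(10):
            props = {d: to_proportions(random_count_matrix(rng, day=d))
                     for d in (1, 3, 5, 8)}
            rc = rank_change(props)
            assert rc["favorite_change"].between(0, 4).all()
            assert rc["least_favorite_change"].between(0, 4).all()

    def test_missing_day_rejected(self):
        base = self.props_for_favorites(["B", "C", "D", "E", "F"])
        with pytest.raises(ValidationError, match="missing day"):
            rank_change({1: base}, day_pairs=((1, 3),))


class TestTubeRank:
    def trials(self, outcomes):
        rows = []
        for (a, b), outs in outcomes.items():
            for t, o in enumerate(outs, 1):
                rows.append({"group_id": 1, "animal_a": a, "animal_b": b,
                             "trial": t, "outcome": o})
        return pd.DataFrame(rows)

    def all_pairs(self, fill="tie"):
        return {(a, b): [fill] * 5
                for i, a in enumerate(LABELS) for b in LABELS[i + 1:]}

    def test_sweeping_winner(self):
        outs = self.all_pairs("tie")
        for b in LABELS[1:]:
            outs[("A", b)] = ["win_a"] * 5
        ranks = tube_rank(self.trials(outs)).set_index("animal_id")
        assert ranks.loc["A", "wins"] == 25
        assert ranks.loc["A", "rank"] == 1

    def test_all_ties(self):
        ranks = tube_rank(self.trials(self.all_pairs("tie")))
        assert (ranks["wins"] == 0).all()
        assert ranks["tied"].all()

    def test_mixed_fixture_matches_hand_count(self):
        outs = self.all_pairs("tie")
        outs[("A", "B")] = ["win_a", "win_b", "win_a", "tie", "win_a"]
        outs[("C", "D")] = ["win_b"] * 5
        ranks = tube_rank(self.trials(outs)).set_index("animal_id")
        assert ranks.loc["A", "wins"] == 3
        assert ranks.loc["B", "wins"] == 1
        assert ranks.loc["D", "wins"] == 5
        assert ranks.loc["D", "rank"] == 1

    def test_missing_pair_rejected(self):
        outs = self.all_pairs()
        del outs[("A", "B")]
        with pytest.raises(ValidationError, match="missing tube-test pair"):
            tube_rank(self.trials(outs))


class TestAvailability:
    def events_with_availability(self, flags):
        return [make_event("A", "B", time_s=float(i),
                           n_partners_available=5 if f else 3)
                for i, f in enumerate(flags)]

    def focal(self, classification="strong_preferred"):
        return pd.DataFrame([{"group_id": 1, "day": 1, "initiator": "A",
                              "recipient": "B",
                              "classification": classification}])

    def test_all_available(self):
        res = availability_adjusted_counts(
            self.events_with_availability([True] * 10), self.focal(), LABELS)
        assert res.fraction_retained == 1.0
        assert res.adjusted[(1, 1)].counts[0, 1] == 10

    def test_none_available(self):
        res = availability_adjusted_counts(
            self.events_with_availability([False] * 10), self.focal(),
            LABELS)
        assert res.fraction_retained == 0.0
        assert res.table.iloc[0]["adjusted_count"] == 0

    def test_toy_log_six_of_ten(self):
        flags = [True] * 6 + [False] * 4
        res = availability_adjusted_counts(
            self.events_with_availability(flags), self.focal(), LABELS)
        assert res.fraction_retained == pytest.approx(0.6)
        row = res.table.iloc[0]
        # hand tally: 6 retained attacks A->B; A's other partners have 0,
        # so median over (6,0,0,0,0) is 0 and the dyad sits above it
        assert row["adjusted_count"] == 6
        assert row["median_adjusted"] == 0.0
        assert row["success"]

    def test_tie_at_median_counts_as_failure(self):
        events = (self.events_with_availability([True] * 3)
                  + [make_event("A", c, time_s=50.0 + i,
                                n_partners_available=5)
                     for i, c in enumerate(["C", "C", "C", "D", "D", "D",
                                            "E", "F"])])
        res = availability_adjusted_counts(events, self.focal(), LABELS)
        row = res.table.iloc[0]
        # adjusted counts per partner: B=3, C=3, D=3, E=1, F=1 -> median 3
        assert row["adjusted_count"] == 3 and row["median_adjusted"] == 3.0
        assert row["at_median"] and not row["success"]

    def test_avoided_success_is_below_median(self):
        events = [make_event("A", c, time_s=float(i),
                             n_partners_available=5)
                  for i, c in enumerate(
                      ["B"] + ["C"] * 5 + ["D"] * 5 + ["E"] * 4 + ["F"] * 4)]
        res = availability_adjusted_counts(
            events, self.focal("avoided"), LABELS)
        row = res.table.iloc[0]
        assert row["adjusted_count"] == 1 and row["success"]
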