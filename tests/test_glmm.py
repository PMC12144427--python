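"""Mixed logistic model: feature table, fitter correctness, invariants,
and an lme4 cross-check."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from ratplay.events import ValidationError
from ratplay.glmm import (SeparationError, build_feature_table,
                          fit_binary_glmm, simulate_glmm_rows)

from conftest import LABELS, make_event


def classified_table(n_strong=31, n_avoided=27):
    """Index table with the requested classified dyad-days, spread over
    groups/days, plus matching events so percentages are defined."""
    rows, events = [], []
    dyads = [(a, b) for a in LABELS for b in LABELS if a != b]
    g, d_idx = 1, 0
    days = (1, 3, 5, 8)
    used = 0
    for cls, n in (("strong_preferred", n_strong), ("avoided", n_avoided)):
        for _ in range(n):
            a, b = dyads[used % len(dyads)]
            day = days[d_idx % 4]
            rows.append({"group_id": g, "day": day, "initiator": a,
                         "recipient": b, "count": 3,
                         "index": 2.5 if cls == "strong_preferred" else 0.2,
                         "classification": cls, "undefined": False})
            for t in range(3):
                events.append(make_event(a, b, group_id=g, day=day,
                                         time_s=10.0 * used + t,
                                         response="pin"))
            events.append(make_event(b, a, group_id=g, day=day,
                                     time_s=10.0 * used + 5,
                                     response="evasion"))
            used += 1
            d_idx += 1
            if used % len(dyads) == 0:
                g += 1
    return pd.DataFrame(rows), events


def support_tables(index_table):
    sym, prox = [], []
    seen = set()
    for r in index_table.to_dict("records"):
        key = (r["group_id"], r["day"],
               *sorted((r["initiator"], r["recipient"])))
        if key in seen:
            continue
        seen.add(key)
        sym.append({"group_id": key[0], "day": key[1], "animal_a": key[2],
                    "animal_b": key[3], "symmetry": 0.6,
                    "undefined": False})
        prox.append({"group_id": key[0], "day": key[1], "animal_a": key[2],
                     "animal_b": key[3], "proximity_s": 290.0})
    groups = sorted(set(index_table["group_id"]))
    weights = {(g, a): 100.0 + 2 * i for g in groups
               for i, a in enumerate(LABELS)}
    ranks = {(g, a): i + 1 for g in groups for i, a in enumerate(LABELS)}
    return pd.DataFrame(sym), pd.DataFrame(prox), weights, ranks


class TestFeatureTable:
    def test_58_rows_from_31_plus_27_dyads(self):
        """The study design's classified dyads produce 58 model rows."""
        idx, events = classified_table(31, 27)
        sym, prox, weights, ranks = support_tables(idx)
        feats = build_feature_table(events, idx, sym, prox, weights, ranks)
        assert len(feats) == 58
        assert feats["outcome"].sum() == 31
        assert (1 - feats["outcome"]).sum() == 27

    def test_all_pin_partner(self):
        idx, events = classified_table(1, 0)
        sym, prox, weights, ranks = support_tables(idx)
        feats = build_feature_table(events, idx, sym, prox, weights, ranks)
        row = feats.iloc[0]
        assert row["pct_pin"] == 100.0
        assert row["pct_no_response"] == 0.0

    def test_percentages_match_hand_tally(self):
        """Explicit event mix: 4 attacks answered pin/evasion/no_response/
        pin with reversals on the pins."""
        idx = pd.DataFrame([{"group_id": 1, "day": 1, "initiator": "A",
                             "recipient": "B", "count": 4, "index": 2.4,
                             "classification": "strong_preferred",
                             "undefined": False}])
        events = [
            make_event("A", "B", time_s=1.0, response="pin",
                       role_reversal=True),
            make_event("A", "B", time_s=2.0, response="evasion"),
            make_event("A", "B", time_s=3.0, response="no_response"),
            make_event("A", "B", time_s=4.0, response="pin",
                       role_reversal=True),
            make_event("B", "A", time_s=5.0, response="box"),
            make_event("B", "A", time_s=6.0, response="box"),
        ]
        sym, prox, weights, ranks = support_tables(idx)
        feats = build_feature_table(events, idx, sym, prox, weights, ranks)
        row = feats.iloc[0]
        assert row["pct_pin"] == 50.0
        assert row["pct_evasion"] == 25.0
        assert row["pct_no_response"] == 25.0
        assert row["pct_role_reversal"] == 50.0
        assert row["partner_play_frequency"] == 2
        assert row["weight_diff"] == weights[(1, "A")] - weights[(1, "B")]
        assert row["dominance_diff"] == ranks[(1, "A")] - ranks[(1, "B")]

    def test_zero_attack_dyad_dropped(self):
        idx = pd.DataFrame([{"group_id": 1, "day": 1, "initiator": "A",
                             "recipient": "B", "count": 0, "index": 0.0,
                             "classification": "avoided",
                             "undefined": False}])
        events = [make_event("B", "A", time_s=1.0)]
        sym, prox, weights, ranks = support_tables(idx)
        feats = build_feature_table(events, idx, sym, prox, weights, ranks)
        assert len(feats) == 0


class TestFitter:
    def test_wald_transforms_are_exact(self):
        rows = simulate_glmm_rows(200, effect=0.05, seed=1)
        fit = fit_binary_glmm(rows, predictors=("pct_role_reversal",))
        t = fit.table
        assert np.allclose(t["odds_ratio"], np.exp(t["estimate"]),
                           rtol=1e-12)
        assert np.allclose(t["ci_low"], t["estimate"] - 1.96 * t["se"],
                           rtol=1e-12)
        assert np.allclose(t["ci_high"], t["estimate"] + 1.96 * t["se"],
                           rtol=1e-12)
        assert np.allclose(t["z"], t["estimate"] / t["se"], rtol=1e-12)

    def test_row_order_invariance(self):
        rows = simulate_glmm_rows(200, effect=0.06, seed=2)
        fit1 = fit_binary_glmm(rows, predictors=("pct_role_reversal",))
        shuffled = rows.sample(frac=1.0, random_state=9)
        fit2 = fit_binary_glmm(shuffled, predictors=("pct_role_reversal",))
        assert np.allclose(fit1.table["estimate"], fit2.table["estimate"],
                           atol=1e-6)

    def test_zero_variance_limit_matches_plain_logit(self):
        rows = simulate_glmm_rows(300, effect=0.04, sigma=0.0, seed=3)
        fit = fit_binary_glmm(rows, predictors=("pct_role_reversal",),
                              force_zero_variance=True)
        assert fit.used_plain_logistic
        X = sm.add_constant(rows["pct_role_reversal"].to_numpy())
        ref = sm.Logit(rows["outcome"], X).fit(disp=0)
        assert np.allclose(fit.table["estimate"], ref.params, atol=1e-6)
        assert np.allclose(fit.table["se"], ref.bse, atol=1e-6)

    def test_null_predictor_covered(self):
        rows = simulate_glmm_rows(400, effect=0.0, intercept=0.0, seed=4)
        fit = fit_binary_glmm(rows, predictors=("pct_role_reversal",))
        c = fit.coef("pct_role_reversal")
        assert abs(c["estimate"]) < 0.05
        assert c["ci_low"] <= 0 <= c["ci_high"]

    def test_single_class_rejected(self):
        rows = simulate_glmm_rows(50, seed=5)
        rows["outcome"] = 1
        with pytest.raises(ValidationError, match="both classes"):
            fit_binary_glmm(rows, predictors=("pct_role_reversal",))

    def test_complete_separation_raises(self):
        rows = pd.DataFrame({
            "outcome": [0] * 20 + [1] * 20,
            "x": list(range(20)) + list(range(30, 50)),
            "initiator_id": ["I%d" % (i % 5) for i in range(40)]})
        with pytest.raises(SeparationError):
            fit_binary_glmm(rows, predictors=("x",))

    def test_crossed_random_intercepts_fit(self):
        rng = np.random.default_rng(6)
        n = 240
        gi = rng.integers(0, 12, n)
        gj = rng.integers(0, 12, n)
        ui = rng.normal(0, 1.0, 12)
        uj = rng.normal(0, 0.8, 12)
        x = rng.normal(0, 1, n)
        eta = 0.8 * x + ui[gi] + uj[gj]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        rows = pd.DataFrame({"outcome": y, "x": x,
                             "initiator_id": [f"I{g}" for g in gi],
                             "partner_id": [f"P{g}" for g in gj]})
        fit = fit_binary_glmm(rows, predictors=("x",),
                              random=("initiator_id", "partner_id"))
        c = fit.coef("x")
        assert c["estimate"] > 0 and c["p"] < 0.05
        assert set(fit.random_variance) == {"initiator_id", "partner_id"}


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="Rscript not on PATH")
class TestAgainstLme4:
    def test_matches_glmer_laplace(self, tmp_path):
        """Estimate, SE and random variance agree with lme4's glmer
        (both use the Laplace approximation)."""
        rows = simulate_glmm_rows(200, effect=0.08, seed=42)
        csv = tmp_path / "rows.csv"
        rows.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent("""
            suppressMessages(library(lme4))
            d <- read.csv(commandArgs(trailingOnly=TRUE)[1])
            m <- glmer(outcome ~ pct_role_reversal + (1|initiator_id),
                       data=d, family=binomial)
            co <- summary(m)$coefficients
            vc <- as.data.frame(VarCorr(m))
            cat(co["pct_role_reversal","Estimate"],
                co["pct_role_reversal","Std. Error"], vc$vcov[1], "\\n")
        """))
        out = subprocess.run(["Rscript", str(script), str(csv)],
                             capture_output=True, text=True, check=True)
        est_r, se_r, var_r = map(float, out.stdout.split())
        fit = fit_binary_glmm(rows, predictors=("pct_role_reversal",))
        c = fit.coef("pct_role_reversal")
        assert c["estimate"] == pytest.approx(est_r, abs=2e-3)
        assert c["se"] == pytest.approx(se_r, abs=2e-3)
        assert fit.random_variance["initiator_id"] == pytest.approx(
            var_r, abs=0.02)
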