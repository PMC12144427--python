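"""Synthetic play-study generator.

Emulates the design of a group-play experiment: ``n_groups`` groups of ``k``
familiar juvenile male rats, each filmed for 20-minute sessions on four
scored days across the peak play period.  Every animal carries a latent
attack rate and, per day, a partner-weight vector over its ``k - 1``
cagemates; each attack draws its recipient from those weights, then draws
the recipient's defensive response and any role reversal from a tactic
profile that depends on how preferred the recipient is.  Day-to-day drift
resamples the weight vectors so that favourites change between sessions,
mirroring the instability seen in real groups.

The generator's purpose is to give every downstream stage (preference
indices, Mantel screens, networks, mixed models, availability correction)
inputs with known planted structure, so recovery can be tested without any
video scoring.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .events import (
    SESSION_S,
    Animal,
    AttackEvent,
    ProximityRecord,
    RESPONSES,
    write_animals,
    write_event_log,
    write_proximity,
)

#: Default animal labels within a group.
LABELS = tuple("ABCDEF")


@dataclass(frozen=True)
class TacticProfile:
    """Distribution of a recipient's defensive responses to nape attacks.

    ``p_no_response + p_evasion + p_pin + p_box`` must sum to 1.
    ``role_reversal_overall`` is the fraction of *all* received attacks that
    end in a successful counterattack; internally role reversals are only
    drawn on defended attacks (an ignored attack cannot be counterattacked),
    so the conditional probability used is
    ``role_reversal_overall / (1 - p_no_response)``.
    """

    p_no_response: float
    p_evasion: float
    p_pin: float
    p_box: float
    role_reversal_overall: float

    def __post_init__(self):
        probs = self.response_probs
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError(f"response probabilities sum to {sum(probs)}")
        if any(p < 0 for p in probs):
            raise ValueError("negative response probability")
        if not (0 <= self.role_reversal_overall <= 1 - self.p_no_response + 1e-12):
            raise ValueError("role_reversal_overall incompatible with "
                             "p_no_response")

    @property
    def response_probs(self) -> tuple[float, float, float, float]:
        return (self.p_no_response, self.p_evasion, self.p_pin, self.p_box)

    @property
    def role_reversal_given_defense(self) -> float:
        defended = 1.0 - self.p_no_response
        return self.role_reversal_overall / defended if defended > 0 else 0.0


#: Tactic profile of preferred partners: they defend most attacks and
#: counterattack (role-reverse) often.  Percentages follow the observed
#: means for preferred partners (no response 29.6%, evasion 31.6%,
#: pin 30.5%, role reversal 47.3% of attacks).
PREFERRED_TACTICS = TacticProfile(0.2958, 0.3161, 0.3053, 0.0828, 0.4728)

#: Tactic profile of non-preferred partners: fewer pins and almost no role
#: reversals (no response 14.8%, evasion 29.6%, pin 11.1%, role reversal
#: 2.4% of attacks); the remainder of defences is upright boxing.
NONPREFERRED_TACTICS = TacticProfile(0.1481, 0.2963, 0.1111, 0.4445, 0.0238)


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study.  Defaults emulate the real design:
    8 groups x 6 males x scored days 1, 3, 5, 8 of 20-min sessions.

    ``concentration`` is the symmetric Dirichlet parameter for each animal's
    partner weights: large values give near-uniform (no-preference) play,
    small values strong idiosyncratic preferences.  ``planted_dyads`` forces
    listed directed dyads (applied in every group) to ``planted_weight``,
    guaranteeing recoverable strong preferences.  ``drift`` scales
    day-to-day resampling of the weights (0 = frozen preferences; larger =
    more daily partner turnover).
    """

    n_groups: int = 8
    k: int = 6
    days: tuple[int, ...] = (1, 3, 5, 8)
    session_s: float = SESSION_S
    attack_rate_range: tuple[float, float] = (20.0, 60.0)
    concentration: float = 3.0
    planted_dyads: tuple[tuple[str, str], ...] = ()
    planted_weight: float = 0.6
    preferred_tactics: TacticProfile = PREFERRED_TACTICS
    nonpreferred_tactics: TacticProfile = NONPREFERRED_TACTICS
    #: partner weight at/below which a recipient gets the non-preferred
    #: tactic profile, and at/above ``tactic_weight_hi`` the preferred one
    #: (linear blend in between).
    tactic_weight_lo: float = 0.05
    tactic_weight_hi: float = 0.40
    drift: float = 0.15
    all_available_fraction: float = 0.6
    #: distribution of n_partners_available (0..k-2) when not all partners
    #: are free; default leaves >= 2 partners free in 98.8% of all attacks.
    partial_availability_probs: tuple[float, ...] = (0.01, 0.02, 0.22, 0.30, 0.45)
    proximity_mean_s: float = 287.0
    proximity_sd_s: float = 60.0
    weight_mean_g: float = 105.0
    weight_sd_g: float = 10.0
    tie_prob: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_groups < 1 or self.k < 2:
            raise ValueError("need at least one group of two animals")
        lo, hi = self.attack_rate_range
        if lo <= 0 or hi < lo:
            raise ValueError(f"bad attack_rate_range {self.attack_rate_range}")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if not 0 < self.planted_weight < 1:
            raise ValueError("planted_weight must be in (0, 1)")
        if not 0 <= self.all_available_fraction <= 1:
            raise ValueError("all_available_fraction must be in [0, 1]")
        if len(self.partial_availability_probs) != self.k - 1:
            raise ValueError(
                f"partial_availability_probs needs {self.k - 1} entries "
                f"(n = 0..{self.k - 2})")
        if abs(sum(self.partial_availability_probs) - 1.0) > 1e-9:
            raise ValueError("partial_availability_probs must sum to 1")
        if self.drift < 0:
            raise ValueError("drift must be non-negative")

    @property
    def labels(self) -> tuple[str, ...]:
        return LABELS[:self.k] if self.k <= len(LABELS) else tuple(
            f"R{i + 1}" for i in range(self.k))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("preferred_tactics", "nonpreferred_tactics"):
            if key in d and isinstance(d[key], dict):
                d[key] = TacticProfile(**d[key])
        for key in ("days", "attack_rate_range", "partial_availability_probs"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        if "planted_dyads" in d:
            d["planted_dyads"] = tuple(tuple(x) for x in d["planted_dyads"])
        return cls(**d)


@dataclass
class SimulatedStudy:
    """Generator output plus the planted ground truth."""

    config: SimulationConfig
    events: list[AttackEvent]
    animals: list[Animal]
    proximity: list[ProximityRecord]
    tube_trials: pd.DataFrame
    #: true partner weights: (group_id, day, initiator) -> {partner: weight}
    weights: dict[tuple[int, int, str], dict[str, float]]


def _blend(a: TacticProfile, b: TacticProfile, t: float) -> TacticProfile:
    """Convex combination of two tactic profiles (t = 0 -> a, t = 1 -> b)."""
    return TacticProfile(
        *(x * (1 - t) + y * t
          for x, y in zip(a.response_probs, b.response_probs)),
        a.role_reversal_overall * (1 - t) + b.role_reversal_overall * t)


def _tactics_for_weight(config: SimulationConfig, w: float) -> TacticProfile:
    lo, hi = config.tactic_weight_lo, config.tactic_weight_hi
    t = float(np.clip((w - lo) / (hi - lo), 0.0, 1.0))
    return _blend(config.nonpreferred_tactics, config.preferred_tactics, t)


def _initial_weights(config: SimulationConfig, rng: np.random.Generator,
                     labels: Sequence[str]) -> dict[str, np.ndarray]:
    """Day-1 partner weight vector per initiator (over labels minus self)."""
    k = config.k
    weights: dict[str, np.ndarray] = {}
    for a in labels:
        w = rng.dirichlet(np.full(k - 1, config.concentration))
        weights[a] = w
    return weights


def _apply_planted(config: SimulationConfig, labels: Sequence[str],
                   weights: dict[str, np.ndarray]) -> None:
    """Force planted directed dyads to ``planted_weight`` (in place)."""
    for init, recip in config.planted_dyads:
        if init not in labels or recip not in labels:
            raise ValueError(f"planted dyad ({init}, {recip}) not in labels")
        partners = [x for x in labels if x != init]
        w = weights[init]
        j = partners.index(recip)
        others = np.delete(w, j)
        total = others.sum()
        if total <= 0:
            others = np.full(len(partners) - 1, 1.0)
            total = others.sum()
        scaled = others * (1.0 - config.planted_weight) / total
        w_new = np.insert(scaled, j, config.planted_weight)
        weights[init] = w_new


def _drift_weights(config: SimulationConfig, rng: np.random.Generator,
                   base: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Day-specific perturbation of each animal's baseline weight vector.

    Weights for the day are ``normalize(base * exp(drift * eps))`` with
    fresh standard-normal ``eps`` per partner, i.e. a logistic-normal jitter
    around the animal's stable preference profile.  Because each day
    perturbs the *baseline* (not the previous day), variability does not
    accumulate over the study; ``drift`` directly sets how often the
    favourite partner changes between days.
    """
    if config.drift == 0:
        return {a: w.copy() for a, w in base.items()}
    out = {}
    for a, w in base.items():
        jitter = np.clip(w, 1e-9, None) * np.exp(
            config.drift * rng.standard_normal(len(w)))
        out[a] = jitter / jitter.sum()
    return out


def _draw_availability(config: SimulationConfig,
                       rng: np.random.Generator) -> int:
    if rng.random() < config.all_available_fraction:
        return config.k - 1
    return int(rng.choice(config.k - 1,
                          p=np.asarray(config.partial_availability_probs)))


def simulate_study(config: SimulationConfig | None = None,
                   seed: int | None = None) -> SimulatedStudy:
    """Generate a complete synthetic study (events, animals, proximity,
    tube-test trials) from planted partner-choice structure.

    Identical ``(config, seed)`` give byte-identical outputs.  ``seed``
    overrides ``config.seed`` when given.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    labels = config.labels
    k = config.k

    events: list[AttackEvent] = []
    animals: list[Animal] = []
    proximity: list[ProximityRecord] = []
    weights_truth: dict[tuple[int, int, str], dict[str, float]] = {}
    tube_rows: list[dict] = []

    for g in range(1, config.n_groups + 1):
        rates = rng.uniform(*config.attack_rate_range, size=k)
        base_weights = _initial_weights(config, rng, labels)
        _apply_planted(config, labels, base_weights)

        # animals and tube test (dominance assayed once, mid-study)
        body = rng.normal(config.weight_mean_g, config.weight_sd_g, size=k)
        body = np.clip(body, 60.0, None)
        strengths = rng.normal(0.0, 1.0, size=k)
        group_animals = [
            Animal(animal_id=a, group_id=g, weight_g=round(float(bw), 1))
            for a, bw in zip(labels, body)]
        trials = simulate_tube_test(group_animals, strengths, rng=rng,
                                    tie_prob=config.tie_prob)
        tube_rows.extend(trials.to_dict("records"))
        wins = {a: 0 for a in labels}
        for t in trials.itertuples():
            if t.outcome == "win_a":
                wins[t.animal_a] += 1
            elif t.outcome == "win_b":
                wins[t.animal_b] += 1
        animals.extend(
            dataclasses.replace(an, tube_wins=wins[an.animal_id])
            for an in group_animals)

        for day in config.days:
            group_weights = _drift_weights(config, rng, base_weights)
            _apply_planted(config, labels, group_weights)
            day_events: list[AttackEvent] = []
            for i, a in enumerate(labels):
                partners = [x for x in labels if x != a]
                w = group_weights[a]
                weights_truth[(g, day, a)] = dict(zip(partners, w.tolist()))
                n_attacks = int(rng.poisson(rates[i]))
                if n_attacks == 0:
                    continue
                times = np.sort(rng.uniform(0.0, config.session_s,
                                            size=n_attacks))
                recipients = rng.choice(len(partners), size=n_attacks, p=w)
                for t, rj in zip(times, recipients):
                    profile = _tactics_for_weight(config, w[rj])
                    resp = RESPONSES[int(rng.choice(
                        4, p=np.asarray(profile.response_probs)))]
                    rr = (resp != "no_response" and
                          rng.random() < profile.role_reversal_given_defense)
                    n_avail = _draw_availability(config, rng)
                    day_events.append(AttackEvent(
                        group_id=g, day=day, time_s=round(float(t), 1),
                        initiator=a, recipient=partners[rj], response=resp,
                        role_reversal=bool(rr),
                        n_partners_available=n_avail,
                        all_available=n_avail == k - 1))
            day_events.sort(key=lambda e: (e.time_s, e.initiator, e.recipient))
            events.extend(day_events)

            # proximity per unordered dyad (play time already excluded)
            for i in range(k):
                for j in range(i + 1, k):
                    p = float(np.clip(
                        rng.normal(config.proximity_mean_s,
                                   config.proximity_sd_s),
                        0.0, config.session_s))
                    proximity.append(ProximityRecord(
                        group_id=g, day=day, animal_a=labels[i],
                        animal_b=labels[j], proximity_s=round(p, 1)))

    tube = pd.DataFrame(
        tube_rows, columns=["group_id", "animal_a", "animal_b", "trial",
                            "outcome"])
    return SimulatedStudy(config=config, events=events, animals=animals,
                          proximity=proximity, tube_trials=tube,
                          weights=weights_truth)


def simulate_tube_test(animals: Sequence[Animal],
                       latent_strengths: Sequence[float],
                       seed: int | None = None,
                       rng: np.random.Generator | None = None,
                       tie_prob: float = 0.05,
                       n_trials: int = 5) -> pd.DataFrame:
    """Simulate the tube-test dominance assay for one group.

    Every unordered pair meets ``n_trials`` times; each trial is a tie with
    probability ``tie_prob``, otherwise animal a wins with probability
    ``expit(strength_a - strength_b)``.  Returns one row per trial with
    outcome in {win_a, win_b, tie}.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    strengths = dict(zip((a.animal_id for a in animals),
                         map(float, latent_strengths)))
    if len(strengths) != len(animals):
        raise ValueError("duplicate animal ids")
    rows = []
    group_id = animals[0].group_id if animals else 0
    ids = [a.animal_id for a in animals]
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = ids[i], ids[j]
            p_a = 1.0 / (1.0 + np.exp(-(strengths[a] - strengths[b])))
            for trial in range(1, n_trials + 1):
                u = rng.random()
                if rng.random() < tie_prob:
                    outcome = "tie"
                else:
                    outcome = "win_a" if u < p_a else "win_b"
                rows.append({"group_id": group_id, "animal_a": a,
                             "animal_b": b, "trial": trial,
                             "outcome": outcome})
    return pd.DataFrame(rows, columns=["group_id", "animal_a", "animal_b",
                                       "trial", "outcome"])


def write_study(study: SimulatedStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write events.csv, animals.csv, proximity.csv, tube_trials.csv and a
    provenance JSON (config + seed) into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "events": out / "events.csv",
        "animals": out / "animals.csv",
        "proximity": out / "proximity.csv",
        "tube_trials": out / "tube_trials.csv",
        "provenance": out / "provenance.json",
    }
    write_event_log(study.events, paths["events"])
    write_animals(study.animals, paths["animals"])
    write_proximity(study.proximity, paths["proximity"])
    study.tube_trials.to_csv(paths["tube_trials"], index=False)
    paths["provenance"].write_text(json.dumps(
        {"config": study.config.to_dict(), "n_events": len(study.events)},
        indent=2, default=list))
    return paths
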