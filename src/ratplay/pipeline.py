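"""End-to-end study pipeline.

Replays the full analysis in order: event ingestion (or simulation) ->
count/proportion matrices -> Mantel randomness screen -> preference indices
on the surviving group-days -> play networks and modularity -> symmetry,
popularity, z-scores, rank-change stability and dominance -> repeated
measures ANOVAs -> the two mixed logistic models -> the partner-availability
correction with exact sign tests.  Every stage writes a long-format CSV into
the output directory and the run closes with a JSON report carrying the
seed, a config hash and the exclusion/row bookkeeping.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .anova import (anova_results_frame, daily_popularity_anova,
                    group_totals_anova, popularity_anova)
from .events import (CountMatrix, build_count_matrix, events_to_frame,
                     matrices_to_frame, read_animals, read_event_log,
                     read_proximity, to_proportions, ValidationError)
from .glmm import (MODEL1_PREDICTORS, MODEL2_PREDICTORS, SeparationError,
                   build_feature_table, fit_binary_glmm)
from .networks import (build_directed_network, build_undirected_network,
                       eigenvector_centrality, network_edgelist,
                       plot_network, preference_network, write_graphml)
from .permutation import (DegenerateMatrixError, mantel_screen,
                          modularity_significance, sign_test_exact)
from .preference import (availability_adjusted_counts, daily_zscores,
                         popularity, rank_change, symmetry_table,
                         thompson_index, tube_rank)
from .simulate import SimulationConfig, simulate_study, write_study

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline configuration.

    Either ``input_dir`` points at events.csv / animals.csv / proximity.csv /
    tube_trials.csv, or ``simulate`` provides a :class:`SimulationConfig`
    block to generate them.  Thresholds must be ordered
    avoided < chance(1) < strong.
    """

    out_dir: str = "ratplay_out"
    input_dir: str | None = None
    simulate: SimulationConfig = field(default_factory=SimulationConfig)
    seed: int = 0
    alpha: float = 0.05
    n_perm: int = 9999
    n_perm_modularity: int = 999
    strong_threshold: float = 2.0
    avoided_threshold: float = 0.25
    z_cutoff: float = 1.96
    plots: bool = False

    def __post_init__(self):
        if not (self.avoided_threshold < 1.0 < self.strong_threshold):
            raise ValidationError(
                "thresholds must satisfy avoided < 1 (chance) < strong")
        if self.n_perm < 1 or not 0 < self.alpha < 1:
            raise ValidationError("bad n_perm or alpha")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "simulate" in raw and isinstance(raw["simulate"], dict):
            raw["simulate"] = SimulationConfig.from_dict(raw["simulate"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (the output
        directory does not affect results and is not hashed)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        canon = json.dumps(d, sort_keys=True, default=list)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


class Pipeline:
    """Lazy, stage-by-stage pipeline over one study's data.

    Stages are cached properties; calling a ``write_*`` method materialises
    the stage and its dependencies and writes the stage's CSV outputs.
    """

    def __init__(self, config: RunConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self._cache: dict[str, object] = {}
        self.report: dict = {
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "stages": {},
        }

    # -- data -----------------------------------------------------------
    @property
    def data(self):
        if "data" not in self._cache:
            cfg = self.config
            if cfg.input_dir:
                base = Path(cfg.input_dir)
                animals = read_animals(base / "animals.csv")
                ids = {a.animal_id for a in animals}
                events = read_event_log(base / "events.csv",
                                        known_animals=ids)
                proximity = read_proximity(base / "proximity.csv")
                tube = pd.read_csv(base / "tube_trials.csv")
                self._cache["data"] = (events, animals, proximity, tube)
                source = str(base)
            else:
                study = simulate_study(cfg.simulate, seed=cfg.seed)
                write_study(study, self.out / "simulated")
                self._cache["data"] = (study.events, study.animals,
                                       study.proximity, study.tube_trials)
                source = "simulated"
            events = self._cache["data"][0]
            self.report["stages"]["data"] = {
                "source": source, "n_events": len(events),
                "n_animals": len(self._cache["data"][1])}
            logger.info("data: %d events from %s", len(events), source)
        return self._cache["data"]

    @property
    def events(self):
        return self.data[0]

    @property
    def animals(self):
        return self.data[1]

    @property
    def group_days(self) -> list[tuple[int, int]]:
        return sorted({(e.group_id, e.day) for e in self.events})

    @property
    def labels_by_group(self) -> dict[int, tuple[str, ...]]:
        out: dict[int, list[str]] = {}
        for a in self.animals:
            out.setdefault(a.group_id, []).append(a.animal_id)
        return {g: tuple(sorted(v)) for g, v in out.items()}

    # -- matrices --------------------------------------------------------
    @property
    def matrices(self) -> dict[tuple[int, int], CountMatrix]:
        if "matrices" not in self._cache:
            by_gd: dict[tuple[int, int], list] = {}
            for e in self.events:
                by_gd.setdefault((e.group_id, e.day), []).append(e)
            labels = self.labels_by_group
            self._cache["matrices"] = {
                (g, d): build_count_matrix(evs, g, d, labels[g])
                for (g, d), evs in sorted(by_gd.items())}
        return self._cache["matrices"]

    def write_matrices(self):
        df = matrices_to_frame(list(self.matrices.values()))
        df.to_csv(self.out / "matrices.csv", index=False)
        self.report["stages"]["matrices"] = {"n_group_days":
                                             len(self.matrices)}

    # -- mantel screen ---------------------------------------------------
    @property
    def mantel(self) -> pd.DataFrame:
        if "mantel" not in self._cache:
            cfg = self.config
            rows = []
            for (g, d), cm in self.matrices.items():
                seed = _stage_seed(cfg.seed, "mantel", g, d)
                try:
                    res = mantel_screen(cm, n_perm=cfg.n_perm, seed=seed,
                                        alpha=cfg.alpha)
                    rows.append({"group_id": g, "day": d, "r": res.r,
                                 "p": res.p, "n_perm": res.n_perm,
                                 "seed": seed, "excluded": res.excluded,
                                 "degenerate": False})
                except DegenerateMatrixError:
                    rows.append({"group_id": g, "day": d, "r": float("nan"),
                                 "p": float("nan"), "n_perm": cfg.n_perm,
                                 "seed": seed, "excluded": False,
                                 "degenerate": True})
            df = pd.DataFrame(rows)
            self._cache["mantel"] = df
            self.report["stages"]["mantel"] = {
                "n_excluded": int(df["excluded"].sum()),
                "excluded_days": df.loc[df["excluded"],
                                        ["group_id", "day"]
                                        ].to_dict("records")}
            logger.info("mantel: %d of %d group-days excluded",
                        int(df["excluded"].sum()), len(df))
        return self._cache["mantel"]

    def write_mantel(self):
        self.mantel.to_csv(self.out / "mantel_results.csv", index=False)

    @property
    def included_days(self) -> set[tuple[int, int]]:
        m = self.mantel
        return {(int(r["group_id"]), int(r["day"]))
                for _, r in m.iterrows() if not r["excluded"]}

    # -- preference indices ----------------------------------------------
    @property
    def indices(self) -> pd.DataFrame:
        if "indices" not in self._cache:
            cfg = self.config
            frames = [thompson_index(cm, strong=cfg.strong_threshold,
                                     avoided=cfg.avoided_threshold)
                      for (g, d), cm in self.matrices.items()
                      if (g, d) in self.included_days]
            df = (pd.concat(frames, ignore_index=True) if frames
                  else pd.DataFrame())
            self._cache["indices"] = df
            counts = (df["classification"].value_counts().to_dict()
                      if len(df) else {})
            above_chance = int((df["index"] > 1).sum()) if len(df) else 0
            self.report["stages"]["preferences"] = {
                "n_dyad_days": len(df), "above_chance": above_chance,
                "strong_preferred": counts.get("strong_preferred", 0),
                "avoided": counts.get("avoided", 0)}
        return self._cache["indices"]

    def write_preferences(self):
        self.indices.to_csv(self.out / "preference_indices.csv", index=False)

    # -- networks ----------------------------------------------------------
    def write_networks(self):
        gm_dir = self.out / "networks"
        gm_dir.mkdir(exist_ok=True)
        edge_frames, cent_rows = [], []
        for (g, d), cm in self.matrices.items():
            directed = build_directed_network(cm)
            undirected = build_undirected_network(cm)
            write_graphml(directed, gm_dir / f"directed_g{g}_d{d}.graphml")
            write_graphml(undirected,
                          gm_dir / f"undirected_g{g}_d{d}.graphml")
            el = network_edgelist(directed)
            el.insert(0, "day", d)
            el.insert(0, "group_id", g)
            el.insert(2, "network", "directed")
            edge_frames.append(el)
            scores, disconnected = eigenvector_centrality(undirected)
            for a, s in scores.items():
                cent_rows.append({"group_id": g, "day": d, "animal_id": a,
                                  "eigenvector_centrality": s,
                                  "disconnected": disconnected})
            if self.config.plots:
                plot_network(directed, gm_dir / f"directed_g{g}_d{d}.png",
                             title=f"group {g} day {d}")
        if len(self.indices):
            for (g, d), sub in self.indices.groupby(["group_id", "day"]):
                pref = preference_network(
                    sub, self.labels_by_group[int(g)])
                write_graphml(pref, gm_dir / f"preference_g{g}_d{d}.graphml")
                if self.config.plots:
                    plot_network(pref, gm_dir / f"preference_g{g}_d{d}.png",
                                 title=f"preferences group {g} day {d}")
        pd.concat(edge_frames, ignore_index=True).to_csv(
            self.out / "network_edges.csv", index=False)
        pd.DataFrame(cent_rows).to_csv(self.out / "centrality.csv",
                                       index=False)
        self.report["stages"]["networks"] = {"n_graphml":
                                             len(list(gm_dir.glob("*.graphml")))}

    # -- modularity --------------------------------------------------------
    @property
    def modularity(self) -> pd.DataFrame:
        if "modularity" not in self._cache:
            cfg = self.config
            rows = []
            for (g, d), cm in self.matrices.items():
                und = build_undirected_network(cm)
                seed = _stage_seed(cfg.seed, "modularity", g, d)
                res = modularity_significance(
                    und, n_perm=cfg.n_perm_modularity, seed=seed,
                    group_id=g, day=d)
                rows.append({
                    "group_id": g, "day": d, "q": res.q, "p": res.p,
                    "n_perm": res.n_perm, "seed": seed,
                    "significant": res.significant,
                    "n_communities": len(res.communities),
                    "communities": "|".join(
                        ",".join(sorted(c)) for c in res.communities)})
            self._cache["modularity"] = pd.DataFrame(rows)
        return self._cache["modularity"]

    def write_modularity(self):
        self.modularity.to_csv(self.out / "modularity_results.csv",
                               index=False)
        self.report["stages"]["modularity"] = {
            "n_significant": int(self.modularity["significant"].sum())}

    # -- descriptive metrics ----------------------------------------------
    @property
    def symmetry(self) -> pd.DataFrame:
        if "symmetry" not in self._cache:
            self._cache["symmetry"] = pd.concat(
                [symmetry_table(cm) for cm in self.matrices.values()],
                ignore_index=True)
        return self._cache["symmetry"]

    @property
    def popularity(self) -> pd.DataFrame:
        if "popularity" not in self._cache:
            self._cache["popularity"] = pd.concat(
                [popularity(to_proportions(cm))
                 for cm in self.matrices.values()], ignore_index=True)
        return self._cache["popularity"]

    @property
    def zscores(self) -> pd.DataFrame:
        if "zscores" not in self._cache:
            self._cache["zscores"] = pd.concat(
                [daily_zscores(cm, z_cutoff=self.config.z_cutoff)
                 for cm in self.matrices.values()], ignore_index=True)
        return self._cache["zscores"]

    @property
    def rank_changes(self) -> pd.DataFrame:
        if "rank_changes" not in self._cache:
            frames = []
            days = sorted({d for _, d in self.matrices})
            pairs = tuple(zip(days[:-1], days[1:]))
            for g in sorted(self.labels_by_group):
                day_props = {d: to_proportions(self.matrices[(g, d)])
                             for gg, d in self.matrices if gg == g}
                frames.append(rank_change(day_props, day_pairs=pairs))
            self._cache["rank_changes"] = pd.concat(frames,
                                                    ignore_index=True)
        return self._cache["rank_changes"]

    @property
    def dominance(self) -> pd.DataFrame:
        if "dominance" not in self._cache:
            tube = self.data[3]
            frames = [tube_rank(sub)
                      for _, sub in tube.groupby("group_id")]
            self._cache["dominance"] = pd.concat(frames, ignore_index=True)
        return self._cache["dominance"]

    def write_stability(self):
        self.rank_changes.to_csv(self.out / "rank_changes.csv", index=False)
        self.symmetry.to_csv(self.out / "symmetry.csv", index=False)
        self.zscores.to_csv(self.out / "zscores.csv", index=False)
        self.dominance.to_csv(self.out / "dominance.csv", index=False)
        self.report["stages"]["stability"] = {
            "median_favorite_change":
                float(self.rank_changes["favorite_change"].median()),
            "median_least_favorite_change":
                float(self.rank_changes["least_favorite_change"].median())}

    # -- ANOVAs -------------------------------------------------------------
    @property
    def anovas(self):
        if "anovas" not in self._cache:
            results = {}
            for g in sorted(self.labels_by_group):
                res = popularity_anova(self.popularity, g)
                results[f"popularity_group_{g}"] = res
                if res.p < self.config.alpha:
                    for target in self.labels_by_group[g]:
                        results[f"daily_popularity_group_{g}_{target}"] = \
                            daily_popularity_anova(self.popularity, g, target)
            if len(self.labels_by_group) >= 2:
                totals = pd.DataFrame(
                    [{"group_id": g, "day": d, "total_attacks": cm.total}
                     for (g, d), cm in self.matrices.items()])
                results["group_totals"] = group_totals_anova(totals)
            else:
                logger.info("single group: between-group totals ANOVA "
                            "not applicable")
            self._cache["anovas"] = results
        return self._cache["anovas"]

    def write_popularity(self):
        self.popularity.to_csv(self.out / "popularity.csv", index=False)
        df = anova_results_frame(self.anovas)
        df.to_csv(self.out / "anova_results.csv", index=False)
        stage: dict = {"n_tests": len(self.anovas)}
        if "group_totals" in self.anovas:
            gt = self.anovas["group_totals"]
            stage["group_totals"] = {"df": [gt.df_factor, gt.df_error],
                                     "F": gt.F, "p": gt.p}
        self.report["stages"]["anova"] = stage

    # -- GLMMs ---------------------------------------------------------------
    @property
    def features(self) -> pd.DataFrame:
        if "features" not in self._cache:
            prox = pd.DataFrame([{
                "group_id": r.group_id, "day": r.day, "animal_a": r.animal_a,
                "animal_b": r.animal_b, "proximity_s": r.proximity_s}
                for r in self.data[2]])
            weights = {(a.group_id, a.animal_id): a.weight_g
                       for a in self.animals}
            ranks = {(r["group_id"], r["animal_id"]): int(r["rank"])
                     for r in self.dominance.to_dict("records")}
            self._cache["features"] = build_feature_table(
                self.events, self.indices, self.symmetry, prox,
                weights, ranks)
        return self._cache["features"]

    def write_glmm(self):
        feats = self.features
        feats.to_csv(self.out / "features.csv", index=False)
        stage: dict = {"n_rows": len(feats)}
        if len(feats):
            stage["n_preferred"] = int(feats["outcome"].sum())
            stage["n_not_preferred"] = int((1 - feats["outcome"]).sum())
        for name, predictors, random in (
                ("model1", MODEL1_PREDICTORS, ("initiator_id",)),
                ("model2", MODEL2_PREDICTORS,
                 ("initiator_id", "partner_id"))):
            try:
                fit = fit_binary_glmm(feats, predictors=predictors,
                                      random=random)
                fit.table.to_csv(self.out / f"glmm_{name}.csv", index=False)
                stage[name] = {
                    "converged": fit.converged,
                    "plain_logistic_fallback": fit.used_plain_logistic,
                    "random_variance": fit.random_variance,
                    "coefficients": {
                        r["term"]: round(float(r["estimate"]), 4)
                        for r in fit.table.to_dict("records")}}
            except (ValidationError, SeparationError) as exc:
                logger.warning("glmm %s skipped: %s", name, exc)
                stage[name] = {"skipped": str(exc)}
        self.report["stages"]["glmm"] = stage

    # -- availability ---------------------------------------------------------
    @property
    def availability(self):
        if "availability" not in self._cache:
            focal = self.indices[self.indices["classification"].isin(
                ["strong_preferred", "avoided"])]
            labels = next(iter(self.labels_by_group.values()))
            self._cache["availability"] = availability_adjusted_counts(
                self.events, focal, labels)
        return self._cache["availability"]

    def write_availability(self):
        av = self.availability
        av.table.to_csv(self.out / "availability.csv", index=False)
        sign_rows = []
        stage = {"fraction_retained": av.fraction_retained}
        for cls in ("strong_preferred", "avoided"):
            sub = av.table[av.table["classification"] == cls]
            if len(sub) == 0:
                continue
            res = sign_test_exact(int(sub["success"].sum()), len(sub))
            sign_rows.append({
                "test": f"availability_{cls}",
                "n_success": res.n_success, "n_trials": res.n_trials,
                "p_two_sided": res.p_two_sided})
            stage[cls] = {"n_success": res.n_success,
                          "n_trials": res.n_trials, "p": res.p_two_sided}
        pd.DataFrame(sign_rows).to_csv(self.out / "sign_tests.csv",
                                       index=False)
        self.report["stages"]["availability"] = stage

    # -- report -----------------------------------------------------------
    def write_report(self):
        path = self.out / "report.json"
        path.write_text(json.dumps(self.report, indent=2, sort_keys=True,
                                   default=str))
        return path

    def run_all(self) -> dict:
        events_df = events_to_frame(self.events)
        events_df.to_csv(self.out / "events_scored.csv", index=False)
        self.write_matrices()
        self.write_mantel()
        self.write_preferences()
        self.write_networks()
        self.write_modularity()
        self.write_stability()
        self.write_popularity()
        self.write_glmm()
        self.write_availability()
        self.write_report()
        return self.report


def _stage_seed(seed: int, stage: str, *parts) -> int:
    """Deterministic per-stage sub-seed derived from the master seed."""
    digest = hashlib.sha256(
        f"{seed}:{stage}:{parts}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31 - 1)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in study order and return the report dict."""
    return Pipeline(config).run_all()
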