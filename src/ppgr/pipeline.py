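"""End-to-end orchestration: simulate/ingest -> qualify -> features ->
decompose -> model -> report, from one config with one seed.

Every stage records row counts in a manifest so each output table is
reconcilable with the filter ledger (reported meals, meals with CGM
coverage, qualified meals, meals with complete features, analysed meals).
Given the same config and seed, every artefact is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .activity import EpochSeries, meal_activity, sleep_before
from .centering import person_center, variance_contribution_table
from .cgm import CoverageError, GlucoseTrace, iauc_2h, preprandial_mean
from .cohort import CohortBundle, SimConfig, generate_cohort
from .exposures import ACTIVITY_EXPOSURES, EXPOSURES, FOOD_GROUPS
from .meals import CoverageRule, build_meal_records, filter_participants, qualify_meals
from .models import association_table, interaction_test, stratified_fit

__all__ = ["RunConfig", "run_pipeline", "compute_meal_features", "build_events"]


@dataclass
class RunConfig:
    """Single entry point for a pipeline run; YAML-serialisable."""

    out_dir: str = "ppgr_run"
    seed: int = 0
    # either simulate ...
    simulate: dict | None = field(default_factory=dict)
    # ... or read the four streams + participant table from CSV
    inputs: dict | None = None
    # filters and feature options (every configurable threshold lives here)
    min_meals: int = 3
    prior_gap_h: float = 2.5
    coverage_fraction: float = 0.8
    iauc_mode: str = "positive_only"
    iauc_baseline: str = "interpolated"
    max_gap_min: float = 45.0
    # modelling options
    run_models: bool = True
    bootstrap_B: int = 0
    run_basic: bool = True
    strata: list = field(default_factory=list)       # subset of {"sex","prediabetes"}
    interactions: list = field(default_factory=list)
    run_icc: bool = True
    write_epochs: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)

    def validate(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("config needs exactly one of 'simulate' or 'inputs'")
        if self.iauc_mode not in ("positive_only", "net"):
            raise ValueError(f"unknown iauc_mode {self.iauc_mode!r}")
        if self.min_meals < 1 or not 0 < self.coverage_fraction <= 1:
            raise ValueError("bad filter thresholds")
        for s in list(self.strata) + list(self.interactions):
            if s not in ("sex", "prediabetes"):
                raise ValueError(f"unknown stratifier/modifier {s!r}")
        if self.inputs is not None:
            for key in ("ema", "cgm", "epochs", "sleep", "participants"):
                p = self.inputs.get(key)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"input stream {key!r} missing: {p}")


def _load_inputs(cfg: RunConfig):
    paths = cfg.inputs
    ema = pd.read_csv(paths["ema"], parse_dates=["response_timestamp"])
    cgm = pd.read_csv(paths["cgm"], parse_dates=["timestamp"])
    epochs_df = pd.read_csv(paths["epochs"], parse_dates=["timestamp"])
    sleep = pd.read_csv(paths["sleep"], parse_dates=["onset", "wake"])
    participants = pd.read_csv(paths["participants"])
    traces = {pid: GlucoseTrace.from_frame(g)
              for pid, g in cgm.groupby("participant_id")}
    epochs = {pid: EpochSeries.from_frame(g)
              for pid, g in epochs_df.groupby("participant_id")}
    return ema, traces, epochs, sleep, participants


def compute_meal_features(meals: pd.DataFrame, traces: dict, epochs: dict,
                          sleep: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    """Glucose, activity and sleep features for each (qualified) meal."""
    sleep_by_pid = {pid: g for pid, g in sleep.groupby("participant_id")}
    rows = []
    for rec in meals.itertuples(index=False):
        t = rec.meal_timestamp
        feat = {"meal_id": rec.meal_id}
        trace = traces.get(rec.participant_id)
        try:
            feat["iauc_2h"] = iauc_2h(trace, t, mode=cfg.iauc_mode,
                                      max_gap_min=cfg.max_gap_min,
                                      baseline=cfg.iauc_baseline)
            feat["preprandial_mean_2h"] = preprandial_mean(trace, t)
        except (CoverageError, AttributeError):
            feat["iauc_2h"] = np.nan
            feat["preprandial_mean_2h"] = np.nan
        series = epochs.get(rec.participant_id)
        if series is not None:
            feat.update(meal_activity(series, t))
        else:
            feat.update({k: np.nan for k in ACTIVITY_EXPOSURES if k != "sleep_h"})
        sw = sleep_by_pid.get(rec.participant_id)
        feat["sleep_h"] = sleep_before(sw, t) if sw is not None else np.nan
        rows.append(feat)
    return pd.DataFrame(rows)


def build_events(meals: pd.DataFrame, features: pd.DataFrame,
                 participants: pd.DataFrame) -> pd.DataFrame:
    """Meal-level analysis table: meal record + features + covariates."""
    ev = meals.merge(features, on="meal_id", how="left")
    cov = participants[["participant_id", "age", "sex", "ethnicity", "education",
                        "smoker", "heavy_alcohol", "bmi", "prediabetes"]]
    return ev.merge(cov, on="participant_id", how="left")


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; write tables, a manifest and a log; return the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"ppgr_version": __version__, "seed": config.seed,
                      "stages": {}}
    log: list[str] = []

    # -- stage 1: data ------------------------------------------------------
    if config.simulate is not None:
        sim = SimConfig(**{**config.simulate, "seed": config.seed})
        bundle: CohortBundle = generate_cohort(sim)
        bundle.write(out / "data", include_epochs=config.write_epochs)
        ema, traces, epochs, sleep = (bundle.ema, bundle.traces, bundle.epochs,
                                      bundle.sleep)
        participants = bundle.participants
        log.append(f"simulated cohort: {len(participants)} participants, "
                   f"{sim.n_days} days, seed {config.seed}")
    else:
        ema, traces, epochs, sleep, participants = _load_inputs(config)
        log.append(f"loaded input streams for {len(participants)} participants")
    manifest["stages"]["participants"] = len(participants)
    manifest["stages"]["ema_responses"] = len(ema)

    # -- stage 2: meal records and qualification ---------------------------
    meals, parse_errors = build_meal_records(ema)
    coverage = CoverageRule(post_fraction=config.coverage_fraction,
                            baseline_gap_min=config.max_gap_min)
    qual = qualify_meals(meals, traces, prior_gap_h=config.prior_gap_h,
                         coverage=coverage)
    retained = filter_participants(qual, min_meals=config.min_meals)
    n_cov = int((~qual["failure_reasons"].str.contains("no_cgm_coverage")).sum())
    manifest["stages"].update({
        "reported_meals": len(meals),
        "parse_errors": len(parse_errors),
        "meals_with_cgm_coverage": n_cov,
        "qualified_meals": int(qual["qualified"].sum()),
        "retained_participants": len(retained),
    })
    log.append(f"{len(meals)} reported meals -> {n_cov} with CGM coverage -> "
               f"{int(qual['qualified'].sum())} qualified; "
               f"{len(retained)} participants with >= {config.min_meals} meals")
    meals.to_csv(out / "meal_records.csv", index=False)
    qual.to_csv(out / "qualification_audit.csv", index=False)

    analysis_meals = meals[
        meals["meal_id"].isin(qual.loc[qual["qualified"], "meal_id"])
        & meals["participant_id"].isin(retained)].reset_index(drop=True)
    manifest["stages"]["analysis_meals"] = len(analysis_meals)

    # -- stage 3: features --------------------------------------------------
    features = compute_meal_features(analysis_meals, traces, epochs, sleep, config)
    events = build_events(analysis_meals, features, participants)
    complete = events.dropna(subset=["iauc_2h", "preprandial_mean_2h",
                                     *ACTIVITY_EXPOSURES]).reset_index(drop=True)
    manifest["stages"]["meals_with_complete_features"] = len(complete)
    log.append(f"{len(complete)} meals with complete glucose/activity/sleep features")

    # -- stage 4: decomposition --------------------------------------------
    events_c = person_center(complete, EXPOSURES)
    events_c.to_csv(out / "meal_events.csv", index=False)
    if config.run_icc:
        icc = variance_contribution_table(
            events_c,
            continuous=["iauc_2h", "satiety", *ACTIVITY_EXPOSURES],
            binary=[g for g in FOOD_GROUPS
                    if 0 < events_c[g].mean() < 1])
        icc.to_csv(out / "variance_contributions.csv", index=False)
        manifest["stages"]["icc_measures"] = len(icc)

    # -- stage 5: association models ---------------------------------------
    if config.run_models:
        table = association_table(events_c, B=config.bootstrap_B,
                                  seed=config.seed, run_basic=config.run_basic)
        table.to_csv(out / "association_table.csv", index=False)
        fm = table.attrs.get("full_model", {})
        manifest["model"] = {
            "n_obs": fm.get("n_obs"), "n_groups": fm.get("n_groups"),
            "icc_outcome_adjusted": fm.get("icc"),
            "converged": fm.get("converged"),
            "bootstrap_B": config.bootstrap_B,
        }
        for mod in config.interactions:
            res = interaction_test(events_c, mod)
            res.to_csv(out / f"interactions_{mod}.csv", index=False)
        for sv in config.strata:
            strat = stratified_fit(events_c, sv)
            for name, df in strat.items():
                df.to_csv(out / f"stratified_{sv}_{name}.csv", index=False)
            manifest["stages"][f"strata_{sv}"] = {
                name: int(df.attrs.get("n_obs", 0)) for name, df in strat.items()}

    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      sort_keys=True))
    (out / "run.log").write_text("\n".join(log) + "\n")
    return manifest
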