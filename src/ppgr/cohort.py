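"""Seeded synthetic free-living cohorts with known ground truth.

The generator emulates a nine-day observational protocol: six daily EMA
survey windows collecting meal reports (15 food-group flags plus satiety),
CGM readings every 15 min, wrist-accelerometer ENMO epochs at 5 s, and
nightly sleep windows.  Wearables start one day before the first survey
day (device fitting at the baseline visit), so every meal has a full 24-h
activity history and a prior night of sleep.

Each meal's 2-h postprandial iAUC is set by a linear model in the meal's
exposures — within-person deviations and person means enter with separate
coefficients — plus a time-of-day effect, a person intercept and Gaussian
noise, truncated at zero.  The target iAUC is delivered into the glucose
trace through a smooth non-negative bump of 2-h support (a Beta(5, 8)
density over 0-120 min, peak ~44 min) normalised to unit area, so
recomputing the trapezoidal iAUC from the generated trace recovers the
intended value up to discretisation error.  Default effect sizes and
summary levels are calibrated to the published cohort this design mirrors
(mean iAUC 137.4 mmol/l*min, pre-prandial glucose 5.4 mmol/l, daily LPA
2.8 h, daily MVPA 1.6 h, sleep 5.5 h, meal-time shares 29/36/35%).

Randomness is a single seed fanned out per participant through
``numpy.random.SeedSequence.spawn``, so enlarging the cohort never
perturbs already-generated participants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .activity import EpochSeries, meal_activity, sleep_before
from .cgm import GlucoseTrace
from .exposures import EXPOSURES, FOOD_GROUPS, TIME_CATEGORIES, validate_exposure_names
from .meals import time_category

__all__ = ["GroundTruth", "SimConfig", "CohortBundle", "generate_cohort",
           "intended_iauc", "default_ground_truth", "null_ground_truth",
           "FOOD_PREVALENCE"]

#: Per-meal consumption frequencies used for calibration (the two beverage
#: groups have no published frequency; defaults chosen once).
FOOD_PREVALENCE: dict[str, float] = {
    "refined_grains": 0.68, "whole_grains": 0.17, "seafood": 0.21,
    "chicken": 0.25, "red_meat": 0.24, "eggs": 0.22, "dairy": 0.07,
    "soy_food": 0.10, "beans_or_nuts": 0.08, "vegetables": 0.42,
    "fruits": 0.13, "deep_fried_food": 0.10, "sweet_desserts": 0.07,
    "sugary_beverages": 0.15, "non_sugary_beverages": 0.35,
}

_WITHIN_EFFECTS: dict[str, float] = {
    "refined_grains": 46.2, "whole_grains": 23.8, "seafood": -8.6,
    "chicken": -2.6, "red_meat": -4.2, "eggs": -5.2, "dairy": -13.5,
    "soy_food": -2.2, "beans_or_nuts": -9.2, "vegetables": 0.8,
    "fruits": -7.1, "deep_fried_food": 11.6, "sweet_desserts": 4.0,
    "sugary_beverages": -1.2, "non_sugary_beverages": -9.5,
    "satiety": 7.7, "pp_lpa_h": -24.7, "pp_mvpa_h": -58.0,
    "daily_lpa_h": -7.5, "daily_mvpa_h": 1.8, "sleep_h": -2.7,
}

_EXPOSURE_MEANS: dict[str, float] = {
    **FOOD_PREVALENCE, "satiety": 3.8, "pp_lpa_h": 0.3, "pp_mvpa_h": 0.2,
    "daily_lpa_h": 2.8, "daily_mvpa_h": 1.6, "sleep_h": 5.5,
}

_TIME_SHARES = {TIME_CATEGORIES[0]: 0.29, TIME_CATEGORIES[1]: 0.36,
                TIME_CATEGORIES[2]: 0.35}

_MEAN_IAUC = 137.4


@dataclass
class GroundTruth:
    """Simulation truth: the coefficients and variance components.

    ``within_effects`` act on a meal's deviation from the person mean,
    ``between_effects`` on the person mean itself; ``time_of_day_effects``
    are contrasts against morning meals.  Units are mmol/l*min per unit
    exposure.
    """

    within_effects: dict[str, float] = field(
        default_factory=lambda: dict(_WITHIN_EFFECTS))
    between_effects: dict[str, float] = field(
        default_factory=lambda: {**_WITHIN_EFFECTS, "refined_grains": 51.7})
    time_of_day_effects: dict[str, float] = field(
        default_factory=lambda: {TIME_CATEGORIES[1]: 54.4, TIME_CATEGORIES[2]: 42.9})
    iauc_intercept: float | None = None   # None -> calibrate to mean 137.4
    person_intercept_sd: float = 32.0
    residual_sd: float = 50.0
    baseline_glucose_mean: float = 5.4
    baseline_glucose_sd: float = 0.4
    kernel_a: float = 5.0
    kernel_b: float = 8.0

    def __post_init__(self) -> None:
        validate_exposure_names(self.within_effects)
        validate_exposure_names(self.between_effects)
        bad = set(self.time_of_day_effects) - set(TIME_CATEGORIES[1:])
        if bad:
            raise ValueError(f"unknown time-of-day categories: {sorted(bad)}")
        if self.person_intercept_sd < 0 or self.residual_sd < 0:
            raise ValueError("variance components must be non-negative")
        if self.iauc_intercept is None:
            fixed = sum(self.between_effects.get(e, 0.0) * _EXPOSURE_MEANS[e]
                        for e in EXPOSURES)
            tod = sum(_TIME_SHARES[c] * self.time_of_day_effects.get(c, 0.0)
                      for c in TIME_CATEGORIES)
            self.iauc_intercept = _MEAN_IAUC - fixed - tod

    def kernel_pdf(self, minutes: np.ndarray) -> np.ndarray:
        """Unit-area postprandial bump density over [0, 120] min."""
        return stats.beta.pdf(np.asarray(minutes) / 120.0,
                              self.kernel_a, self.kernel_b) / 120.0


def default_ground_truth() -> GroundTruth:
    return GroundTruth()


def null_ground_truth() -> GroundTruth:
    """All exposure and time-of-day effects zero; intercept kept positive."""
    zeros = {e: 0.0 for e in EXPOSURES}
    return GroundTruth(within_effects=dict(zeros), between_effects=dict(zeros),
                       time_of_day_effects={TIME_CATEGORIES[1]: 0.0,
                                            TIME_CATEGORIES[2]: 0.0},
                       iauc_intercept=95.0)


@dataclass
class SimConfig:
    """Study-design knobs of the generator; the seed determines everything."""

    n_participants: int = 150
    n_days: int = 9
    seed: int = 0
    start_date: str = "2023-03-06"
    ema_windows: tuple = ((8.0, 9.5), (10.5, 12.0), (13.0, 14.5),
                         (15.5, 17.0), (18.0, 19.5), (20.5, 21.5))
    cgm_interval_min: float = 15.0
    epoch_seconds: float = 5.0
    # meal reporting behaviour
    meal_probabilities: tuple = (0.75, 0.95, 0.90)   # morning / lunch / dinner
    spacing_violation_rate: float = 0.06
    night_meal_rate: float = 0.015
    ema_nonresponse: float = 0.08
    # sensor imperfections
    cgm_dropout: float = 0.02
    cgm_gap_rate: float = 0.03            # per day, chance of a 2-6 h sensor gap
    measurement_noise_sd: float = 0.10    # mmol/l
    circadian_amplitude: float = 0.05     # mmol/l; kept small so baseline
    # drift inside a 2-h window stays below ~1 mmol/l*min of area
    # exposure distributions (between = person level, within = occasion level)
    food_between_latent_share: float = 0.2
    food_prevalence: dict = field(default_factory=lambda: dict(FOOD_PREVALENCE))
    satiety_mean: float = 3.8
    satiety_between_sd: float = 0.65
    satiety_within_sd: float = 0.8
    daily_lpa_mean_h: float = 2.8
    daily_lpa_between_sd: float = 0.7
    daily_lpa_within_sd: float = 0.8
    daily_mvpa_mean_h: float = 1.6
    daily_mvpa_between_sd: float = 0.55
    daily_mvpa_within_sd: float = 0.45
    sleep_mean_h: float = 5.5
    sleep_between_sd: float = 0.85
    sleep_within_sd: float = 1.1
    sleep_onset_hour: float = 23.5
    sleep_onset_sd: float = 0.5
    lpa_bout_min: float = 8.0
    mvpa_bout_min: float = 6.0
    vigorous_fraction: float = 0.03
    #: optional within-meal latent correlations between food groups,
    #: e.g. {("refined_grains", "whole_grains"): -0.85}
    exposure_corr: dict | None = None

    def validate(self) -> None:
        if self.n_participants < 1 or self.n_days < 1:
            raise ValueError("cohort and study length must be positive")
        prev_end = 6.0
        for lo, hi in self.ema_windows:
            if not (6.0 <= lo < hi <= 24.0):
                raise ValueError(f"EMA window ({lo}, {hi}) outside 06:00-24:00")
            if lo < prev_end:
                raise ValueError("EMA windows must be ordered and non-overlapping")
            prev_end = hi
        for name in ("spacing_violation_rate", "night_meal_rate",
                     "ema_nonresponse", "cgm_dropout", "cgm_gap_rate",
                     "food_between_latent_share"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if sorted(self.food_prevalence) != sorted(FOOD_GROUPS):
            raise ValueError("food_prevalence must cover the canonical food groups")


def intended_iauc(exposures: dict[str, float], truth: GroundTruth,
                  time_cat: str = TIME_CATEGORIES[0],
                  person_intercept: float = 0.0,
                  person_means: dict[str, float] | None = None,
                  rng: np.random.Generator | None = None) -> float:
    """Target iAUC for one meal: max(0, linear predictor + noise).

    The linear predictor is ``intercept + sum_e bw_e * x_e +
    sum_e (bb_e - bw_e) * xbar_e + time-of-day + person intercept``; with
    ``person_means`` omitted the meal is treated as a pure within-person
    deviation from zero.
    """
    lp = float(truth.iauc_intercept) + person_intercept
    lp += truth.time_of_day_effects.get(time_cat, 0.0)
    means = person_means or {}
    for e, x in exposures.items():
        bw = truth.within_effects.get(e, 0.0)
        bb = truth.between_effects.get(e, 0.0)
        lp += bw * float(x) + (bb - bw) * float(means.get(e, 0.0))
    if rng is not None and truth.residual_sd > 0:
        lp += rng.normal(0.0, truth.residual_sd)
    return max(0.0, lp)


@dataclass
class CohortBundle:
    """Everything one simulated study produces, plus its hidden truth."""

    participants: pd.DataFrame
    ema: pd.DataFrame
    traces: dict[str, GlucoseTrace]
    epochs: dict[str, EpochSeries]
    sleep: pd.DataFrame
    truth: GroundTruth
    meal_truth: pd.DataFrame
    config: SimConfig

    def cgm_frame(self) -> pd.DataFrame:
        return pd.concat([t.to_frame() for t in self.traces.values()],
                         ignore_index=True)

    def epoch_frame(self) -> pd.DataFrame:
        return pd.concat([s.to_frame() for s in self.epochs.values()],
                         ignore_index=True)

    def write(self, out_dir, include_epochs: bool = True) -> None:
        """Write the four streams plus participants, truth and config."""
        from pathlib import Path
        import yaml
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.participants.to_csv(out / "participants.csv", index=False)
        self.ema.to_csv(out / "ema_responses.csv", index=False)
        self.cgm_frame().to_csv(out / "cgm.csv", index=False)
        self.sleep.to_csv(out / "sleep_windows.csv", index=False)
        if include_epochs:
            self.epoch_frame().to_csv(out / "epochs.csv", index=False,
                                      float_format="%.1f")
        self.meal_truth.to_csv(out / "meal_truth.csv", index=False)
        truth = {k: v for k, v in asdict(self.truth).items()}
        (out / "ground_truth.json").write_text(json.dumps(truth, indent=2,
                                                          sort_keys=True))
        cfg = asdict(self.config)
        cfg["ema_windows"] = [list(w) for w in self.config.ema_windows]
        if cfg.get("exposure_corr"):
            cfg["exposure_corr"] = {f"{a}|{b}": r for (a, b), r
                                    in self.config.exposure_corr.items()}
        with open(out / "sim_config.yaml", "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=True)


def _food_latent_chol(cfg: SimConfig) -> np.ndarray | None:
    if not cfg.exposure_corr:
        return None
    R = np.eye(len(FOOD_GROUPS))
    pos = {g: i for i, g in enumerate(FOOD_GROUPS)}
    for (a, b), r in cfg.exposure_corr.items():
        R[pos[a], pos[b]] = R[pos[b], pos[a]] = float(r)
    return np.linalg.cholesky(R)


def _place_bouts(labels: np.ndarray, i0: int, i1: int, rng,
                 lpa_epochs: int, mvpa_epochs: int, cfg: SimConfig) -> None:
    """Scatter non-overlapping LPA/MVPA bouts inside labels[i0:i1]."""
    W = i1 - i0
    total = lpa_epochs + mvpa_epochs
    if W <= 0 or total <= 0:
        return
    if total > W:
        scale = W / total
        lpa_epochs = int(lpa_epochs * scale)
        mvpa_epochs = int(mvpa_epochs * scale)
        total = lpa_epochs + mvpa_epochs
    bouts = []
    for band, tot, mean_min in ((1, lpa_epochs, cfg.lpa_bout_min),
                                (2, mvpa_epochs, cfg.mvpa_bout_min)):
        if tot <= 0:
            continue
        nb = max(1, int(round(tot * cfg.epoch_seconds / 60.0 / mean_min)))
        frac = rng.dirichlet(np.full(nb, 3.0))
        lens = np.maximum(1, np.round(frac * tot).astype(int))
        bouts.extend((band, int(l)) for l in lens)
    rng.shuffle(bouts)
    used = sum(l for _, l in bouts)
    free = W - used
    if free < 0:   # rounding overshoot: trim the last bouts
        for j in range(len(bouts) - 1, -1, -1):
            band, l = bouts[j]
            cut = min(l - 1, -free)
            bouts[j] = (band, l - cut)
            free += cut
            if free >= 0:
                break
        free = max(free, 0)
    gaps = np.floor(rng.dirichlet(np.ones(len(bouts) + 1)) * free).astype(int)
    pos = i0
    for j, (band, l) in enumerate(bouts):
        pos += gaps[j]
        labels[pos:pos + l] = band
        pos += l


def _enmo_from_labels(labels: np.ndarray, rng, cfg: SimConfig) -> np.ndarray:
    enmo = rng.uniform(0.0, 35.0, size=labels.size).astype(np.float32)
    lpa = labels == 1
    enmo[lpa] = rng.uniform(42.0, 95.0, size=int(lpa.sum()))
    mvpa = labels == 2
    n_mvpa = int(mvpa.sum())
    vals = rng.uniform(105.0, 380.0, size=n_mvpa)
    vig = rng.random(n_mvpa) < cfg.vigorous_fraction
    vals[vig] = rng.uniform(400.0, 600.0, size=int(vig.sum()))
    enmo[mvpa] = vals
    return enmo


def _schedule_meals(rng, cfg: SimConfig,
                    wake_hours: list[float] | None = None) -> list[tuple[int, float]]:
    """(day index, clock hour) pairs for one participant.

    Morning meals are scheduled after that morning's wake so "sleep the
    night before" is always defined for daytime meals.
    """
    p_morning, p_lunch, p_dinner = cfg.meal_probabilities
    meals: list[tuple[int, float]] = []
    for d in range(cfg.n_days):
        wake = wake_hours[d] if wake_hours is not None else 0.0
        day: list[float] = []
        if rng.random() < p_morning:
            lo = max(6.6, wake + 0.25)
            day.append(rng.uniform(lo, max(9.4, lo + 0.2)))
        if rng.random() < p_lunch:
            t = rng.uniform(11.8, 14.4)
            if day:
                t = max(t, day[-1] + 2.6)
            day.append(t)
        if rng.random() < p_dinner:
            t = rng.uniform(17.9, 21.3)
            if day:
                t = max(t, day[-1] + 2.6)
            day.append(t)
        if day and rng.random() < cfg.spacing_violation_rate:
            base = day[int(rng.integers(len(day)))]
            extra = base + rng.uniform(0.6, 2.4)
            if extra < 23.9:
                day.append(extra)
        if rng.random() < cfg.night_meal_rate:
            day.append(rng.uniform(0.3, 5.4))
        clocks = sorted(round(c * 60) / 60 for c in day)
        dedup = [c for j, c in enumerate(clocks) if j == 0 or c > clocks[j - 1]]
        meals.extend((d, c) for c in dedup)
    return meals


def generate_cohort(config: SimConfig | None = None,
                    truth: GroundTruth | None = None) -> CohortBundle:
    """Generate one complete synthetic study dataset.

    Returns a :class:`CohortBundle` whose ``meal_truth`` table records, for
    every generated meal, the realised exposures and the intended iAUC the
    glucose trace was built to carry.
    """
    cfg = config or SimConfig()
    cfg.validate()
    truth = truth or default_ground_truth()
    root = np.random.SeedSequence(cfg.seed)
    seeds = root.spawn(cfg.n_participants)
    start = pd.Timestamp(cfg.start_date)
    t_day0 = start.value / 1e9                       # first survey day, 00:00
    t0 = t_day0 - 86400.0                            # wearables start (day -1)
    t_end = t_day0 + cfg.n_days * 86400.0 + 6 * 3600.0
    n_epochs = int(round((t_end - t0) / cfg.epoch_seconds))
    chol = _food_latent_chol(cfg)
    n_foods = len(FOOD_GROUPS)
    thresholds = stats.norm.ppf([cfg.food_prevalence[g] for g in FOOD_GROUPS])
    r_b = cfg.food_between_latent_share

    p_rows, ema_rows, sleep_rows, truth_rows = [], [], [], []
    traces: dict[str, GlucoseTrace] = {}
    epochs: dict[str, EpochSeries] = {}

    for i in range(cfg.n_participants):
        rng = np.random.default_rng(seeds[i])
        pid = f"P{i:04d}"

        # --- baseline characteristics -------------------------------------
        age = int(np.clip(np.round(rng.normal(41, 14)), 21, 69))
        sex = "male" if rng.random() < 0.36 else "female"
        ethnicity = rng.choice(["Chinese", "Malay", "Indian"],
                               p=[0.75, 0.16, 0.09])
        education = rng.choice(
            ["secondary_or_below", "a_level", "university_or_above"],
            p=[0.12, 0.29, 0.59])
        smoker = bool(rng.random() < 0.12)
        alcohol = bool(rng.random() < 0.08)
        bmi = float(np.round(np.clip(rng.normal(24, 5), 16, 45), 1))
        z_f = rng.normal()
        fpg = float(np.round(np.clip(5.0 + 0.5 * z_f, 3.5, 7.5), 2))
        hba1c = float(np.round(np.clip(
            5.4 + 0.3 * (0.5 * z_f + np.sqrt(0.75) * rng.normal()), 4.2, 7.0), 2))
        prediabetes = bool(fpg >= 5.6 or hba1c >= 5.7)
        p_rows.append(dict(participant_id=pid, age=age, sex=sex,
                           ethnicity=ethnicity, education=education,
                           smoker=smoker, heavy_alcohol=alcohol, bmi=bmi,
                           fpg=fpg, hba1c=hba1c, prediabetes=prediabetes))

        b_i = rng.normal(0.0, truth.person_intercept_sd)
        baseline_i = rng.normal(truth.baseline_glucose_mean,
                                truth.baseline_glucose_sd)

        # --- sleep schedule (nights j = 0 .. n_days) ----------------------
        sleep_b = rng.normal(0.0, cfg.sleep_between_sd)
        onsets, wakes = [], []
        for j in range(cfg.n_days + 1):
            onset_h = np.clip(rng.normal(cfg.sleep_onset_hour,
                                         cfg.sleep_onset_sd), 22.0, 25.5)
            dur = np.clip(cfg.sleep_mean_h + sleep_b
                          + rng.normal(0.0, cfg.sleep_within_sd), 1.5, 11.0)
            onset_s = t0 + j * 86400.0 + onset_h * 3600.0
            onsets.append(onset_s)
            wakes.append(onset_s + dur * 3600.0)
        onsets = [round(o) for o in onsets]
        wakes = [round(w) for w in wakes]
        sleep_rows.extend(
            dict(participant_id=pid,
                 onset=pd.Timestamp(int(o) * 10**9),
                 wake=pd.Timestamp(int(w) * 10**9))
            for o, w in zip(onsets, wakes))
        sleep_df_i = pd.DataFrame({
            "onset": pd.to_datetime(np.array(onsets, dtype="int64"), unit="s"),
            "wake": pd.to_datetime(np.array(wakes, dtype="int64"), unit="s")})

        # --- accelerometer epochs -----------------------------------------
        labels = np.zeros(n_epochs, dtype=np.int8)
        lpa_b = rng.normal(0.0, cfg.daily_lpa_between_sd)
        mvpa_b = rng.normal(0.0, cfg.daily_mvpa_between_sd)
        waking = [(t0 + 6.5 * 3600.0, onsets[0])]
        waking += [(wakes[j], onsets[j + 1]) for j in range(cfg.n_days)]
        if wakes[cfg.n_days] < t_end:
            waking.append((wakes[cfg.n_days], t_end))
        for (w_start, w_end) in waking:
            L_h = (w_end - w_start) / 3600.0
            if L_h <= 0.5:
                continue
            lpa_h = float(np.clip(cfg.daily_lpa_mean_h + lpa_b
                                  + rng.normal(0.0, cfg.daily_lpa_within_sd),
                                  0.2, 0.8 * L_h))
            mvpa_h = float(np.clip(cfg.daily_mvpa_mean_h + mvpa_b
                                   + rng.normal(0.0, cfg.daily_mvpa_within_sd),
                                   0.05, 0.4 * L_h))
            i0 = int(np.ceil((w_start - t0) / cfg.epoch_seconds))
            i1 = int(np.floor((w_end - t0) / cfg.epoch_seconds))
            _place_bouts(labels, i0, i1, rng,
                         int(round(lpa_h * 3600.0 / cfg.epoch_seconds)),
                         int(round(mvpa_h * 3600.0 / cfg.epoch_seconds)), cfg)
        series = EpochSeries(pid, t0, _enmo_from_labels(labels, rng, cfg),
                             step_s=cfg.epoch_seconds)
        epochs[pid] = series

        # --- meals, foods, satiety ----------------------------------------
        wake_hours = [(wakes[d] - (t0 + (d + 1) * 86400.0)) / 3600.0
                      for d in range(cfg.n_days)]
        sched = _schedule_meals(rng, cfg, wake_hours)
        n_meals = len(sched)
        sat_b = rng.normal(0.0, cfg.satiety_between_sd)
        z_person = rng.standard_normal(n_foods)
        if chol is not None:
            z_person = chol @ z_person
        e_meal = rng.standard_normal((n_meals, n_foods))
        if chol is not None:
            e_meal = e_meal @ chol.T
        latent = np.sqrt(r_b) * z_person[None, :] + np.sqrt(1 - r_b) * e_meal
        flags = (latent < thresholds[None, :]).astype(int)
        satiety = np.clip(np.round(
            cfg.satiety_mean + sat_b
            + rng.normal(0.0, cfg.satiety_within_sd, size=n_meals)), 1, 6
        ).astype(int)

        meal_info = []
        for j, (d, clock) in enumerate(sched):
            t_meal = t_day0 + d * 86400.0 + clock * 3600.0
            t_meal = float(round(t_meal))            # whole-second meal times
            ts = pd.Timestamp(int(t_meal) * 10**9)
            act = meal_activity(series, t_meal)
            slp = sleep_before(sleep_df_i, t_meal)
            exposures = {g: float(flags[j, k]) for k, g in enumerate(FOOD_GROUPS)}
            exposures["satiety"] = float(satiety[j])
            exposures.update({k: float(v) for k, v in act.items()})
            exposures["sleep_h"] = float(slp)
            meal_info.append(dict(day=d, clock=clock, t_s=t_meal, ts=ts,
                                  idx=j, exposures=exposures,
                                  category=time_category(ts)))

        # --- EMA reporting -------------------------------------------------
        resp_hours = rng.uniform([w[0] for w in cfg.ema_windows],
                                 [w[1] for w in cfg.ema_windows],
                                 size=(cfg.n_days, len(cfg.ema_windows)))
        answered = rng.random((cfg.n_days, len(cfg.ema_windows))) >= cfg.ema_nonresponse
        for m in meal_info:
            d, clock = m["day"], m["clock"]
            row_day, row_w, occasion = None, None, None
            if clock < 6.0:
                if answered[d, 0]:
                    row_day, row_w = d, 0
                    occasion = ("after_last_ema_yesterday" if d > 0
                                else "since_waking")
            else:
                for w in range(len(cfg.ema_windows)):
                    if answered[d, w] and resp_hours[d, w] > clock:
                        row_day, row_w = d, w
                        occasion = ("since_waking" if w == 0
                                    else "since_last_prompt")
                        break
                else:
                    if d + 1 < cfg.n_days and answered[d + 1, 0]:
                        row_day, row_w = d + 1, 0
                        occasion = "after_last_ema_yesterday"
            m["logged"] = row_day is not None
            if not m["logged"]:
                continue
            resp_s = t_day0 + row_day * 86400.0 + resp_hours[row_day, row_w] * 3600.0
            hh, mm = int(clock), int(round((clock - int(clock)) * 60))
            j = m["idx"]
            rec = dict(participant_id=pid,
                       response_timestamp=pd.Timestamp(int(round(resp_s)) * 10**9),
                       occasion=occasion,
                       reported_clock_time=f"{hh:02d}:{mm:02d}",
                       satiety=int(satiety[j]))
            rec.update({g: int(flags[j, k]) for k, g in enumerate(FOOD_GROUPS)})
            ema_rows.append(rec)

        # --- intended iAUC and glucose trace ------------------------------
        day_meals = [m for m in meal_info
                     if m["logged"] and m["category"] is not None]
        means = {}
        for e in EXPOSURES:
            vals = [m["exposures"][e] for m in day_meals]
            mu = float(np.nanmean(vals)) if vals else float("nan")
            means[e] = mu if np.isfinite(mu) else _EXPOSURE_MEANS[e]
        for m in meal_info:
            cat = m["category"] or TIME_CATEGORIES[0]
            # a missing exposure (e.g. sleep before a night meal) contributes
            # at the person's habitual level, i.e. zero within-person deviation
            expo = {e: (x if np.isfinite(x) else means[e])
                    for e, x in m["exposures"].items()}
            m["intended"] = intended_iauc(expo, truth, time_cat=cat,
                                          person_intercept=b_i,
                                          person_means=means, rng=rng)
            truth_rows.append(dict(
                participant_id=pid,
                meal_id=f"{pid}-{m['ts']:%Y%m%dT%H%M}",
                meal_timestamp=m["ts"], time_category=m["category"],
                logged=m["logged"], intended_iauc=m["intended"],
                person_intercept=b_i, person_baseline=baseline_i,
                **m["exposures"]))

        # The intended iAUC is the *total* incremental area over the window,
        # circadian drift included; the bump therefore delivers the intended
        # value minus the (deterministic) net circadian area, so recomputing
        # the iAUC from the trace returns the intended value.
        u_min = np.arange(0.0, 121.0)
        for m in meal_info:
            h0 = ((m["t_s"] - t_day0) / 3600.0) % 24.0
            circ = cfg.circadian_amplitude * (
                np.sin(2 * np.pi * (h0 + u_min / 60.0 - 10.0) / 24.0)
                - np.sin(2 * np.pi * (h0 - 10.0) / 24.0))
            m["bump_scale"] = max(0.0, m["intended"] - float(np.trapezoid(circ, u_min)))

        phase = float(round(rng.uniform(0.0, cfg.cgm_interval_min * 60.0)))
        times = np.arange(t0 + phase, t_end, cfg.cgm_interval_min * 60.0)
        keep = rng.random(times.size) >= cfg.cgm_dropout
        for d in range(cfg.n_days + 1):
            if rng.random() < cfg.cgm_gap_rate:
                gs = t0 + d * 86400.0 + rng.uniform(0.0, 20.0) * 3600.0
                ge = gs + rng.uniform(2.0, 6.0) * 3600.0
                keep &= ~((times >= gs) & (times <= ge))
        times = times[keep]
        hours = ((times - t_day0) / 3600.0) % 24.0
        values = (baseline_i
                  + cfg.circadian_amplitude * np.sin(2 * np.pi * (hours - 10.0) / 24.0)
                  + rng.normal(0.0, cfg.measurement_noise_sd, size=times.size))
        for m in meal_info:
            if m["bump_scale"] <= 0.0:
                continue
            sel = (times > m["t_s"]) & (times <= m["t_s"] + 7200.0)
            if np.any(sel):
                offsets = (times[sel] - m["t_s"]) / 60.0
                values[sel] += m["bump_scale"] * truth.kernel_pdf(offsets)
        traces[pid] = GlucoseTrace(pid, times, np.maximum(values, 0.5))

    participants = pd.DataFrame(p_rows)
    ema = pd.DataFrame(ema_rows).sort_values(
        ["participant_id", "response_timestamp", "reported_clock_time"]
    ).reset_index(drop=True)
    sleep = pd.DataFrame(sleep_rows)
    meal_truth = pd.DataFrame(truth_rows)
    return CohortBundle(participants=participants, ema=ema, traces=traces,
                        epochs=epochs, sleep=sleep, truth=truth,
                        meal_truth=meal_truth, config=cfg)
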