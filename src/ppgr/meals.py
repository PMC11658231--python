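"""Meal records from EMA survey responses and the analysis inclusion rules.

A reported clock time ("HH:MM") is combined with the survey response date
to a full meal timestamp; for intakes reported the next morning on the
"after the last survey, before sleep yesterday" occasion, a clock time in
the evening half of the day places the meal on the previous calendar day.

A meal qualifies for analysis when (1) time-matched CGM readings cover
the pre- and postprandial windows, (2) no other reported intake falls in
the 2.5 h before it, and (3) it was eaten between 06:00 and 24:00.
Participants with fewer than three qualifying meals are excluded.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cgm import GlucoseTrace
from .exposures import FOOD_GROUPS, TIME_CATEGORIES

__all__ = [
    "OCCASIONS", "MealParseError", "CoverageRule",
    "resolve_meal_timestamp", "build_meal_records", "time_category",
    "qualify_meals", "filter_participants",
]

OCCASIONS = {"since_last_prompt", "after_last_ema_yesterday", "since_waking"}

_CLOCK_RE = re.compile(r"^\s*(\d{1,2})\s*:\s*(\d{2})\s*$")


class MealParseError(ValueError):
    """A malformed EMA record (bad clock time or occasion)."""


def _parse_clock(clock: str) -> tuple[int, int]:
    m = _CLOCK_RE.match(str(clock))
    if not m:
        raise MealParseError(f"clock time {clock!r} is not HH:MM")
    hh, mm = int(m.group(1)), int(m.group(2))
    if hh > 23 or mm > 59:
        raise MealParseError(f"clock time {clock!r} out of range")
    return hh, mm


def resolve_meal_timestamp(response_timestamp, occasion: str,
                           reported_clock_time: str) -> pd.Timestamp:
    """Full meal timestamp from a survey response.

    For ``after_last_ema_yesterday`` with an evening clock time (>= 12:00,
    i.e. before midnight) the meal date is the day before the response
    date; after-midnight intakes on that occasion, and all other
    occasions, keep the response date.
    """
    if occasion not in OCCASIONS:
        raise MealParseError(f"unknown occasion {occasion!r}")
    hh, mm = _parse_clock(reported_clock_time)
    day = pd.Timestamp(response_timestamp).normalize()
    if occasion == "after_last_ema_yesterday" and hh >= 12:
        day -= pd.Timedelta(days=1)
    return day + pd.Timedelta(hours=hh, minutes=mm)


def time_category(ts) -> str | None:
    """Half-open meal-time category, or None outside 06:00-24:00."""
    h = pd.Timestamp(ts).hour + pd.Timestamp(ts).minute / 60.0
    if 6.0 <= h < 12.0:
        return TIME_CATEGORIES[0]
    if 12.0 <= h < 18.0:
        return TIME_CATEGORIES[1]
    if 18.0 <= h < 24.0:
        return TIME_CATEGORIES[2]
    return None


def build_meal_records(ema: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Timestamped meal records from an EMA response table.

    Expects columns ``participant_id``, ``response_timestamp``,
    ``occasion``, ``reported_clock_time``, ``satiety`` and one 0/1 column
    per canonical food group.  Unparseable rows are skipped and returned in
    an error table; duplicate reports of the same meal (same participant
    and timestamp) keep the first occurrence.
    """
    rows, errors = [], []
    for i, rec in enumerate(ema.itertuples(index=False)):
        try:
            ts = resolve_meal_timestamp(rec.response_timestamp, rec.occasion,
                                        rec.reported_clock_time)
        except MealParseError as exc:
            errors.append({"row": i, "participant_id": rec.participant_id,
                           "error": str(exc)})
            continue
        row = {"participant_id": rec.participant_id, "meal_timestamp": ts,
               "satiety": rec.satiety}
        for g in FOOD_GROUPS:
            row[g] = int(getattr(rec, g))
        rows.append(row)
    meals = pd.DataFrame(rows)
    err = pd.DataFrame(errors, columns=["row", "participant_id", "error"])
    if meals.empty:
        cols = ["meal_id", "participant_id", "meal_timestamp", "satiety",
                *FOOD_GROUPS, "time_category"]
        return pd.DataFrame(columns=cols), err
    n0 = len(meals)
    meals = meals.drop_duplicates(subset=["participant_id", "meal_timestamp"],
                                  keep="first")
    if len(meals) < n0:
        err = pd.concat([err, pd.DataFrame([{
            "row": -1, "participant_id": "",
            "error": f"dropped {n0 - len(meals)} duplicate meal report(s)"}])],
            ignore_index=True)
    meals = meals.sort_values(["participant_id", "meal_timestamp"]).reset_index(drop=True)
    meals["time_category"] = meals["meal_timestamp"].map(time_category)
    meals.insert(0, "meal_id", [
        f"{p}-{t:%Y%m%dT%H%M}" for p, t in
        zip(meals["participant_id"], meals["meal_timestamp"])
    ])
    return meals, err


@dataclass
class CoverageRule:
    """What "time-matched CGM measures" requires of a trace around a meal.

    At least ``min_pre_readings`` readings in the closed 2-h pre-window,
    one reading within ``baseline_gap_min`` before the meal (so the
    baseline is interpolable), at least ``post_fraction`` of the expected
    readings inside the half-open 2-h post-window, and the whole
    [t-2h, t+2h] window inside the trace span.
    """

    window_min: float = 120.0
    interval_min: float = 15.0
    post_fraction: float = 0.8
    min_pre_readings: int = 1
    baseline_gap_min: float = 45.0

    @property
    def min_post_readings(self) -> int:
        return int(np.ceil(self.post_fraction * self.window_min / self.interval_min))


def _has_coverage(trace: GlucoseTrace, t_s: float, rule: CoverageRule) -> bool:
    w = rule.window_min * 60.0
    lo, hi = trace.span
    if t_s - w < lo or t_s + w > hi:
        return False
    pre = np.count_nonzero((trace.times >= t_s - w) & (trace.times <= t_s))
    if pre < rule.min_pre_readings:
        return False
    near = np.count_nonzero((trace.times >= t_s - rule.baseline_gap_min * 60.0)
                            & (trace.times <= t_s))
    if near < 1:
        return False
    post = np.count_nonzero((trace.times > t_s) & (trace.times <= t_s + w))
    return post >= rule.min_post_readings


def qualify_meals(meals: pd.DataFrame, traces: dict[str, GlucoseTrace],
                  prior_gap_h: float = 2.5,
                  coverage: CoverageRule | None = None) -> pd.DataFrame:
    """Apply the three inclusion rules to every meal, reporting all failures.

    The prior-intake rule looks at *all* reported meals (qualified or not)
    in the half-open window [t-2.5h, t); the clock rule requires the meal
    time in [06:00, 24:00); the coverage rule is :class:`CoverageRule`.
    Rules are applied independently, so a meal can fail several at once.
    """
    coverage = coverage or CoverageRule()
    out = []
    meals = meals.reset_index(drop=True)
    ts_all = meals["meal_timestamp"].astype("int64").to_numpy() / 1e9
    for pid, grp in meals.groupby("participant_id", sort=False):
        t = np.sort(ts_all[grp.index.to_numpy()])
        trace = traces.get(pid)
        for idx in grp.index:
            t_s = ts_all[idx]
            reasons = []
            lo = np.searchsorted(t, t_s - prior_gap_h * 3600.0, side="left")
            hi = np.searchsorted(t, t_s, side="left")
            if hi > lo:
                reasons.append("prior_intake_within_2p5h")
            if meals.at[idx, "time_category"] is None:
                reasons.append("outside_0600_2400")
            if trace is None or not _has_coverage(trace, t_s, coverage):
                reasons.append("no_cgm_coverage")
            out.append({"meal_id": meals.at[idx, "meal_id"],
                        "participant_id": pid,
                        "qualified": not reasons,
                        "failure_reasons": ";".join(reasons)})
    return pd.DataFrame(out, columns=["meal_id", "participant_id", "qualified",
                                      "failure_reasons"])


def filter_participants(qualification: pd.DataFrame, min_meals: int = 3) -> list[str]:
    """Participants retained for analysis: >= ``min_meals`` qualifying meals."""
    if qualification.empty:
        return []
    counts = qualification[qualification["qualified"]].groupby("participant_id").size()
    return sorted(counts[counts >= min_meals].index.tolist())
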