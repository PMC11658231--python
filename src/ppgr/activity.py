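"""Intensity classification of 5-s ENMO epochs and meal-anchored exposures.

Epochs are classified by ENMO cut-points (lower edge inclusive): < 40 mg
inactive, 40-100 mg light (LPA), >= 100 mg moderate-to-vigorous (MVPA),
with >= 400 mg additionally flagged vigorous.  Durations are plain epoch
counts times 5 s — no bout-length requirement.  Window conventions are
half-open and consistent: the postprandial window is (t, t+2h], the daily
window [t-24h, t), so no epoch is counted twice across the meal boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cgm import to_epoch_seconds

__all__ = [
    "INACTIVE", "LPA", "MVPA",
    "LPA_THRESHOLD_MG", "MVPA_THRESHOLD_MG", "VIGOROUS_THRESHOLD_MG",
    "classify_enmo", "classify_epoch", "EpochSeries",
    "duration_in_window", "meal_activity", "sleep_before",
]

INACTIVE, LPA, MVPA = 0, 1, 2
_BAND_CODES = {"inactive": INACTIVE, "lpa": LPA, "mvpa": MVPA}
_BAND_NAMES = {v: k for k, v in _BAND_CODES.items()}

LPA_THRESHOLD_MG = 40.0
MVPA_THRESHOLD_MG = 100.0
VIGOROUS_THRESHOLD_MG = 400.0


def classify_enmo(enmo) -> np.ndarray:
    """Vectorised band codes (0 inactive, 1 LPA, 2 MVPA) for ENMO in mg."""
    x = np.asarray(enmo, dtype=np.float64)
    if np.any(~np.isfinite(x)) or np.any(x < 0):
        raise ValueError("ENMO values must be finite and non-negative")
    codes = np.zeros(x.shape, dtype=np.int8)
    codes[x >= LPA_THRESHOLD_MG] = LPA
    codes[x >= MVPA_THRESHOLD_MG] = MVPA
    return codes


def classify_epoch(enmo: float) -> tuple[str, bool]:
    """Band name and vigorous flag for a single epoch's ENMO (mg)."""
    code = int(classify_enmo(np.array([enmo]))[0])
    return _BAND_NAMES[code], bool(enmo >= VIGOROUS_THRESHOLD_MG)


@dataclass
class EpochSeries:
    """Regular 5-s ENMO series for one participant.

    Stored as a start time plus a dense value array; epoch ``i`` is stamped
    ``start_s + i * step_s``.  Band-count prefix sums are cached so window
    queries cost O(1).
    """

    participant_id: str
    start_s: float
    enmo: np.ndarray
    step_s: float = 5.0
    _cum: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.enmo = np.asarray(self.enmo, dtype=np.float32)
        if np.any(self.enmo < 0):
            raise ValueError("ENMO must be non-negative")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, participant_id: str | None = None,
                   step_s: float = 5.0) -> "EpochSeries":
        if participant_id is not None:
            frame = frame[frame["participant_id"] == participant_id]
        else:
            participant_id = frame["participant_id"].iloc[0]
        t = pd.to_datetime(frame["timestamp"]).astype("int64").to_numpy() / 1e9
        order = np.argsort(t)
        t = t[order]
        vals = frame["enmo_mg"].to_numpy()[order]
        if t.size > 1:
            steps = np.diff(t)
            if not np.allclose(steps, step_s):
                raise ValueError("epoch timestamps are not on a regular 5-s grid")
        return cls(str(participant_id), float(t[0]), vals, step_s=step_s)

    def to_frame(self) -> pd.DataFrame:
        t = self.start_s + self.step_s * np.arange(self.enmo.size)
        return pd.DataFrame({
            "participant_id": self.participant_id,
            "timestamp": pd.to_datetime(np.round(t).astype("int64"), unit="s"),
            "enmo_mg": self.enmo.astype(np.float64),
        })

    @property
    def end_s(self) -> float:
        """Timestamp of the last epoch."""
        return self.start_s + self.step_s * (self.enmo.size - 1)

    def _cumulative(self) -> np.ndarray:
        if self._cum is None:
            codes = classify_enmo(self.enmo)
            cum = np.zeros((3, codes.size + 1), dtype=np.int64)
            for band in (INACTIVE, LPA, MVPA):
                np.cumsum(codes == band, out=cum[band, 1:])
            self._cum = cum
        return self._cum

    def _index_range(self, a_s: float, b_s: float, left_open: bool,
                     right_closed: bool) -> tuple[int, int]:
        # Epochs with timestamp in the requested interval, as [i0, i1).
        ra = (a_s - self.start_s) / self.step_s
        rb = (b_s - self.start_s) / self.step_s
        i0 = math.floor(ra) + 1 if left_open else math.ceil(ra)
        i1 = math.floor(rb) + 1 if right_closed else math.ceil(rb)
        i0 = max(i0, 0)
        i1 = min(i1, self.enmo.size)
        return i0, max(i1, i0)

    def count_in(self, a_s: float, b_s: float, band: int,
                 left_open: bool = False, right_closed: bool = True) -> int:
        i0, i1 = self._index_range(a_s, b_s, left_open, right_closed)
        cum = self._cumulative()
        return int(cum[band, i1] - cum[band, i0])

    def total_in(self, a_s: float, b_s: float, left_open: bool = False,
                 right_closed: bool = True) -> int:
        i0, i1 = self._index_range(a_s, b_s, left_open, right_closed)
        return i1 - i0


def duration_in_window(series: EpochSeries, start, end, band: str,
                       left_open: bool = False, right_closed: bool = True) -> float:
    """Hours of a band inside a time window (epoch count x 5 s)."""
    a, b = to_epoch_seconds(start), to_epoch_seconds(end)
    if b < a:
        raise ValueError("window end precedes window start")
    n = series.count_in(a, b, _BAND_CODES[band], left_open, right_closed)
    return n * series.step_s / 3600.0


def meal_activity(series: EpochSeries, meal_time,
                  pp_window_h: float = 2.0, daily_window_h: float = 24.0) -> dict:
    """Meal-anchored activity exposures, or NaNs when a window leaves the span.

    Returns ``pp_lpa_h``/``pp_mvpa_h`` for the (t, t+2h] window and
    ``daily_lpa_h``/``daily_mvpa_h`` for [t-24h, t).
    """
    t = to_epoch_seconds(meal_time)
    out: dict[str, float] = {}
    pp_ok = t >= series.start_s and t + pp_window_h * 3600.0 <= series.end_s
    daily_ok = t - daily_window_h * 3600.0 >= series.start_s and t <= series.end_s
    for band, name in ((LPA, "lpa"), (MVPA, "mvpa")):
        out[f"pp_{name}_h"] = (
            series.count_in(t, t + pp_window_h * 3600.0, band,
                            left_open=True, right_closed=True) * series.step_s / 3600.0
            if pp_ok else float("nan")
        )
        out[f"daily_{name}_h"] = (
            series.count_in(t - daily_window_h * 3600.0, t, band,
                            left_open=False, right_closed=False) * series.step_s / 3600.0
            if daily_ok else float("nan")
        )
    return out


def sleep_before(sleep_windows: pd.DataFrame, meal_time,
                 lookback_h: float = 24.0) -> float:
    """Duration (h) of the most recent sleep window waking before the meal.

    ``sleep_windows`` holds one participant's windows with ``onset`` and
    ``wake`` columns.  The window must wake within ``lookback_h`` hours of
    the meal; among several candidates (e.g. nap then main sleep) the later
    wake wins.  Returns NaN when no window qualifies.
    """
    if sleep_windows.empty:
        return float("nan")
    onset = pd.to_datetime(sleep_windows["onset"]).astype("int64").to_numpy() / 1e9
    wake = pd.to_datetime(sleep_windows["wake"]).astype("int64").to_numpy() / 1e9
    if np.any(wake <= onset):
        raise ValueError("sleep windows must have wake > onset")
    order = np.argsort(onset)
    onset, wake = onset[order], wake[order]
    if np.any(onset[1:] < wake[:-1]):
        raise ValueError("sleep windows overlap")
    t = to_epoch_seconds(meal_time)
    ok = (wake <= t) & (wake >= t - lookback_h * 3600.0)
    if not np.any(ok):
        return float("nan")
    last = np.nonzero(ok)[0][-1]
    return float((wake[last] - onset[last]) / 3600.0)
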