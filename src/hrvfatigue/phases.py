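"""Sleep/active phase segmentation of timed HRV measurements.

The protocol classifies measurements by clock time alone: the sleep phase is
a fixed nightly window (default 22:00-08:00, ten hourly slots) and the rest
of the day is the active phase (fourteen hourly slots).  Windows are
half-open, ``[start, end)``, so the two phases partition the 24-hour day and
a measurement taken exactly at wake-up time counts as active.

Also provided: detection of daytime rest events — active-phase measurements
with LF-HF < 1 together with a heart rate well below the patient's active
median, the signature of an unplanned nap on real traces.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import time

import pandas as pd

from .errors import ConfigurationError, InsufficientDataError

__all__ = ["PhaseConfig", "assign_phases", "detect_rest_events", "night_ids", "day_ids"]

SLEEP = "sleep"
ACTIVE = "active"


@dataclass(frozen=True)
class PhaseConfig:
    """Clock-time boundaries of the nightly sleep window (may wrap midnight)."""

    sleep_start: time = time(22, 0)
    sleep_end: time = time(8, 0)

    def __post_init__(self) -> None:
        if self.sleep_start == self.sleep_end:
            raise ConfigurationError("sleep window must not cover the whole day")

    def is_sleep(self, clock: time) -> bool:
        s, e = self.sleep_start, self.sleep_end
        if s < e:
            return s <= clock < e
        return clock >= s or clock < e  # wraps midnight


def _clock(times: pd.Series) -> pd.Series:
    return pd.to_datetime(times).dt.time


def assign_phases(records: pd.DataFrame, config: PhaseConfig | None = None) -> pd.DataFrame:
    """Label each measurement ``sleep`` or ``active`` by its clock time.

    Returns a copy with the ``phase`` column (re)written; idempotent.
    """
    cfg = config or PhaseConfig()
    if "timestamp" not in records.columns:
        raise ConfigurationError("records need a 'timestamp' column")
    out = records.copy()
    is_sleep = _clock(out["timestamp"]).map(cfg.is_sleep)
    out["phase"] = is_sleep.map({True: SLEEP, False: ACTIVE})
    return out


def night_ids(records: pd.DataFrame, config: PhaseConfig | None = None) -> pd.Series:
    """Calendar date on which each sleep-phase record's night began.

    For a window wrapping midnight, post-midnight measurements belong to the
    previous day's night.
    """
    cfg = config or PhaseConfig()
    ts = pd.to_datetime(records["timestamp"])
    dates = ts.dt.date
    if cfg.sleep_start > cfg.sleep_end:  # wraps midnight
        before_start = ts.dt.time < cfg.sleep_start
        dates = dates.where(~before_start, dates - pd.Timedelta(days=1))
    return dates


def day_ids(records: pd.DataFrame) -> pd.Series:
    """Calendar date of each active-phase record."""
    return pd.to_datetime(records["timestamp"]).dt.date


def detect_rest_events(
    records: pd.DataFrame,
    hr_drop: float = 5.0,
    config: PhaseConfig | None = None,
) -> pd.DataFrame:
    """Flag daytime rest events among active-phase measurements.

    An active record is a rest event when LF-HF < 1 *and* its heart rate is
    more than ``hr_drop`` beats/min below the patient's active-phase median.
    Flagged records are returned; the active disorder ratio itself uses only
    the LF-HF criterion, so this is a descriptive report.
    """
    if "phase" not in records.columns or records["phase"].eq("unassigned").all():
        records = assign_phases(records, config)
    active = records[records["phase"] == ACTIVE]
    if len(active) < 3:
        raise InsufficientDataError(
            f"need >= 3 active-phase records to estimate the HR baseline, got {len(active)}"
        )
    threshold = active["hr"].median() - hr_drop
    flagged = active[(active["lfhf"] < 1.0) & (active["hr"] < threshold)]
    return flagged.copy()
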