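"""Per-patient HRV fatigue features.

Three statistics summarise a patient's phase-labelled measurement stream:

* the **sleep disorder ratio** — the mean nightly count of sleep-phase
  measurements with LF-HF > 1 divided by the slots per night; high values
  indicate shortened deep sleep,
* the **mean sleep LF-HF** — arithmetic mean (and sample SD) of the
  sleep-phase ratio over all nights,
* the **active disorder ratio** — the mean daily count of active-phase
  measurements with LF-HF < 1 divided by the slots per day; high values
  indicate frequent daytime sleep/rest events.

Thresholds are strict: a measurement at exactly LF-HF = 1 counts in neither
tally.  Invalid measurements are excluded from both numerator and
denominator; by default the denominator is the observed number of valid
slots, with the nominal 10/14 available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import phases
from .errors import InsufficientDataError
from .phases import PhaseConfig

__all__ = [
    "FatigueFeatures",
    "sleep_disorder_ratio",
    "active_disorder_ratio",
    "mean_sleep_lfhf",
    "extract_features",
]


@dataclass(frozen=True)
class FatigueFeatures:
    """The per-patient feature triple plus bookkeeping.

    Ratios are fractions on [0, 1]; ``sleep_count``/``active_count`` are the
    mean per-night / per-day disorder counts the fractions derive from.
    """

    patient_id: str
    sleep_count: float
    sleep_disorder_ratio: float
    mean_sleep_lfhf: float
    sd_sleep_lfhf: float
    active_count: float
    active_disorder_ratio: float
    per_night_counts: tuple[int, ...]
    per_day_counts: tuple[int, ...]
    n_days: int
    bfi: float | None = None

    @property
    def vector(self) -> np.ndarray:
        """(sleep disorder ratio, mean sleep LF-HF, active disorder ratio)."""
        return np.array(
            [self.sleep_disorder_ratio, self.mean_sleep_lfhf, self.active_disorder_ratio]
        )


def _valid(records: pd.DataFrame) -> pd.DataFrame:
    if "valid" in records.columns:
        return records[records["valid"].astype(bool)]
    return records


def _phase_records(records: pd.DataFrame, phase: str) -> pd.DataFrame:
    if "phase" not in records.columns:
        raise InsufficientDataError("records must be phase-labelled first")
    return _valid(records[records["phase"] == phase])


def sleep_disorder_ratio(
    records: pd.DataFrame,
    config: PhaseConfig | None = None,
    nominal_slots: int | None = None,
) -> tuple[float, float, tuple[int, ...]]:
    """Mean nightly count of sleep measurements with LF-HF > 1, and its fraction.

    Returns ``(mean_count, fraction, per_night_counts)``.  The fraction
    divides the total disorder count by the total number of valid sleep
    slots observed; pass ``nominal_slots`` (e.g. 10) to divide by the
    nominal slot count instead.
    """
    sleep = _phase_records(records, phases.SLEEP)
    if sleep.empty:
        raise InsufficientDataError("no valid sleep-phase records")
    nights = phases.night_ids(sleep, config)
    disorder = sleep["lfhf"] > 1.0
    counts = disorder.groupby(nights).sum()
    slots = disorder.groupby(nights).size()
    mean_count = float(counts.mean())
    if nominal_slots is not None:
        fraction = mean_count / nominal_slots
    else:
        fraction = float(counts.sum() / slots.sum())
    return mean_count, fraction, tuple(int(c) for c in counts)


def active_disorder_ratio(
    records: pd.DataFrame,
    nominal_slots: int | None = None,
) -> tuple[float, float, tuple[int, ...]]:
    """Mean daily count of active measurements with LF-HF < 1, and its fraction."""
    active = _phase_records(records, phases.ACTIVE)
    if active.empty:
        raise InsufficientDataError("no valid active-phase records")
    days = phases.day_ids(active)
    disorder = active["lfhf"] < 1.0
    counts = disorder.groupby(days).sum()
    slots = disorder.groupby(days).size()
    mean_count = float(counts.mean())
    if nominal_slots is not None:
        fraction = mean_count / nominal_slots
    else:
        fraction = float(counts.sum() / slots.sum())
    return mean_count, fraction, tuple(int(c) for c in counts)


def mean_sleep_lfhf(records: pd.DataFrame) -> tuple[float, float]:
    """Mean and sample SD of the LF-HF ratio over all valid sleep measurements."""
    sleep = _phase_records(records, phases.SLEEP)
    if len(sleep) < 2:
        raise InsufficientDataError(
            f"need >= 2 valid sleep-phase records for a mean and SD, got {len(sleep)}"
        )
    vals = sleep["lfhf"].to_numpy(dtype=float)
    return float(vals.mean()), float(vals.std(ddof=1))


def extract_features(
    records: pd.DataFrame,
    patient_id: str | None = None,
    bfi: float | None = None,
    config: PhaseConfig | None = None,
    nominal_slots: tuple[int, int] | None = None,
) -> FatigueFeatures:
    """Bundle the three fatigue statistics for one patient's stream."""
    if records.empty:
        raise InsufficientDataError("empty measurement stream")
    if patient_id is None:
        ids = records.get("patient_id")
        patient_id = str(ids.iloc[0]) if ids is not None else "unknown"
    nom_sleep, nom_active = nominal_slots or (None, None)
    s_count, s_ratio, per_night = sleep_disorder_ratio(records, config, nom_sleep)
    a_count, a_ratio, per_day = active_disorder_ratio(records, nom_active)
    m, sd = mean_sleep_lfhf(records)
    return FatigueFeatures(
        patient_id=patient_id,
        sleep_count=s_count,
        sleep_disorder_ratio=s_ratio,
        mean_sleep_lfhf=m,
        sd_sleep_lfhf=sd,
        active_count=a_count,
        active_disorder_ratio=a_ratio,
        per_night_counts=per_night,
        per_day_counts=per_day,
        n_days=len(per_night),
        bfi=bfi,
    )
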