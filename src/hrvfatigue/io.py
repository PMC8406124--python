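"""File schemas, the embedded study table, and run configuration.

Tabular data travel as UTF-8 CSV ('.' decimal): the measurement schema
``patient_id,timestamp,hr,lf,hf,lfhf,phase,valid`` (ISO-8601 timestamps with
offset) and the per-patient feature schema written by
:func:`write_features`.  Models and reports are JSON.

The embedded study table holds the published per-patient summary statistics
for the 12-patient lung-cancer cohort: mean nightly count (and percent) of
sleep measurements with LF-HF > 1 out of 10 slots, mean (SD) sleep LF-HF,
mean daily count (and percent) of active measurements with LF-HF < 1 out of
14 slots, and the self-reported BFI-T score.  It is the reference input for
refitting the mapping and reproducing the error statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError
from .features import FatigueFeatures

__all__ = [
    "MEASUREMENT_COLUMNS",
    "StudyFixture",
    "load_fixture",
    "fixture_features",
    "read_measurements",
    "write_measurements",
    "read_features",
    "write_features",
]

MEASUREMENT_COLUMNS = ["patient_id", "timestamp", "hr", "lf", "hf", "lfhf", "phase", "valid"]

FEATURE_COLUMNS = [
    "patient_id",
    "sleep_count",
    "sleep_ratio",
    "mean_lfhf",
    "sd_lfhf",
    "active_count",
    "active_ratio",
    "bfi",
]

#: slots per night / per day in the study protocol
SLEEP_SLOTS, ACTIVE_SLOTS = 10, 14

# Published per-patient summary rows, ordered by fatigue severity:
# (id, sleep disorder count, %, mean sleep LF-HF, SD, active disorder
#  count, %, BFI-T, note)
_STUDY_ROWS = [
    ("P03", 0.0, 0, 0.73, 0.07, 4.5, 32, 0.00, "No"),
    ("P13", 0.8, 8, 0.91, 0.44, 7.0, 50, 0.00, "No"),
    ("P06", 1.7, 17, 0.95, 0.20, 2.6, 19, 0.00, "No"),
    ("P02", 2.5, 25, 1.14, 0.51, 8.6, 61, 0.00, "No"),
    ("P10", 3.7, 37, 1.04, 0.44, 1.5, 11, 1.22, "Mild"),
    ("P07", 3.3, 33, 1.04, 0.25, 5.0, 36, 1.33, "Mild"),
    ("P11", 3.6, 36, 1.11, 0.33, 12.3, 88, 1.78, "Mild"),
    ("P01", 4.5, 45, 1.11, 0.27, 0.2, 1, 1.56, "Mild"),
    ("P12", 6.0, 60, 1.51, 0.73, 1.8, 13, 1.22, "Mild"),
    ("P04", 4.5, 45, 2.12, 1.65, 1.5, 11, 1.11, "Mild"),
    ("P08", 8.0, 80, 2.49, 1.78, 1.2, 9, 5.00, "Moderate"),
    ("P05", 9.1, 91, 3.19, 2.29, 1.9, 14, 5.67, "Moderate"),
]

_STUDY_COLUMNS = [
    "patient_id",
    "sleep_count",
    "sleep_pct",
    "mean_lfhf",
    "sd_lfhf",
    "active_count",
    "active_pct",
    "bfi",
    "note",
]


@dataclass(frozen=True)
class StudyFixture:
    """The 12-patient summary table with consistency checks applied."""

    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)

    def row(self, patient_id: str) -> pd.Series:
        match = self.table[self.table["patient_id"] == patient_id]
        if match.empty:
            raise KeyError(f"unknown patient id {patient_id!r}")
        return match.iloc[0]


def _check_fixture(df: pd.DataFrame) -> None:
    for _, r in df.iterrows():
        sleep_pct = round(r["sleep_count"] / SLEEP_SLOTS * 100)
        active_pct = round(r["active_count"] / ACTIVE_SLOTS * 100)
        if sleep_pct != r["sleep_pct"] or active_pct != r["active_pct"]:
            raise SchemaError(f"inconsistent count/percent pair in row {r['patient_id']}")
        if not 0.0 <= r["bfi"] <= 10.0:
            raise SchemaError(f"BFI out of range in row {r['patient_id']}")


def load_fixture() -> StudyFixture:
    """The embedded 12-patient study table (validated)."""
    df = pd.DataFrame(_STUDY_ROWS, columns=_STUDY_COLUMNS)
    _check_fixture(df)
    return StudyFixture(table=df)


def fixture_features(fixture: StudyFixture | None = None) -> tuple[list[FatigueFeatures], np.ndarray]:
    """The study table as fraction-scale feature objects plus BFI scores.

    Disorder ratios come from the printed counts divided by the nominal
    slots per night/day (10 and 14); only summary statistics are available
    for the published cohort, so per-night count lists are empty.
    """
    fx = fixture or load_fixture()
    feats = []
    for _, r in fx.table.iterrows():
        feats.append(
            FatigueFeatures(
                patient_id=r["patient_id"],
                sleep_count=float(r["sleep_count"]),
                sleep_disorder_ratio=float(r["sleep_count"]) / SLEEP_SLOTS,
                mean_sleep_lfhf=float(r["mean_lfhf"]),
                sd_sleep_lfhf=float(r["sd_lfhf"]),
                active_count=float(r["active_count"]),
                active_disorder_ratio=float(r["active_count"]) / ACTIVE_SLOTS,
                per_night_counts=(),
                per_day_counts=(),
                n_days=7,
                bfi=float(r["bfi"]),
            )
        )
    return feats, fx.table["bfi"].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Measurement / feature CSV schemas
# ---------------------------------------------------------------------------

def read_measurements(path: str | Path, rel_tol: float = 1e-6) -> pd.DataFrame:
    """Load and validate a measurement CSV.

    Checks the header, timestamp parseability, positivity of HF for valid
    rows, and that the stored ``lfhf`` matches ``lf / hf``; violations are
    reported with 1-based data row numbers.
    """
    df = pd.read_csv(path)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"{path}: unparseable timestamps ({exc})") from exc
    df["valid"] = df["valid"].astype(bool)

    problems = []
    valid = df["valid"]
    bad_hf = valid & ~(df["hf"] > 0)
    for i in df.index[bad_hf]:
        problems.append(f"row {i + 1}: non-positive hf on a valid record")
    have = valid & df[["lf", "hf", "lfhf"]].notna().all(axis=1) & (df["hf"] > 0)
    ratio = df.loc[have, "lf"] / df.loc[have, "hf"]
    off = (ratio - df.loc[have, "lfhf"]).abs() > rel_tol * np.maximum(1.0, ratio.abs())
    for i in off.index[off]:
        problems.append(
            f"row {i + 1}: lfhf={df.loc[i, 'lfhf']:g} inconsistent with lf/hf={ratio[i]:g}"
        )
    if problems:
        raise SchemaError(f"{path}: " + "; ".join(problems))
    return df[MEASUREMENT_COLUMNS]


def write_measurements(df: pd.DataFrame, path: str | Path) -> None:
    """Write measurements in the canonical column order, ISO timestamps."""
    out = df[MEASUREMENT_COLUMNS].copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).map(lambda t: t.isoformat())
    out.to_csv(path, index=False)


def write_features(features: Sequence[FatigueFeatures], path: str | Path) -> None:
    rows = [
        (
            f.patient_id,
            f.sleep_count,
            f.sleep_disorder_ratio,
            f.mean_sleep_lfhf,
            f.sd_sleep_lfhf,
            f.active_count,
            f.active_disorder_ratio,
            "" if f.bfi is None else f.bfi,
        )
        for f in features
    ]
    pd.DataFrame(rows, columns=FEATURE_COLUMNS).to_csv(path, index=False)


def read_features(path: str | Path) -> list[FatigueFeatures]:
    df = pd.read_csv(path)
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    feats = []
    for _, r in df.iterrows():
        feats.append(
            FatigueFeatures(
                patient_id=str(r["patient_id"]),
                sleep_count=float(r["sleep_count"]),
                sleep_disorder_ratio=float(r["sleep_ratio"]),
                mean_sleep_lfhf=float(r["mean_lfhf"]),
                sd_sleep_lfhf=float(r["sd_lfhf"]),
                active_count=float(r["active_count"]),
                active_disorder_ratio=float(r["active_ratio"]),
                per_night_counts=(),
                per_day_counts=(),
                n_days=0,
                bfi=None if pd.isna(r["bfi"]) else float(r["bfi"]),
            )
        )
    return feats


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2) + "\n")
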