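"""Frequency-domain HRV parameters from 2-minute interbeat-interval segments.

Reproduces what the device cloud computes for each timed measurement: heart
rate plus spectral power of the interbeat-interval (tachogram) series in a
low-frequency band (sympathetic + parasympathetic, default 0.05-0.15 Hz) and
a high-frequency band (parasympathetic, default 0.15-0.40 Hz), and their
ratio LF/HF as the sympathovagal-balance index consumed downstream.

Two estimators are provided behind one interface: a Lomb-Scargle periodogram
of the detrended tachogram (default; handles gaps left by artifact removal)
and cubic interpolation to an evenly sampled series followed by a windowed
periodogram.  Band powers are normalised so that the periodogram integrated
over the full frequency grid equals the series variance, which guarantees
LF + HF never exceeds the total variance and makes the LF/HF ratio exactly
invariant under amplitude scaling of the fluctuations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import datetime

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import lombscargle, periodogram

from .errors import ConfigurationError

__all__ = [
    "IBISegment",
    "SpectralBands",
    "MeasurementRecord",
    "CleanResult",
    "clean_ibi",
    "estimate_band_power",
    "compute_measurement",
]

#: minimum segment length for a valid measurement (the device records 2 min)
MIN_DURATION_S = 120.0
#: physiologically plausible interbeat-interval range, ms
IBI_RANGE_MS = (300.0, 2000.0)
#: relative deviation from the running median that marks an artifact
ARTIFACT_REL_TOL = 0.20
#: fraction of corrected beats above which the segment is unusable
MAX_CORRECTED_FRACTION = 0.20
#: HF power (ms^2) below which the LF/HF ratio is not computed
HF_POWER_FLOOR = 1e-6


@dataclass(frozen=True)
class IBISegment:
    """An ordered interbeat-interval sequence (ms) with its start time."""

    intervals: np.ndarray
    start_time: datetime | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "intervals", np.asarray(self.intervals, dtype=float))
        if self.intervals.ndim != 1 or self.intervals.size == 0:
            raise ValueError("intervals must be a non-empty 1-D sequence")
        if np.any(self.intervals <= 0):
            raise ValueError("all interbeat intervals must be positive")

    @property
    def duration_s(self) -> float:
        return float(self.intervals.sum() / 1000.0)

    @property
    def mean_interval_ms(self) -> float:
        return float(self.intervals.mean())


@dataclass(frozen=True)
class SpectralBands:
    """LF/HF band edges in Hz.

    The defaults use a half-open split at 0.15 Hz so the bands partition the
    spectrum; the overlapping band pair sometimes printed in the HRV
    literature (LF up to 0.15, HF from 0.14) double-counts power around the
    split and is available via :meth:`overlapping`.
    """

    lf_band: tuple[float, float] = (0.05, 0.15)
    hf_band: tuple[float, float] = (0.15, 0.40)

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("lf_band", self.lf_band), ("hf_band", self.hf_band)):
            if not 0.0 < lo < hi:
                raise ConfigurationError(f"{name} must satisfy 0 < lo < hi, got ({lo}, {hi})")

    @classmethod
    def overlapping(cls) -> "SpectralBands":
        """Band pair with the literal 0.14-0.40 Hz HF band (overlaps LF)."""
        return cls(lf_band=(0.05, 0.15), hf_band=(0.14, 0.40))


@dataclass(frozen=True)
class MeasurementRecord:
    """One timed HRV observation."""

    timestamp: datetime | None
    hr: float
    lf: float
    hf: float
    lfhf: float  # NaN when invalid
    phase: str = "unassigned"
    valid: bool = True


@dataclass(frozen=True)
class CleanResult:
    segment: IBISegment
    n_corrected: int
    valid: bool


def clean_ibi(segment: IBISegment, median_window: int = 11) -> CleanResult:
    """Remove and interpolate artifactual beats.

    Intervals outside the physiological range or deviating more than 20%
    from a running median are replaced by linear interpolation over beat
    index.  If more than 20% of beats need correction the segment is
    flagged invalid (e.g. poor PPG contact).
    """
    iv = segment.intervals.copy()
    n = iv.size
    if n < 3:
        return CleanResult(segment, 0, False)
    half = max(1, median_window // 2)
    running_med = np.array(
        [np.median(iv[max(0, i - half): min(n, i + half + 1)]) for i in range(n)]
    )
    bad = (
        (iv < IBI_RANGE_MS[0])
        | (iv > IBI_RANGE_MS[1])
        | (np.abs(iv - running_med) > ARTIFACT_REL_TOL * running_med)
    )
    n_corrected = int(bad.sum())
    if n_corrected:
        idx = np.arange(n)
        good = ~bad
        if good.sum() >= 2:
            iv[bad] = np.interp(idx[bad], idx[good], iv[good])
        else:  # nothing to interpolate from
            return CleanResult(segment, n_corrected, False)
    valid = n_corrected <= MAX_CORRECTED_FRACTION * n
    return CleanResult(replace(segment, intervals=iv), n_corrected, valid)


def _tachogram(segment: IBISegment) -> tuple[np.ndarray, np.ndarray]:
    """Detrended fluctuation series and its nominal time axis (s).

    The time axis is beat index times the mean interval: frequencies are
    then expressed per unit of mean heart period, the convention under
    which the LF/HF ratio is exactly scale-invariant.  The mean is
    quantized to 1e-6 ms so that float noise in the mean cannot move
    frequency-grid points across a band edge.
    """
    y = segment.intervals
    t = np.arange(y.size) * round(float(y.mean()), 6) / 1000.0
    trend = np.polyval(np.polyfit(t, y, 1), t)
    return t, y - trend


def _band_mask(f: np.ndarray, band: tuple[float, float], closed_hi: bool) -> np.ndarray:
    lo, hi = band
    return (f >= lo) & ((f <= hi) if closed_hi else (f < hi))


def estimate_band_power(
    segment: IBISegment,
    bands: SpectralBands | None = None,
    method: str = "lombscargle",
) -> tuple[float, float]:
    """Integrate the tachogram power spectrum over the LF and HF bands.

    Returns ``(lf, hf)`` in ms^2.  A zero-variance (constant) segment
    yields ``(0.0, 0.0)``; the caller flags the measurement invalid.
    """
    bands = bands or SpectralBands()
    if segment.duration_s < MIN_DURATION_S:
        raise ValueError(
            f"segment too short: {segment.duration_s:.1f} s < {MIN_DURATION_S:.0f} s"
        )
    t, y = _tachogram(segment)
    var = float(y.var())
    if var < 1e-12:
        return 0.0, 0.0

    if method == "lombscargle":
        dur = t[-1] - t[0]
        nyquist = 0.5 / (round(segment.mean_interval_ms, 6) / 1000.0)
        df = 1.0 / (4.0 * dur)  # 4x oversampled grid
        f = np.arange(df, min(0.5, nyquist), df)
        p = lombscargle(t, y, 2.0 * np.pi * f)
    elif method == "resample":
        fs = 4.0
        grid = np.arange(t[0], t[-1], 1.0 / fs)
        yg = CubicSpline(t, y)(grid)
        f, p = periodogram(yg, fs=fs, window="hann", detrend="linear")
        keep = (f > 0) & (f <= 0.5)
        f, p = f[keep], p[keep]
    else:
        raise ConfigurationError(f"unknown spectral method: {method!r}")

    total = float(p.sum())
    if total <= 0:
        return 0.0, 0.0
    # normalise so the full-grid integral equals the series variance
    lf = var * float(p[_band_mask(f, bands.lf_band, closed_hi=False)].sum()) / total
    hf = var * float(p[_band_mask(f, bands.hf_band, closed_hi=True)].sum()) / total
    return lf, hf


def compute_measurement(
    segment: IBISegment,
    bands: SpectralBands | None = None,
    method: str = "lombscargle",
    timestamp: datetime | None = None,
) -> MeasurementRecord:
    """Full per-segment pipeline: artifact cleaning, HR, band powers, LF/HF.

    HR is 60000 divided by the mean cleaned interval (ms).  The record is
    flagged invalid when cleaning corrected too many beats or when HF power
    falls below the floor (the ratio would be numerically meaningless).
    """
    cleaned = clean_ibi(segment)
    seg = cleaned.segment
    hr = 60000.0 / seg.mean_interval_ms
    lf, hf = estimate_band_power(seg, bands, method=method)
    valid = cleaned.valid and hf > HF_POWER_FLOOR
    lfhf = lf / hf if valid else float("nan")
    return MeasurementRecord(
        timestamp=timestamp or segment.start_time,
        hr=hr,
        lf=lf,
        hf=hf,
        lfhf=lfhf,
        valid=valid,
    )
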