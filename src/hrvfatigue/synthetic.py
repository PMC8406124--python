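"""Synthetic wearable-HRV streams for patients with a known fatigue level.

The generator emulates the measurement protocol of a timed wrist-worn PPG
device: one 2-minute HRV measurement per hour for several consecutive days,
split into a nightly sleep phase (10 hourly slots, 22:00-08:00 by default)
and a daytime active phase (14 hourly slots).  Each patient carries a
ground-truth fatigue level (a 0-10 Brief Fatigue Inventory score) that
jointly raises the probability of sympathetic-dominant sleep measurements
(LF-HF ratio > 1) and the mean sleep-phase LF-HF ratio, mirroring what is
observed clinically in fatigued oncology patients.

Sleep-slot LF-HF ratios are drawn from a log-normal family conditioned on a
per-slot Bernoulli "disorder" indicator, so that the exceedance probability
P(LF-HF > 1) equals the profile's ``sleep_disorder_prob`` exactly and the
marginal mean equals ``mean_sleep_lfhf`` (accounting for REM bursts, see
:func:`generate_measurements`).  Nights follow a hypnogram of 90-120 minute
non-REM/REM cycles; disordered measurements falling in REM are amplified
into the bursts seen on real traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta, timezone

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .errors import ConfigurationError
from .spectral import IBISegment

__all__ = [
    "PatientProfile",
    "SimulationConfig",
    "Hypnogram",
    "make_profile",
    "generate_hypnogram",
    "generate_measurements",
    "generate_ibi_segment",
]

#: Sleep-stage labels; a cycle walks down and back up the non-REM ladder
#: and ends in REM.
NREM_STAGES = ("NREM1", "NREM2", "NREM3", "NREM4", "NREM3", "NREM2", "NREM1")
REM = "REM"

#: Timezone used for simulated timestamps (the study cohort's locale).
TZ = timezone(timedelta(hours=8))


@dataclass(frozen=True)
class PatientProfile:
    """Generative parameters for one simulated patient.

    Attributes
    ----------
    true_bfi : float
        Ground-truth Brief Fatigue Inventory score in [0, 10].
    sleep_disorder_prob : float
        Per sleep-slot probability that LF-HF > 1.
    active_rest_prob : float
        Per active-slot probability of a daytime rest event
        (LF-HF < 1 together with a lowered heart rate).
    mean_sleep_lfhf : float
        Target marginal mean of the sleep-phase LF-HF ratio.
    lfhf_dispersion : float
        Log-scale standard deviation of the LF-HF draws.
    base_hr : float
        Resting-baseline heart rate in beats/min.
    """

    patient_id: str
    true_bfi: float
    sleep_disorder_prob: float
    active_rest_prob: float
    mean_sleep_lfhf: float
    lfhf_dispersion: float
    base_hr: float
    seed: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_bfi <= 10.0:
            raise ValueError(f"true_bfi must be in [0, 10], got {self.true_bfi}")
        for name in ("sleep_disorder_prob", "active_rest_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")
        if self.mean_sleep_lfhf <= 0:
            raise ValueError("mean_sleep_lfhf must be positive")
        if self.lfhf_dispersion <= 0:
            raise ValueError("lfhf_dispersion must be positive")
        if not 30.0 <= self.base_hr <= 200.0:
            raise ValueError(f"base_hr must be in [30, 200], got {self.base_hr}")


@dataclass(frozen=True)
class SimulationConfig:
    """Measurement-protocol and sleep-architecture settings.

    Defaults encode the study protocol: 7 days of hourly 2-minute
    measurements, a 22:00-08:00 sleep window (10 hourly slots/night) and
    14 active slots/day.
    """

    n_days: int = 7
    measurement_interval_min: int = 60
    measurement_duration_min: int = 2
    sleep_start: time = time(22, 0)
    sleep_end: time = time(8, 0)
    cycle_length_range: tuple[float, float] = (90.0, 120.0)
    rem_fraction: float = 0.2
    rem_burst_multiplier: float = 3.0
    active_mean_lfhf: float = 2.0
    start_date: date = date(2024, 1, 1)

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ConfigurationError("n_days must be >= 1")
        if self.measurement_interval_min <= 0:
            raise ConfigurationError("measurement_interval_min must be > 0")
        lo, hi = self.cycle_length_range
        if not (0 < lo <= hi):
            raise ConfigurationError("cycle_length_range must satisfy 0 < lo <= hi")
        if not 0.0 < self.rem_fraction < 1.0:
            raise ConfigurationError("rem_fraction must be in (0, 1)")
        if self.rem_burst_multiplier < 1.0:
            raise ConfigurationError("rem_burst_multiplier must be >= 1")

    @property
    def sleep_window_min(self) -> float:
        """Length of the sleep window in minutes (wraps midnight)."""
        start = self.sleep_start.hour * 60 + self.sleep_start.minute
        end = self.sleep_end.hour * 60 + self.sleep_end.minute
        return float((end - start) % (24 * 60) or 24 * 60)

    @property
    def sleep_slots_per_day(self) -> int:
        return int(self.sleep_window_min // self.measurement_interval_min)

    @property
    def active_slots_per_day(self) -> int:
        total = int(24 * 60 // self.measurement_interval_min)
        return total - self.sleep_slots_per_day


@dataclass(frozen=True)
class Hypnogram:
    """One night's sleep-stage sequence tiling the sleep window.

    ``stages`` holds (start_minute, duration_minute, stage) triples measured
    from sleep onset; they tile [0, window) without gaps or overlaps.
    """

    stages: tuple[tuple[float, float, str], ...]
    n_complete_cycles: int

    def stage_at(self, minute: float) -> str:
        """Sleep stage at ``minute`` after sleep onset."""
        for start, dur, stage in self.stages:
            if start <= minute < start + dur:
                return stage
        # the window end is half-open; clamp queries at the boundary
        return self.stages[-1][2]

    @property
    def total_minutes(self) -> float:
        return sum(d for _, d, _ in self.stages)


# ---------------------------------------------------------------------------
# Profile calibration
# ---------------------------------------------------------------------------

# Linear anchors chosen so that a BFI-0 patient lands in the low-fatigue
# band (sleep disorder 0-25%, mean sleep LF-HF <= 1.15) and a BFI ~5.7
# patient in the high band (disorder ~0.9, mean LF-HF ~3.2), reproducing
# the spread observed across the study cohort.
_DISORDER_INTERCEPT, _DISORDER_SLOPE = 0.125, 0.137
_LFHF_INTERCEPT, _LFHF_SLOPE = 0.95, 0.40
_REST_INTERCEPT, _REST_SLOPE = 0.35, -0.03


def make_profile(true_bfi: float, seed: int, patient_id: str | None = None) -> PatientProfile:
    """Build a patient profile from a ground-truth fatigue level.

    The calibration is monotone: for a fixed seed both
    ``sleep_disorder_prob`` and ``mean_sleep_lfhf`` are non-decreasing in
    ``true_bfi``, while ``active_rest_prob`` is non-increasing (fatigued
    patients rest less effectively during the day).  The seed adds a
    patient-level jitter so cohorts are heterogeneous yet reproducible.
    """
    if not 0.0 <= true_bfi <= 10.0:
        raise ValueError(f"true_bfi must be in [0, 10], got {true_bfi}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x9E37]))
    j_dis = rng.uniform(-0.10, 0.10)
    j_lfhf = rng.uniform(-0.15, 0.15)
    j_rest = rng.uniform(-0.18, 0.18)
    j_hr = rng.uniform(-6.0, 6.0)
    return PatientProfile(
        patient_id=patient_id or f"SIM{seed:04d}",
        true_bfi=float(true_bfi),
        sleep_disorder_prob=float(
            np.clip(_DISORDER_INTERCEPT + _DISORDER_SLOPE * true_bfi + j_dis, 0.01, 0.95)
        ),
        active_rest_prob=float(
            np.clip(_REST_INTERCEPT + _REST_SLOPE * true_bfi + j_rest, 0.01, 0.90)
        ),
        mean_sleep_lfhf=float(
            np.clip(_LFHF_INTERCEPT + _LFHF_SLOPE * true_bfi + j_lfhf, 0.30, 8.0)
        ),
        lfhf_dispersion=0.5,
        base_hr=float(70.0 + j_hr),
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# Hypnogram
# ---------------------------------------------------------------------------

def generate_hypnogram(config: SimulationConfig, seed: int) -> Hypnogram:
    """Simulate one night of sleep architecture.

    Cycles are drawn uniformly from ``config.cycle_length_range`` minutes;
    each walks the non-REM ladder 1-2-3-4-3-2-1 (equal shares of the
    non-REM portion) and ends in REM occupying ``rem_fraction`` of the
    cycle.  The final cycle is truncated at the window end so the stages
    tile the window exactly.
    """
    window = config.sleep_window_min
    lo, hi = config.cycle_length_range
    if window < lo:
        raise ConfigurationError(
            f"sleep window ({window:g} min) is shorter than one cycle ({lo:g} min)"
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x48F1]))
    stages: list[tuple[float, float, str]] = []
    t = 0.0
    n_complete = 0
    while t < window - 1e-9:
        cycle_len = float(rng.uniform(lo, hi))
        nrem_each = cycle_len * (1.0 - config.rem_fraction) / len(NREM_STAGES)
        plan = [(s, nrem_each) for s in NREM_STAGES] + [(REM, cycle_len * config.rem_fraction)]
        truncated = False
        for stage, dur in plan:
            if t >= window - 1e-9:
                truncated = True
                break
            d = min(dur, window - t)
            if d < dur - 1e-9:
                truncated = True
            stages.append((t, d, stage))
            t += d
        if not truncated:
            n_complete += 1
    return Hypnogram(stages=tuple(stages), n_complete_cycles=n_complete)


# ---------------------------------------------------------------------------
# Conditional log-normal machinery for LF-HF draws
# ---------------------------------------------------------------------------

def _truncated_means(mu: float, sigma: float) -> tuple[float, float]:
    """(E[X | X <= 1], E[X | X > 1]) for X ~ LogNormal(mu, sigma)."""
    z = -mu / sigma
    full = mu + 0.5 * sigma**2
    # log-space ratios keep the tails stable for extreme locations
    e_le = np.exp(full + norm.logcdf(z - sigma) - norm.logcdf(z))
    e_gt = np.exp(full + norm.logcdf(-z + sigma) - norm.logcdf(-z))
    return float(e_le), float(e_gt)


def solve_lfhf_location(
    sigma: float, p_exceed: float, target_mean: float, burst_factor: float = 1.0
) -> float:
    """Log-normal location making the marginal LF-HF mean hit its target.

    Slot values are drawn from LogNormal(mu, sigma) conditioned above or
    below 1 according to a Bernoulli(``p_exceed``) indicator; above-1 draws
    are further multiplied by ``burst_factor`` on average (REM bursts).
    The marginal mean is then

        (1 - p) E[X | X <= 1] + p * burst_factor * E[X | X > 1]

    which is strictly increasing in mu; this solves it for ``target_mean``.
    """
    if not 0.0 <= p_exceed <= 1.0:
        raise ValueError("p_exceed must be a probability")
    floor = p_exceed * burst_factor  # E[X | X > 1] >= 1
    if target_mean <= floor:
        raise ConfigurationError(
            f"target mean {target_mean:g} unreachable: exceedance {p_exceed:g} with "
            f"burst factor {burst_factor:g} forces a mean > {floor:g}"
        )
    if p_exceed == 0.0 and target_mean >= 1.0:
        raise ConfigurationError(
            "with exceedance 0 every draw lies below 1, so the mean must be < 1"
        )

    def gap(mu: float) -> float:
        e_le, e_gt = _truncated_means(mu, sigma)
        return (1.0 - p_exceed) * e_le + p_exceed * burst_factor * e_gt - target_mean

    lo, hi = -40.0, 10.0
    while gap(hi) < 0:
        hi += 10.0
        if hi > 200:  # pragma: no cover - unreachable for valid inputs
            raise ConfigurationError("failed to bracket LF-HF location")
    return float(brentq(gap, lo, hi, xtol=1e-12))


def _draw_conditional(
    rng: np.random.Generator, mu: float, sigma: float, above: bool
) -> float:
    """Inverse-CDF draw from LogNormal(mu, sigma) truncated at 1."""
    p_le = norm.cdf(-mu / sigma)
    if above:
        u = rng.uniform(p_le, 1.0)
    else:
        u = rng.uniform(0.0, p_le)
    # clip away from 0/1 to keep ppf finite
    u = min(max(u, 1e-15), 1.0 - 1e-15)
    return float(np.exp(mu + sigma * norm.ppf(u)))


# ---------------------------------------------------------------------------
# Measurement stream
# ---------------------------------------------------------------------------

#: Total spectral power (ms^2) used to decompose a ratio into LF and HF.
_SLEEP_TOTAL_POWER = 800.0
_ACTIVE_TOTAL_POWER = 1500.0


def _powers_from_ratio(ratio: float, total: float) -> tuple[float, float]:
    hf = total / (1.0 + ratio)
    return total - hf, hf


def _sleep_hr(base_hr: float, frac_of_night: float) -> float:
    # gradual decline to a nadir at 60% of the night, then a pre-wake rise
    if frac_of_night < 0.6:
        return base_hr - 5.0 - 10.0 * (frac_of_night / 0.6)
    return base_hr - 15.0 + 10.0 * ((frac_of_night - 0.6) / 0.4)


def generate_measurements(
    profile: PatientProfile, config: SimulationConfig | None = None
):
    """Simulate the full multi-day stream of hourly HRV measurements.

    Returns a :class:`pandas.DataFrame` in the measurement schema
    (``patient_id, timestamp, hr, lf, hf, lfhf, phase, valid``), one row per
    hourly slot, phases labelled by construction (and consistent with
    timestamp-based segmentation).

    Sleep slots: a Bernoulli(``sleep_disorder_prob``) indicator decides
    whether LF-HF exceeds 1; values are truncated log-normal draws with the
    location solved so the marginal mean equals ``mean_sleep_lfhf``.
    Disordered draws whose slot midpoint falls in REM are multiplied by
    ``rem_burst_multiplier`` (the bursts visible on real nocturnal traces);
    the location solve accounts for the expected REM fraction so the mean
    stays on target.  Active slots: rest events (LF-HF < 1 with lowered HR)
    occur with probability ``active_rest_prob``; other active slots sit
    above 1 around ``active_mean_lfhf``.
    """
    import pandas as pd

    cfg = config or SimulationConfig()
    n_sleep = cfg.sleep_slots_per_day
    n_active = cfg.active_slots_per_day

    ss = np.random.SeedSequence([int(profile.seed), 0xC0FE])
    children = ss.spawn(2 + cfg.n_days)
    rng_sleep = np.random.default_rng(children[0])
    rng_active = np.random.default_rng(children[1])
    night_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in children[2:]]

    first = datetime.combine(cfg.start_date, cfg.sleep_start, TZ)
    step = timedelta(minutes=cfg.measurement_interval_min)
    window = cfg.sleep_window_min

    # Hypnograms first: the burst factor in the location solve uses the
    # realized fraction of slot midpoints falling in REM (window truncation
    # cuts REM, so the nominal rem_fraction would bias the mean upward).
    hyps = [generate_hypnogram(cfg, seed=night_seeds[d]) for d in range(cfg.n_days)]
    offsets = [
        slot * cfg.measurement_interval_min + cfg.measurement_duration_min / 2
        for slot in range(n_sleep)
    ]
    rem_slot = [
        [hyp.stage_at(min(off, window - 1e-6)) == REM for off in offsets] for hyp in hyps
    ]
    rem_frac = float(np.mean(rem_slot)) if n_sleep else 0.0

    burst = 1.0 + rem_frac * (cfg.rem_burst_multiplier - 1.0)
    mu_sleep = solve_lfhf_location(
        profile.lfhf_dispersion,
        profile.sleep_disorder_prob,
        profile.mean_sleep_lfhf,
        burst_factor=burst,
    )
    mu_active = solve_lfhf_location(
        profile.lfhf_dispersion,
        1.0 - profile.active_rest_prob,  # active "order" is LF-HF > 1
        cfg.active_mean_lfhf,
    )

    rows = []
    for day in range(cfg.n_days):
        night_start = first + timedelta(days=day)
        for slot in range(n_sleep):
            ts = night_start + slot * step
            disordered = rng_sleep.uniform() < profile.sleep_disorder_prob
            ratio = _draw_conditional(rng_sleep, mu_sleep, profile.lfhf_dispersion, disordered)
            if disordered and rem_slot[day][slot]:
                ratio *= cfg.rem_burst_multiplier
            hr = _sleep_hr(profile.base_hr, offsets[slot] / window) + rng_sleep.normal(0.0, 2.0)
            lf, hf = _powers_from_ratio(ratio, _SLEEP_TOTAL_POWER)
            rows.append((profile.patient_id, ts, hr, lf, hf, ratio, "sleep", True))
        for slot in range(n_active):
            ts = night_start + (n_sleep + slot) * step
            resting = rng_active.uniform() < profile.active_rest_prob
            ratio = _draw_conditional(rng_active, mu_active, profile.lfhf_dispersion, not resting)
            if resting:
                hr = profile.base_hr - 10.0 + rng_active.normal(0.0, 2.0)
            else:
                hr = profile.base_hr + 5.0 + rng_active.normal(0.0, 4.0)
            lf, hf = _powers_from_ratio(ratio, _ACTIVE_TOTAL_POWER)
            rows.append((profile.patient_id, ts, hr, lf, hf, ratio, "active", True))

    return pd.DataFrame(
        rows,
        columns=["patient_id", "timestamp", "hr", "lf", "hf", "lfhf", "phase", "valid"],
    )


# ---------------------------------------------------------------------------
# Raw interbeat-interval synthesis (ground truth for the spectral module)
# ---------------------------------------------------------------------------

def generate_ibi_segment(
    target_lf: float,
    target_hf: float,
    mean_hr: float,
    duration_s: float = 120.0,
    seed: int = 0,
    noise_frac: float = 0.05,
    start_time: datetime | None = None,
) -> IBISegment:
    """Synthesize a 2-minute interbeat-interval segment with known band powers.

    The interval series is the mean interval (60000 / ``mean_hr`` ms) plus
    two band-limited sinusoidal modulations centred at 0.1 Hz (LF) and
    0.25 Hz (HF) whose variances equal ``target_lf`` and ``target_hf``
    (ms^2), plus white noise with standard deviation
    ``noise_frac * sqrt(target_lf + target_hf)``.  Fluctuations are centred
    so the mean interval is exact.
    """
    if duration_s < 120.0:
        raise ValueError("duration_s must be >= 120 (one full measurement window)")
    if target_lf < 0 or target_hf < 0:
        raise ValueError("band-power targets must be non-negative")
    if not 30.0 <= mean_hr <= 200.0:
        raise ValueError(f"mean_hr must be in [30, 200], got {mean_hr}")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x1B1]))
    mean_ms = 60000.0 / mean_hr
    n = int(np.ceil(duration_s * 1000.0 / mean_ms)) + 1
    t = np.arange(n) * mean_ms / 1000.0  # seconds, nominal beat times

    amp_lf = np.sqrt(2.0 * target_lf)
    amp_hf = np.sqrt(2.0 * target_hf)
    ph_lf, ph_hf = rng.uniform(0.0, 2.0 * np.pi, size=2)
    noise_sd = noise_frac * np.sqrt(target_lf + target_hf)
    fluct = (
        amp_lf * np.sin(2.0 * np.pi * 0.10 * t + ph_lf)
        + amp_hf * np.sin(2.0 * np.pi * 0.25 * t + ph_hf)
        + rng.normal(0.0, noise_sd, size=n)
    )
    fluct -= fluct.mean()
    intervals = mean_ms + fluct
    if np.any(intervals <= 0):
        raise ConfigurationError(
            "band-power targets too large for the mean interval (non-positive IBI)"
        )
    return IBISegment(
        intervals=intervals,
        start_time=start_time or datetime.combine(date(2024, 1, 1), time(12, 0), TZ),
    )
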