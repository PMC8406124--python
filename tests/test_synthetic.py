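"""Synthetic cohort generator: calibration, hypnograms, determinism."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st

import hrvfatigue as hf
from hrvfatigue.errors import ConfigurationError
from hrvfatigue.synthetic import NREM_STAGES, REM, solve_lfhf_location


class TestMakeProfile:
    def test_no_fatigue_profile_sits_in_low_band(self):
        p = hf.make_profile(0.0, seed=1)
        assert p.sleep_disorder_prob <= 0.25
        assert p.mean_sleep_lfhf <= 1.15

    def test_high_fatigue_profile_matches_severe_band(self):
        p = hf.make_profile(5.67, seed=1)
        assert p.sleep_disorder_prob == pytest.approx(0.9, abs=0.12)
        assert p.mean_sleep_lfhf == pytest.approx(3.2, abs=0.25)

    def test_same_seed_same_profile(self):
        assert hf.make_profile(2.0, seed=7) == hf.make_profile(2.0, seed=7)

    def test_different_seeds_differ(self):
        assert hf.make_profile(2.0, seed=7) != hf.make_profile(2.0, seed=8)

    @given(st.floats(min_value=0, max_value=10), st.floats(min_value=0, max_value=10))
    def test_calibration_monotone_in_fatigue(self, b1, b2):
        lo, hi = sorted([b1, b2])
        p_lo, p_hi = hf.make_profile(lo, seed=11), hf.make_profile(hi, seed=11)
        assert p_lo.sleep_disorder_prob <= p_hi.sleep_disorder_prob
        assert p_lo.mean_sleep_lfhf <= p_hi.mean_sleep_lfhf

    @pytest.mark.parametrize("bad", [-0.1, 10.5])
    def test_out_of_range_bfi_rejected(self, bad):
        with pytest.raises(ValueError):
            hf.make_profile(bad, seed=0)


class TestHypnogram:
    def test_ten_hour_window_gives_five_or_six_cycles(self):
        # 600 min window, cycles in [90, 120]: floor(600/120)=5, 600/90 -> 6 max
        for seed in range(30):
            hyp = hf.generate_hypnogram(hf.SimulationConfig(), seed=seed)
            assert hyp.n_complete_cycles in (5, 6)

    def test_stages_tile_window_without_gaps(self):
        hyp = hf.generate_hypnogram(hf.SimulationConfig(), seed=2)
        t = 0.0
        for start, dur, _ in hyp.stages:
            assert start == pytest.approx(t)
            assert dur > 0
            t += dur
        assert t == pytest.approx(600.0)

    def test_cycle_grammar_descends_and_ascends_nrem_then_rem(self):
        hyp = hf.generate_hypnogram(hf.SimulationConfig(), seed=5)
        labels = [s for _, _, s in hyp.stages]
        cycle = list(NREM_STAGES) + [REM]
        for i in range(hyp.n_complete_cycles):
            assert labels[i * 8:(i + 1) * 8] == cycle

    def test_exact_fit_single_cycle(self):
        from datetime import time
        cfg = hf.SimulationConfig(sleep_start=time(22, 0), sleep_end=time(23, 30),
                                  cycle_length_range=(90.0, 90.0))
        hyp = hf.generate_hypnogram(cfg, seed=1)
        assert hyp.n_complete_cycles == 1
        assert hyp.total_minutes == pytest.approx(90.0)

    def test_window_shorter_than_cycle_rejected(self):
        from datetime import time
        cfg = hf.SimulationConfig(sleep_start=time(23, 0), sleep_end=time(0, 0))
        with pytest.raises(ConfigurationError):
            hf.generate_hypnogram(cfg, seed=0)

    def test_same_seed_identical(self):
        cfg = hf.SimulationConfig()
        assert hf.generate_hypnogram(cfg, 9) == hf.generate_hypnogram(cfg, 9)


class TestLfhfLocationSolve:
    @pytest.mark.parametrize(
        "p,m,rem_frac,mult", [(0.25, 1.1, 0.2, 3.0), (0.9, 3.2, 0.2, 3.0), (0.5, 1.5, 0.0, 1.0)]
    )
    def test_marginal_mean_and_exceedance_hit_targets(self, p, m, rem_frac, mult):
        # Monte-Carlo check of the analytic location solve: disorder
        # indicator Bernoulli(p); above-1 draws hit a REM burst (x mult)
        # with probability rem_frac.
        from hrvfatigue.synthetic import _draw_conditional
        sigma = 0.5
        burst = 1.0 + rem_frac * (mult - 1.0)
        mu = solve_lfhf_location(sigma, p, m, burst_factor=burst)
        rng = np.random.default_rng(0)
        n = 100_000
        above = rng.uniform(size=n) < p
        draws = np.array([_draw_conditional(rng, mu, sigma, a) for a in above])
        in_rem = rng.uniform(size=n) < rem_frac
        draws[above & in_rem] *= mult
        assert (draws > 1).mean() == pytest.approx(p, abs=3 * np.sqrt(p * (1 - p) / n) + 1e-12)
        assert draws.mean() == pytest.approx(m, abs=3 * draws.std() / np.sqrt(n))

    def test_unreachable_mean_rejected(self):
        with pytest.raises(ConfigurationError):
            solve_lfhf_location(0.5, 0.9, 0.8)  # mean below the exceedance floor

    def test_zero_exceedance_needs_submean_one(self):
        with pytest.raises(ConfigurationError):
            solve_lfhf_location(0.5, 0.0, 1.2)


class TestGenerateMeasurements:
    def test_default_protocol_counts(self, sim_stream):
        assert len(sim_stream) == 168
        counts = sim_stream["phase"].value_counts()
        assert counts["sleep"] == 70 and counts["active"] == 98

    def test_same_seed_byte_identical(self, sim_profile, sim_stream):
        again = hf.generate_measurements(sim_profile)
        assert again.equals(sim_stream)

    def test_different_seed_differs(self, sim_profile, sim_stream):
        other = hf.generate_measurements(dataclasses.replace(sim_profile, seed=99))
        assert not other["lfhf"].equals(sim_stream["lfhf"])

    def test_zero_disorder_probability_never_exceeds_one(self, sim_profile):
        p0 = dataclasses.replace(sim_profile, sleep_disorder_prob=0.0, mean_sleep_lfhf=0.8)
        df = hf.generate_measurements(p0)
        assert (df.loc[df["phase"] == "sleep", "lfhf"] <= 1).all()

    def test_disorder_fraction_binomially_consistent(self):
        # p=0.4, 70 slots: fraction within 3 binomial SE for an overwhelming
        # share of seeds
        p_target, se = 0.4, np.sqrt(0.4 * 0.6 / 70)
        hits = 0
        for seed in range(40):
            prof = dataclasses.replace(
                hf.make_profile(2.0, seed=seed), sleep_disorder_prob=p_target
            )
            df = hf.generate_measurements(prof)
            frac = (df.loc[df["phase"] == "sleep", "lfhf"] > 1).mean()
            hits += abs(frac - p_target) <= 3 * se
        assert hits >= 38

    def test_sleep_mean_lfhf_on_target(self):
        devs = []
        for seed in range(25):
            prof = hf.make_profile(4.0, seed=seed)
            df = hf.generate_measurements(prof)
            devs.append(df.loc[df["phase"] == "sleep", "lfhf"].mean() - prof.mean_sleep_lfhf)
        # per-seed noise cancels; the generator is unbiased
        assert abs(np.mean(devs)) < 0.15

    def test_active_hr_exceeds_sleep_hr(self, sim_stream):
        by_phase = sim_stream.groupby("phase")["hr"].mean()
        assert by_phase["active"] > by_phase["sleep"]


class TestGenerateIbiSegment:
    def test_mean_interval_is_exact(self):
        seg = hf.generate_ibi_segment(2.0, 1.0, mean_hr=60, seed=1)
        assert seg.mean_interval_ms == pytest.approx(1000.0)

    def test_equal_band_targets_give_unit_ratio(self):
        ratios = []
        for seed in range(20):
            seg = hf.generate_ibi_segment(3.0, 3.0, mean_hr=65, seed=seed)
            lf, hfp = hf.estimate_band_power(seg)
            ratios.append(lf / hfp)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.1)

    def test_too_short_duration_rejected(self):
        with pytest.raises(ValueError):
            hf.generate_ibi_segment(1.0, 1.0, mean_hr=60, duration_s=60)

    def test_negative_target_rejected(self):
        with pytest.raises(ValueError):
            hf.generate_ibi_segment(-1.0, 1.0, mean_hr=60)
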