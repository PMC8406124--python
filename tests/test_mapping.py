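"""BFI mapping: OLS weights, grouping, compensation, clipping."""

import numpy as np
import pytest

import hrvfatigue as hf
from hrvfatigue.features import FatigueFeatures
from hrvfatigue.mapping import FatigueGroup


def _feat(x1, x2, x3, pid="T"):
    return FatigueFeatures(
        patient_id=pid, sleep_count=x1 * 10, sleep_disorder_ratio=x1,
        mean_sleep_lfhf=x2, sd_sleep_lfhf=0.1, active_count=x3 * 14,
        active_disorder_ratio=x3, per_night_counts=(), per_day_counts=(), n_days=7,
    )


def _synthetic_cohort(rng, n=12):
    feats = [
        _feat(rng.uniform(0, 1), rng.uniform(0.5, 3.5), rng.uniform(0, 1), pid=f"S{i}")
        for i in range(n)
    ]
    return feats


class TestComputeMbfi:
    def test_printed_style_weights_on_severe_patient(self, study):
        # hand evaluation: 6.4*0.91 + 0.45*3.19 + 1.23*(1.9/14) - 2.07
        feats, _ = study
        p05 = next(f for f in feats if f.patient_id == "P05")
        w = hf.MappingWeights(6.4, 0.45, 1.23, -2.07)
        est = hf.compute_mbfi(p05, w)
        assert est.value == pytest.approx(5.3564, abs=1e-3)

    def test_negative_affine_clips_to_zero(self, study):
        feats, _ = study
        est = hf.compute_mbfi(feats[0], hf.MappingWeights(0, 0, 0, -1))
        assert est.value == 0.0 and est.unclipped == -1.0

    def test_zero_weights_map_to_zero(self, study):
        feats, _ = study
        assert hf.compute_mbfi(feats[0], hf.MappingWeights(0, 0, 0, 0)).value == 0.0

    def test_output_never_negative(self, study):
        feats, _ = study
        w = hf.MappingWeights(-5, -5, -5, 0)
        assert all(hf.compute_mbfi(f, w).value >= 0 for f in feats)


class TestFitWeights:
    def test_noise_free_linear_recovery(self):
        rng = np.random.default_rng(0)
        feats = _synthetic_cohort(rng)
        truth = np.array([2.0, 1.0, 0.5, 1.0])
        bfi = [2 * f.sleep_disorder_ratio + f.mean_sleep_lfhf
               + 0.5 * f.active_disorder_ratio + 1.0 for f in feats]
        w = hf.fit_weights(feats, bfi)
        np.testing.assert_allclose(w.vector, truth, atol=1e-8)
        assert w.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_constant_response_gives_zero_slopes_and_zero_r2(self):
        rng = np.random.default_rng(1)
        feats = _synthetic_cohort(rng)
        w = hf.fit_weights(feats, [2.0] * len(feats))
        assert np.allclose([w.alpha, w.beta, w.gamma], 0, atol=1e-10)
        assert w.epsilon == pytest.approx(2.0)
        assert w.r_squared == 0.0

    def test_residuals_orthogonal_to_features(self, study):
        # normal-equations check against the pseudo-inverse oracle
        feats, bfi = study
        w = hf.fit_weights(feats, bfi)
        x = np.column_stack([np.vstack([f.vector for f in feats]), np.ones(len(feats))])
        resid = np.asarray(bfi) - x @ np.r_[w.alpha, w.beta, w.gamma, w.epsilon]
        assert np.max(np.abs(x.T @ resid)) < 1e-8
        oracle = np.linalg.pinv(x) @ np.asarray(bfi)
        np.testing.assert_allclose(w.vector, oracle, atol=1e-8)

    def test_too_few_patients_rejected(self):
        rng = np.random.default_rng(2)
        feats = _synthetic_cohort(rng, n=4)
        with pytest.raises(ValueError, match=">= 5"):
            hf.fit_weights(feats, [1, 2, 3, 4])

    def test_singular_design_rejected(self):
        f = _feat(0.5, 1.0, 0.5)
        with pytest.raises(ValueError, match="singular"):
            hf.fit_weights([f] * 6, [1, 1, 1, 2, 2, 2])


class TestAssignGroup:
    @pytest.mark.parametrize(
        "bfi,group",
        [(0.0, FatigueGroup.A), (1.56, FatigueGroup.B), (2.5, FatigueGroup.B),
         (3.0, FatigueGroup.B), (3.01, FatigueGroup.C), (5.67, FatigueGroup.C)],
    )
    def test_cluster_rule(self, bfi, group):
        assert hf.assign_group(bfi) is group

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            hf.assign_group(-1.0)

    def test_severity_bands_label_the_cohort_notes(self, study):
        feats, bfi = study
        fixture = hf.load_fixture()
        for f, b in zip(feats, bfi):
            assert hf.severity_band(b) == fixture.row(f.patient_id)["note"]


class TestCompensation:
    def test_moderate_group_factor_from_hand_computation(self, study):
        # unit-weight MBFI for P08/P05 -> deltas {1.624, 1.434} -> CF ~ 1.529
        feats, bfi = study
        table = hf.compensation_factors(feats, bfi)
        assert table.factor(FatigueGroup.C) == pytest.approx(1.5293, abs=1e-3)
        assert table.counts[FatigueGroup.C] == 2

    def test_perfect_unit_mapping_gives_zero_factor(self):
        feats = [_feat(0.2, 1.0, 0.3), _feat(0.4, 1.2, 0.5)]
        bfi = [hf.unit_mbfi(f) for f in feats]
        table = hf.compensation_factors(feats, bfi)
        assert table.factor(hf.assign_group(bfi[0])) == pytest.approx(0.0, abs=1e-12)

    def test_single_member_group_factor_is_its_delta(self):
        feats = [_feat(0.8, 3.0, 0.2), _feat(0.1, 0.8, 0.3)]
        bfi = [5.0, 0.0]
        table = hf.compensation_factors(feats, bfi)
        assert table.factor(FatigueGroup.C) == pytest.approx(5.0 - hf.unit_mbfi(feats[0]))

    def test_group_mean_residual_zero_before_clipping(self, study):
        feats, bfi = study
        table, estimates = hf.map_cohort(feats, bfi)
        groups = np.array([hf.assign_group(b).value for b in bfi])
        resid = np.asarray(bfi) - np.array([e.unclipped for e in estimates])
        for g in "ABC":
            assert resid[groups == g].mean() == pytest.approx(0.0, abs=1e-12)

    def test_no_fatigue_patient_clipped_to_zero(self, study):
        # P03: unit MBFI ~ 1.05, CF_A ~ -1.46 -> negative, clipped
        feats, bfi = study
        table, estimates = hf.map_cohort(feats, bfi)
        p03 = next(e for f, e in zip(feats, estimates) if f.patient_id == "P03")
        assert p03.unclipped < 0 and p03.value == 0.0

    def test_zero_factor_identity(self):
        f = _feat(0.3, 1.5, 0.4)
        table = hf.CompensationTable(factors={FatigueGroup.B: 0.0}, counts={FatigueGroup.B: 1})
        est = hf.compensated_mbfi(f, table, FatigueGroup.B)
        assert est.value == pytest.approx(hf.unit_mbfi(f))

    def test_unknown_group_rejected(self):
        f = _feat(0.3, 1.5, 0.4)
        table = hf.CompensationTable(factors={FatigueGroup.B: 0.1}, counts={FatigueGroup.B: 1})
        with pytest.raises(KeyError):
            hf.compensated_mbfi(f, table, FatigueGroup.A)

    def test_moderate_group_estimates_close_to_reported_scores(self, study):
        feats, bfi = study
        _, estimates = hf.map_cohort(feats, bfi)
        for f, b, e in zip(feats, bfi, estimates):
            if hf.assign_group(b) is FatigueGroup.C:
                assert abs(e.value - b) <= 0.1
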