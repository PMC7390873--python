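"""Hazard conversions, hazard-ratio algebra and transition-matrix structure."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import hfcea as h
from hfcea.hazards import (
    ArmDynamics,
    HealthState,
    apply_hazard_ratio,
    background_mortality_monthly,
    build_transition_matrix,
    calibrate_weibull_lam,
    event_probabilities,
    monthly_prob_exponential,
    monthly_prob_weibull,
)
from hfcea.params import HazardModelSpec, with_parameter_values

from conftest import quiet_config

EXP_CV = HazardModelSpec(family="exponential", lam=-0.00577)
WEIBULL_HOSP = HazardModelSpec(family="weibull", lam=-0.00097, gamma_shape=1.02685)


class TestMonthlyProbExponential:
    def test_closed_form(self):
        assert monthly_prob_exponential(EXP_CV) == pytest.approx(
            1.0 - math.exp(-0.00577), abs=1e-12
        )
        assert monthly_prob_exponential(EXP_CV) == pytest.approx(0.0057534, abs=5e-8)

    def test_memoryless(self):
        assert monthly_prob_exponential(EXP_CV, cycle=1) == monthly_prob_exponential(
            EXP_CV, cycle=120
        )

    def test_small_rate_limit(self):
        tiny = HazardModelSpec(family="exponential", lam=-1e-12)
        assert monthly_prob_exponential(tiny) == pytest.approx(1e-12, rel=1e-3)

    def test_nonnegative_rate_rejected(self):
        with pytest.raises(ValueError):
            monthly_prob_exponential(HazardModelSpec(family="exponential", lam=0.001))


class TestMonthlyProbWeibull:
    def test_shape_one_reduces_to_exponential(self):
        wb = HazardModelSpec(family="weibull", lam=-0.00577, gamma_shape=1.0)
        for t in (1, 7, 120):
            assert monthly_prob_weibull(wb, t) == pytest.approx(
                monthly_prob_exponential(EXP_CV), abs=1e-15
            )

    def test_increasing_hazard_for_shape_above_one(self):
        probs = [monthly_prob_weibull(WEIBULL_HOSP, t) for t in range(1, 121)]
        assert all(b > a for a, b in zip(probs, probs[1:]))

    def test_cycle_below_one_rejected(self):
        with pytest.raises(ValueError):
            monthly_prob_weibull(WEIBULL_HOSP, 0)

    @pytest.mark.parametrize("anchor", [0.00868, 0.0145])
    def test_calibration_hits_window_mean(self, anchor):
        lam = calibrate_weibull_lam(1.02685, anchor)
        model = HazardModelSpec(family="weibull", lam=lam, gamma_shape=1.02685)
        mean_p = np.mean([monthly_prob_weibull(model, t) for t in range(1, 121)])
        assert mean_p == pytest.approx(anchor, abs=1e-10)

    def test_calibration_single_cycle_anchors_first_probability(self):
        lam = calibrate_weibull_lam(1.02685, 0.0145, n_cycles=1)
        model = HazardModelSpec(family="weibull", lam=lam, gamma_shape=1.02685)
        assert monthly_prob_weibull(model, 1) == pytest.approx(0.0145, abs=1e-10)


class TestApplyHazardRatio:
    def test_identity_and_zero(self):
        assert apply_hazard_ratio(0.42, 1.0) == pytest.approx(0.42, abs=1e-15)
        assert apply_hazard_ratio(0.0, 3.7) == 0.0

    def test_published_example(self):
        p = 1.0 - math.exp(-0.00577)
        assert apply_hazard_ratio(p, 0.80) == pytest.approx(0.00460536, abs=5e-9)

    @given(
        p=st.floats(min_value=0.0, max_value=0.99),
        hr=st.floats(min_value=0.01, max_value=5.0),
    )
    def test_matches_rate_scale_oracle(self, p, hr):
        # Independent oracle: scale the cumulative rate -ln(1-p) and map back.
        oracle = 1.0 - math.exp(hr * math.log(1.0 - p)) if p > 0 else 0.0
        assert apply_hazard_ratio(p, hr) == pytest.approx(oracle, abs=1e-12)

    @given(
        p=st.floats(min_value=1e-6, max_value=0.5),
        hr1=st.floats(min_value=0.1, max_value=2.0),
        hr2=st.floats(min_value=0.1, max_value=2.0),
    )
    def test_monotone_in_multiplier(self, p, hr1, hr2):
        lo, hi = sorted((hr1, hr2))
        assert apply_hazard_ratio(p, lo) <= apply_hazard_ratio(p, hi) + 1e-15

    def test_certain_event_rejected(self):
        with pytest.raises(ValueError):
            apply_hazard_ratio(1.0, 0.8)


class TestBackgroundMortality:
    def test_annual_to_monthly_conversion(self, cfg):
        monthly = background_mortality_monthly(cfg.mortality_table, 65.0)
        assert monthly == pytest.approx(1 - (1 - 0.0066972) ** (1 / 12), abs=1e-12)
        assert monthly == pytest.approx(0.00055982, abs=1e-8)

    def test_left_step_function(self, cfg):
        assert background_mortality_monthly(
            cfg.mortality_table, 67.5
        ) == background_mortality_monthly(cfg.mortality_table, 65.0)
        assert background_mortality_monthly(
            cfg.mortality_table, 64.0
        ) == pytest.approx(1 - (1 - 0.0028332) ** (1 / 12), abs=1e-12)

    def test_certain_death_at_100(self, cfg):
        assert background_mortality_monthly(cfg.mortality_table, 100.0) == 1.0
        assert background_mortality_monthly(cfg.mortality_table, 104.2) == 1.0

    def test_below_table_rejected(self, cfg):
        with pytest.raises(ValueError):
            background_mortality_monthly(cfg.mortality_table, 0.5)


class TestEventProbabilities:
    def test_comparator_baseline_values(self, cfg):
        ev = event_probabilities("enalapril", HealthState.NYHA_II, 1, cfg)
        assert ev.p_cv_death == pytest.approx(0.0057534, abs=1e-7)
        assert ev.p_nyha_change == 0.0088
        assert ev.p_readmit == 0.0147
        ev_s = event_probabilities("sacval", HealthState.NYHA_II, 1, cfg)
        assert ev_s.p_nyha_change == 0.0068

    def test_treatment_reduces_event_risk(self, cfg):
        for klass in range(4):
            e = event_probabilities("enalapril", klass, 12, cfg)
            s = event_probabilities("sacval", klass, 12, cfg)
            assert s.p_hosp < e.p_hosp
            assert s.p_cv_death < e.p_cv_death
            assert s.p_noncv_death == e.p_noncv_death

    def test_class_multipliers_in_small_probability_limit(self, cfg):
        e2 = event_probabilities("enalapril", HealthState.NYHA_II, 1, cfg)
        e4 = event_probabilities("enalapril", HealthState.NYHA_IV, 1, cfg)
        assert e4.p_hosp / e2.p_hosp == pytest.approx(3.4, rel=5e-3)
        assert e4.p_cv_death / e2.p_cv_death == pytest.approx(1.640, rel=1e-9)


class TestTransitionMatrix:
    def test_row_stochastic_everywhere(self, cfg):
        for arm in cfg.arms:
            dyn = ArmDynamics(arm, cfg)  # 120 cycles, ages 64-74
            sums = dyn.matrices.sum(axis=2)
            assert np.all(np.abs(sums - 1.0) <= 1e-9)
            assert np.all(dyn.matrices >= 0.0) and np.all(dyn.matrices <= 1.0)

    def test_death_states_absorbing(self, cfg):
        tm = build_transition_matrix("sacval", 37, cfg)
        for dead in (HealthState.DEATH_CV, HealthState.DEATH_NONCV):
            row = tm.matrix[dead]
            assert row[dead] == 1.0 and row.sum() == 1.0

    def test_class_iv_change_goes_to_class_iii(self, cfg):
        tm = build_transition_matrix("enalapril", 1, cfg)
        row = tm.matrix[HealthState.NYHA_IV]
        # All class-change mass from IV lands in III (conditional prob 1.000).
        assert row[HealthState.NYHA_I] == 0.0 and row[HealthState.NYHA_II] == 0.0
        change_mass = 1.0 - row[HealthState.NYHA_IV] - row[HealthState.DEATH_CV] \
            - row[HealthState.DEATH_NONCV]
        assert row[HealthState.NYHA_III] == pytest.approx(change_mass, abs=1e-12)

    def test_no_events_gives_identity(self, cfg):
        quiet = quiet_config(cfg)
        tm = build_transition_matrix("enalapril", 1, quiet)
        assert np.allclose(tm.matrix, np.eye(6), atol=1e-15)

    def test_arm_equivalence_without_treatment_effect(self, cfg):
        # With unit hazard ratios and shared NYHA-change probability the two
        # arms must generate identical matrices cycle by cycle.
        neutral = with_parameter_values(
            cfg,
            {
                "hr_hosp_sacval": 1.0,
                "hr_cv_death_sacval": 1.0,
                "p_nyha_change_sacval": cfg.param("p_nyha_change_enalapril"),
            },
        )
        a = ArmDynamics("sacval", neutral)
        b = ArmDynamics("enalapril", neutral)
        assert np.array_equal(a.matrices, b.matrices)
        assert np.array_equal(a.hosp_mass, b.hosp_mass)
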