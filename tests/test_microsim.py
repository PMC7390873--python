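"""Patient-level simulation: determinism, closed-form cases, the cohort
oracle-equivalence check, and hazard-parameter recovery."""

import math

import numpy as np
import pytest
from scipy.stats import chi2

import hfcea as h
from hfcea.params import with_overrides, with_parameter_values

from conftest import quiet_config


def test_no_event_patient_closed_form(cfg):
    quiet = quiet_config(cfg, discount_rate_annual=0.0)
    traj = h.simulate_patient("enalapril", quiet, np.random.default_rng(0))
    assert traj.states == tuple([1] * 121)  # stays in NYHA II
    assert traj.events == ()
    assert traj.cost == pytest.approx(120 * (10.65 + 41.56), abs=1e-9)
    assert traj.qaly == pytest.approx(7.80, abs=1e-9)


def test_certain_cv_death_first_cycle(cfg):
    lethal = with_parameter_values(quiet_config(cfg), {"p_cv_death_monthly": 1.0})
    traj = h.simulate_patient("enalapril", lethal, np.random.default_rng(0))
    assert traj.states[1] == 4 and all(s == 4 for s in traj.states[1:])
    assert traj.events == ((1, "cv_death"),)
    # Half-cycle convention: half a month of utility and fixed costs.
    assert traj.qaly == pytest.approx(0.5 * 0.780 / 12.0, abs=1e-12)
    assert traj.cost == pytest.approx(0.5 * (10.65 + 41.56), abs=1e-12)


def test_population_of_one_equals_single_patient(cfg):
    traj = h.simulate_patient("sacval", cfg, np.random.default_rng(123))
    pop = h.simulate_population("sacval", 1, cfg, seed=123)
    assert pop.mean_cost == pytest.approx(traj.cost_discounted, abs=1e-12)
    assert pop.mean_qaly == pytest.approx(traj.qaly_discounted, abs=1e-12)


def test_seed_reproducibility(cfg):
    a = h.simulate_population("enalapril", 500, cfg, seed=7)
    b = h.simulate_population("enalapril", 500, cfg, seed=7)
    assert a.mean_cost == b.mean_cost and a.mean_qaly == b.mean_qaly
    assert np.array_equal(a.dataset.hosp_time, b.dataset.hosp_time)


def test_trajectory_event_log_consistent(cfg):
    rng = np.random.default_rng(2024)
    for _ in range(50):
        traj = h.simulate_patient("enalapril", cfg, rng)
        death_cycles = [c for c, e in traj.events if e in ("cv_death", "noncv_death")]
        assert len(death_cycles) <= 1
        if death_cycles:
            d = death_cycles[0]
            assert all(c <= d for c, _ in traj.events)  # no events after death
            assert all(s >= 4 for s in traj.states[d:])


@pytest.mark.parametrize("arm", ["sacval", "enalapril"])
def test_microsim_agrees_with_cohort_engine(arm, populations_200k, base_pair):
    """The central cross-validation: patient-level Monte Carlo means must
    match the deterministic cohort totals within 3 standard errors."""
    pop = populations_200k[arm]
    res = base_pair[0] if arm == "sacval" else base_pair[1]
    assert abs(pop.mean_cost - res.total_cost) <= 3 * pop.se_cost
    assert abs(pop.mean_qaly - res.total_qaly) <= 3 * pop.se_qaly
    assert abs(
        pop.death_fraction - res.death_fraction_by_cycle[-1]
    ) <= 3 * pop.se_death_fraction


@pytest.fixture(scope="module")
def cv_dataset(cfg):
    # CV death as the only transition: censoring only at the horizon.
    pure = quiet_config(cfg, p_cv=cfg.param("p_cv_death_monthly"))
    return h.simulate_population("enalapril", 50_000, pure, seed=31).dataset


@pytest.fixture(scope="module")
def hosp_dataset(cfg):
    # Hospitalization hazard alone, at a scale giving ~70% uncensored.
    pure = quiet_config(cfg, p_hosp=0.01)
    return h.simulate_population("enalapril", 50_000, pure, seed=32).dataset


class TestParameterRecovery:
    def test_exponential_rate_recovery(self, cfg, cv_dataset):
        fit = h.recover_exponential(cv_dataset, event="cv_death")
        assert fit.n_events > 20_000
        assert fit.lam == pytest.approx(-0.00577, rel=0.10)

    def test_exponential_scaling(self, cfg):
        # Doubling the monthly hazard halves the recovered median event time.
        p = cfg.param("p_cv_death_monthly")
        p_double = 1.0 - (1.0 - p) ** 2  # exactly twice the rate
        slow = quiet_config(cfg, p_cv=p)
        fast = quiet_config(cfg, p_cv=p_double)
        t_slow = h.simulate_population("enalapril", 20_000, slow, seed=8).dataset
        t_fast = h.simulate_population("enalapril", 20_000, fast, seed=9).dataset
        lam_slow = h.recover_exponential(t_slow, event="cv_death").lam
        lam_fast = h.recover_exponential(t_fast, event="cv_death").lam
        med_slow, med_fast = math.log(2) / -lam_slow, math.log(2) / -lam_fast
        assert med_slow / med_fast == pytest.approx(2.0, rel=0.1)

    def test_weibull_shape_recovery(self, cfg, hosp_dataset):
        fit = h.recover_weibull(hosp_dataset, event="hospitalization")
        assert fit.gamma_shape == pytest.approx(1.02685, abs=0.1)
        # Scale check robust to the lam/gamma correlation: the implied
        # window-mean monthly probability matches the generating anchor.
        t = np.arange(1.0, 121.0)
        incr = t**fit.gamma_shape - (t - 1) ** fit.gamma_shape
        mean_p = np.mean(1.0 - np.exp(fit.lam * incr))
        assert mean_p == pytest.approx(0.01, rel=0.05)

    def test_weibull_beats_or_matches_exponential_loglik(self, hosp_dataset):
        wb = h.recover_weibull(hosp_dataset, event="hospitalization")
        ex = h.recover_exponential(hosp_dataset, event="hospitalization")
        assert wb.loglik >= ex.loglik - 1e-6  # nested models

    def test_exponential_not_rejected_on_exponential_data(self, cfg):
        # Likelihood-ratio test of Weibull vs exponential on shape-1 data:
        # at alpha = 0.05 the exponential should survive in >= 90% of runs.
        pure = quiet_config(cfg, p_hosp=0.01)
        pure = with_overrides(
            pure,
            hazard_models={
                **pure.hazard_models,
                "hospitalization_enalapril": pure.hazard_models[
                    "hospitalization_enalapril"
                ].__class__(family="weibull", lam=-0.01, gamma_shape=1.0),
            },
        )
        crit = chi2.ppf(0.95, df=1)
        rejections = 0
        for rep in range(10):
            ds = h.simulate_population("enalapril", 4_000, pure, seed=400 + rep).dataset
            wb = h.recover_weibull(ds, event="hospitalization")
            ex = h.recover_exponential(ds, event="hospitalization")
            if 2 * (wb.loglik - ex.loglik) > crit:
                rejections += 1
        assert rejections <= 1

    def test_all_censored_rejected(self, cfg):
        silent = quiet_config(cfg)
        ds = h.simulate_population("enalapril", 200, silent, seed=1).dataset
        with pytest.raises(ValueError, match="no uncensored"):
            h.recover_exponential(ds, event="cv_death")

    def test_minimum_event_count_enforced(self, cfg):
        small = quiet_config(cfg, p_hosp=0.01)
        ds = h.simulate_population("enalapril", 300, small, seed=2).dataset
        with pytest.raises(ValueError, match=">= 500"):
            h.recover_weibull(ds, event="hospitalization")
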