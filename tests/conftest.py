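"""Shared fixtures: the default configuration, base-case runs, and the heavy
Monte Carlo artefacts (200k-patient microsimulations, 10k-draw PSA) that
several test modules validate against."""

import pytest
from hypothesis import settings

import hfcea as h
from hfcea.params import MortalityTable, with_overrides, with_parameter_values

settings.register_profile("repeatable", derandomize=True)
settings.load_profile("repeatable")


@pytest.fixture(scope="session")
def cfg():
    return h.default_config()


@pytest.fixture(scope="session")
def base_pair(cfg):
    """(sacval, enalapril) base-case cohort results."""
    return h.scenario_run(cfg)


@pytest.fixture(scope="session")
def populations_200k(cfg):
    """200,000-patient microsimulations per arm (the cohort-engine oracle)."""
    return {
        arm: h.simulate_population(arm, 200_000, cfg, seed=100 + i)
        for i, arm in enumerate(("sacval", "enalapril"))
    }


@pytest.fixture(scope="session")
def psa_10k(cfg):
    """The full 10,000-draw probabilistic sensitivity analysis."""
    return h.run_psa(cfg, n_draws=10_000, seed=cfg.seed)


def quiet_config(
    cfg,
    p_hosp=0.0,
    p_cv=0.0,
    p_readmit=0.0,
    p_change=0.0,
    zero_mortality=True,
    neutral_multipliers=True,
    initial=(0.0, 1.0, 0.0, 0.0),
    **overrides,
):
    """A stripped configuration for closed-form and recovery tests.

    Defaults silence every event channel and put the whole cohort in NYHA II,
    so individual hazards can be switched on in isolation.
    """
    values = {
        "p_hosp_monthly": p_hosp,
        "p_cv_death_monthly": p_cv,
        "p_readmission": p_readmit,
        "p_nyha_change_enalapril": p_change,
        "p_nyha_change_sacval": p_change,
    }
    if neutral_multipliers:
        values.update(
            hr_hosp_sacval=1.0, hr_cv_death_sacval=1.0,
            hr_hosp_nyha3=1.0, hr_hosp_nyha4=1.0,
            rr_cv_death_nyha3=1.0, rr_cv_death_nyha4=1.0,
        )
    out = with_parameter_values(cfg, values)
    kwargs = dict(initial_nyha_distribution=tuple(initial), **overrides)
    if zero_mortality:
        kwargs["mortality_table"] = MortalityTable(entries=((1.0, 0.0), (100.0, 1.0)))
    return with_overrides(out, **kwargs)
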