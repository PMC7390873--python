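"""Deterministic Markov cohort engine: occupancy, events, discounted accrual.

One run evolves the state-occupancy vector through the per-cycle transition
matrices and accrues, per cycle,

* quality-adjusted life (state utility / 12 per occupant, half-cycle
  corrected) minus one-time disutilities per expected hospitalization or
  readmission, and
* patient-borne costs: monthly drug and outpatient-visit cost per living
  occupant (half-cycle corrected) plus the inpatient copay share of
  hospitalization and readmission costs per expected event.

Discounting is monthly at (1 + r)**(-(t - 0.5) / 12): all of cycle t's
accrual is valued at the cycle midpoint, the convention implied by the
half-cycle correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hazards import ArmDynamics, HealthState, N_LIVING
from .params import ModelConfig, with_overrides

__all__ = ["CohortResult", "run_cohort", "death_fraction", "scenario_run", "accrual_inputs"]


@dataclass(frozen=True)
class AccrualInputs:
    """Per-cycle economic inputs shared by the cohort engine and the microsim."""

    utilities: np.ndarray          # (4,) per living class, per year
    disutility_hosp: float         # QALY decrement per hospitalization (>= 0)
    disutility_readmit: float
    monthly_fixed_cost: float      # drug + outpatient visit, per living month
    event_cost_hosp: float         # patient-borne, per event
    event_cost_readmit: float
    discount: np.ndarray           # (T,) midpoint discount factors


def accrual_inputs(arm: str, config: ModelConfig, horizon_cycles: int) -> AccrualInputs:
    s = config.settings
    p = config.param
    copay = p("copay_inpatient")
    patient_share = copay if s.inpatient_copay_is_patient_share else 1.0 - copay
    dis_scale = 1.0 if s.disutility_mode == "per_event" else 1.0 / 12.0
    t = np.arange(1, horizon_cycles + 1, dtype=float)
    return AccrualInputs(
        utilities=np.array(
            [p("utility_nyha12"), p("utility_nyha12"), p("utility_nyha3"), p("utility_nyha4")]
        ),
        disutility_hosp=-p("disutility_hosp") * dis_scale,
        disutility_readmit=-p("disutility_readmit") * dis_scale,
        monthly_fixed_cost=p(config.arms[arm].drug_cost_param) + p("cost_outpatient_monthly"),
        event_cost_hosp=p("cost_hospitalization") * patient_share,
        event_cost_readmit=p("cost_readmission") * patient_share,
        discount=(1.0 + config.discount_rate_annual) ** (-(t - 0.5) / 12.0),
    )


@dataclass
class CohortResult:
    """Per-cycle trace arrays and discounted totals for one arm.

    Array fields have length ``horizon_cycles`` (index t-1 is cycle t);
    ``occupancy`` has shape (horizon_cycles + 1, 6) with row 0 the initial
    state vector.  ``traces`` builds the audit table on demand.
    """

    arm: str
    horizon_cycles: int
    occupancy: np.ndarray
    ages: np.ndarray
    hospitalizations: np.ndarray
    readmissions: np.ndarray
    cv_deaths: np.ndarray
    noncv_deaths: np.ndarray
    cost: np.ndarray
    cost_discounted: np.ndarray
    qaly: np.ndarray
    qaly_discounted: np.ndarray

    @property
    def total_cost(self) -> float:
        return float(self.cost_discounted.sum())

    @property
    def total_qaly(self) -> float:
        return float(self.qaly_discounted.sum())

    @property
    def total_cost_undiscounted(self) -> float:
        return float(self.cost.sum())

    @property
    def total_qaly_undiscounted(self) -> float:
        return float(self.qaly.sum())

    @property
    def death_fraction_by_cycle(self) -> np.ndarray:
        """Combined death-state occupancy at each cycle boundary (length T+1)."""
        return self.occupancy[:, HealthState.DEATH_CV] + self.occupancy[:, HealthState.DEATH_NONCV]

    @property
    def traces(self):
        """Audit table: one row per cycle with occupancy, events and accruals."""
        import pandas as pd

        T = self.horizon_cycles
        data = {
            "cycle": np.arange(1, T + 1),
            "age": self.ages,
        }
        names = [s.name for s in HealthState]
        for i, n in enumerate(names):
            data[f"start_{n}"] = self.occupancy[:-1, i]
        for i, n in enumerate(names):
            data[f"end_{n}"] = self.occupancy[1:, i]
        data.update(
            hospitalizations=self.hospitalizations,
            readmissions=self.readmissions,
            cv_deaths=self.cv_deaths,
            noncv_deaths=self.noncv_deaths,
            cost=self.cost,
            cost_discounted=self.cost_discounted,
            qaly=self.qaly,
            qaly_discounted=self.qaly_discounted,
        )
        return pd.DataFrame(data)


def run_cohort(arm: str, config: ModelConfig, horizon_cycles: int | None = None) -> CohortResult:
    """Run the deterministic cohort simulation for one arm.

    ``horizon_cycles`` overrides the configured horizon (0 is allowed and
    yields zero totals).  The state vector starts with the configured NYHA
    distribution across the living classes and zero mass in the death states.
    """
    T = config.horizon_cycles if horizon_cycles is None else horizon_cycles
    if T < 0:
        raise ValueError(f"horizon_cycles must be >= 0, got {T}")

    occ = np.zeros((T + 1, 6))
    occ[0, :N_LIVING] = config.initial_nyha_distribution
    zeros = np.zeros(T)
    result = CohortResult(
        arm=arm, horizon_cycles=T, occupancy=occ,
        ages=config.start_age + np.arange(T) / 12.0,
        hospitalizations=zeros.copy(), readmissions=zeros.copy(),
        cv_deaths=zeros.copy(), noncv_deaths=zeros.copy(),
        cost=zeros.copy(), cost_discounted=zeros.copy(),
        qaly=zeros.copy(), qaly_discounted=zeros.copy(),
    )
    if T == 0:
        return result

    dyn = ArmDynamics(arm, config, horizon_cycles=T)
    acc = accrual_inputs(arm, config, T)

    n = occ[0]
    for t in range(T):
        living = n[:N_LIVING]
        n_end = n @ dyn.matrices[t]
        occ[t + 1] = n_end

        hosp = float(living @ dyn.hosp_mass[:, t])
        readmit = float(living @ dyn.readmit_mass[:, t])
        result.hospitalizations[t] = hosp
        result.readmissions[t] = readmit
        result.cv_deaths[t] = float(living @ dyn.p_cv)
        result.noncv_deaths[t] = float(living @ ((1.0 - dyn.p_cv) * dyn.p_ncv[t]))

        avg_living = 0.5 * (living + n_end[:N_LIVING])
        qaly = float(avg_living @ acc.utilities) / 12.0
        qaly -= hosp * acc.disutility_hosp + readmit * acc.disutility_readmit
        cost = acc.monthly_fixed_cost * float(avg_living.sum())
        cost += hosp * acc.event_cost_hosp + readmit * acc.event_cost_readmit

        result.qaly[t] = qaly
        result.cost[t] = cost
        result.qaly_discounted[t] = qaly * acc.discount[t]
        result.cost_discounted[t] = cost * acc.discount[t]
        n = n_end

    return result


def death_fraction(result: CohortResult, at_years: float) -> float:
    """Combined death-state occupancy at the boundary of cycle round(12 * years)."""
    cycle = round(12.0 * at_years)
    if not 0 <= cycle <= result.horizon_cycles:
        raise ValueError(
            f"{at_years} years is outside the simulated horizon "
            f"of {result.horizon_cycles} cycles"
        )
    return float(result.death_fraction_by_cycle[cycle])


def scenario_run(
    config: ModelConfig,
    horizon_years: float | None = None,
    initial_distribution: tuple[float, float, float, float] | None = None,
) -> tuple[CohortResult, CohortResult]:
    """Run both arms under shared scenario overrides.

    Returns ``(intervention, comparator)`` results under the same horizon and
    initial NYHA distribution, ready for incremental comparison.
    """
    overrides = {}
    if horizon_years is not None:
        overrides["horizon_cycles"] = round(12 * horizon_years)
    if initial_distribution is not None:
        overrides["initial_nyha_distribution"] = tuple(initial_distribution)
    cfg = with_overrides(config, **overrides) if overrides else config
    return (
        run_cohort(cfg.intervention_arm, cfg),
        run_cohort(cfg.comparator_arm, cfg),
    )
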