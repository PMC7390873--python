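"""Patient-level Monte Carlo realization of the same clinical pathway.

Each simulated patient walks the identical monthly cycle the cohort engine
integrates in expectation: CV death first, then non-CV death among
survivors, then a NYHA class change among cycle survivors; hospitalization
(and its 30-day readmission) is drawn among cycle survivors.  Accrual uses
the same half-cycle convention — state utility and fixed monthly costs at
the average of the start and end states, one-time event costs and
disutilities in full — and the same midpoint discount factors, so the
population mean is an unbiased Monte Carlo estimate of the cohort result.
This makes the microsimulation the package's independent oracle for the
cohort engine, and its event-time output a test bed for recovering the
parametric hazard coefficients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .cohort import accrual_inputs
from .hazards import ArmDynamics, N_LIVING
from .params import ModelConfig

__all__ = [
    "PatientTrajectory",
    "EventTimeDataset",
    "PopulationResult",
    "ExponentialFit",
    "WeibullFit",
    "simulate_patient",
    "simulate_population",
    "recover_exponential",
    "recover_weibull",
]

_DEATH_CV, _DEATH_NONCV = 4, 5


@dataclass(frozen=True)
class PatientTrajectory:
    """One simulated patient: state path, event log, realized outcomes."""

    arm: str
    states: tuple[int, ...]                 # length horizon+1, start state first
    events: tuple[tuple[int, str], ...]     # (cycle, event name), cycle is 1-based
    cost: float
    cost_discounted: float
    qaly: float
    qaly_discounted: float


@dataclass(frozen=True)
class EventTimeDataset:
    """First-event times in months with right-censoring indicators.

    ``hosp_time`` is the cycle of the first hospitalization when
    ``hosp_observed``, otherwise the last cycle the patient was at risk
    (death or horizon).  ``cv_death_time`` is analogous for CV death
    (censored by non-CV death or the horizon).
    """

    hosp_time: np.ndarray
    hosp_observed: np.ndarray
    cv_death_time: np.ndarray
    cv_death_observed: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "patient_id": np.arange(len(self.hosp_time)),
                "hosp_time": self.hosp_time,
                "hosp_observed": self.hosp_observed,
                "cv_death_time": self.cv_death_time,
                "cv_death_observed": self.cv_death_observed,
            }
        )


@dataclass(frozen=True)
class PopulationResult:
    """Monte Carlo estimates (mean and standard error) over n patients."""

    arm: str
    n: int
    mean_cost: float
    se_cost: float
    mean_qaly: float
    se_qaly: float
    death_fraction: float
    se_death_fraction: float
    mean_cost_undiscounted: float
    mean_qaly_undiscounted: float
    dataset: EventTimeDataset


def _simulate_kernel(
    arm: str,
    config: ModelConfig,
    rng: np.random.Generator,
    n: int,
    collect: bool,
):
    dyn = ArmDynamics(arm, config)
    acc = accrual_inputs(arm, config, dyn.horizon_cycles)
    T = dyn.horizon_cycles
    per_hosp = config.settings.readmission_mode == "per_hospitalization"

    state = rng.choice(
        N_LIVING, size=n, p=np.asarray(config.initial_nyha_distribution)
    ).astype(np.int64)
    u6 = np.concatenate([acc.utilities, [0.0, 0.0]])
    change_cum = np.cumsum(dyn.change_rows, axis=1)

    cost = np.zeros(n)
    cost_d = np.zeros(n)
    qaly = np.zeros(n)
    qaly_d = np.zeros(n)
    hosp_time = np.zeros(n, dtype=np.int64)
    hosp_obs = np.zeros(n, dtype=bool)
    cv_time = np.zeros(n, dtype=np.int64)
    cv_obs = np.zeros(n, dtype=bool)
    states_path = [state.copy()] if collect else None
    event_log: list[tuple[np.ndarray, str]] = []

    for t in range(T):
        u = rng.random((6, n))
        alive = state < N_LIVING
        k = np.minimum(state, N_LIVING - 1)  # safe index for dead rows

        die_cv = alive & (u[0] < dyn.p_cv[k])
        at_risk_ncv = alive & ~die_cv
        die_ncv = at_risk_ncv & (u[1] < dyn.p_ncv[t])
        surv = at_risk_ncv & ~die_ncv

        change = surv & (u[2] < dyn.p_change)
        dest = (u[3][:, None] > change_cum[k]).sum(axis=1)
        hosp = surv & (u[4] < dyn.p_hosp[k, t])
        readmit = (hosp if per_hosp else surv) & (u[5] < dyn.p_readmit)

        new_state = state.copy()
        new_state[die_cv] = _DEATH_CV
        new_state[die_ncv] = _DEATH_NONCV
        new_state[change] = dest[change]

        # First-event times (1-based cycles) and censoring.
        newly_hosp = hosp & ~hosp_obs
        hosp_time[newly_hosp] = t + 1
        hosp_obs |= hosp
        # Patients dying in cycle t were at risk of hospitalization only
        # through cycle t-1; CV-death risk in the death cycle itself.
        died = die_cv | die_ncv
        hosp_time[died & ~hosp_obs] = t  # may be 0 for a first-cycle death
        cv_time[die_cv & ~cv_obs] = t + 1
        cv_obs |= die_cv
        cv_time[die_ncv & ~cv_obs] = t + 1

        # Accrual with the half-cycle convention.
        u_start = np.where(alive, u6[k], 0.0)
        u_end = u6[np.minimum(new_state, 5)] * (new_state < N_LIVING)
        q_t = 0.5 * (u_start + u_end) / 12.0
        q_t -= hosp * acc.disutility_hosp + readmit * acc.disutility_readmit
        exposure = np.where(surv, 1.0, np.where(died, 0.5, 0.0))
        c_t = acc.monthly_fixed_cost * exposure
        c_t += hosp * acc.event_cost_hosp + readmit * acc.event_cost_readmit

        qaly += q_t
        cost += c_t
        qaly_d += q_t * acc.discount[t]
        cost_d += c_t * acc.discount[t]

        if collect:
            states_path.append(new_state.copy())
            for mask, name in (
                (hosp, "hosp"), (readmit, "readmit"), (change, "nyha_change"),
                (die_cv, "cv_death"), (die_ncv, "noncv_death"),
            ):
                if mask.any():
                    event_log.append((t + 1, name, mask.copy()))
        state = new_state

    still_alive = state < N_LIVING
    hosp_time[still_alive & ~hosp_obs] = T
    cv_time[still_alive & ~cv_obs] = T
    # Non-CV deaths: censor CV time at the death cycle (set above).

    dataset = EventTimeDataset(
        hosp_time=hosp_time, hosp_observed=hosp_obs,
        cv_death_time=cv_time, cv_death_observed=cv_obs,
    )
    return state, cost, cost_d, qaly, qaly_d, dataset, states_path, event_log


def simulate_patient(arm: str, config: ModelConfig, rng: np.random.Generator) -> PatientTrajectory:
    """Simulate a single patient trajectory with full state and event log."""
    state, cost, cost_d, qaly, qaly_d, _, path, log = _simulate_kernel(
        arm, config, rng, n=1, collect=True
    )
    events = tuple((cycle, name) for cycle, name, mask in log if mask[0])
    return PatientTrajectory(
        arm=arm,
        states=tuple(int(s[0]) for s in path),
        events=events,
        cost=float(cost[0]),
        cost_discounted=float(cost_d[0]),
        qaly=float(qaly[0]),
        qaly_discounted=float(qaly_d[0]),
    )


def simulate_population(
    arm: str, n: int, config: ModelConfig, seed: int | np.random.Generator
) -> PopulationResult:
    """Simulate ``n`` independent patients; aggregate estimates with SEs."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    state, cost, cost_d, qaly, qaly_d, dataset, _, _ = _simulate_kernel(
        arm, config, rng, n=n, collect=False
    )
    dead = (state >= N_LIVING).astype(float)
    sqrt_n = math.sqrt(n)

    def se(x: np.ndarray) -> float:
        return float(x.std(ddof=1) / sqrt_n) if n > 1 else math.nan

    return PopulationResult(
        arm=arm, n=n,
        mean_cost=float(cost_d.mean()), se_cost=se(cost_d),
        mean_qaly=float(qaly_d.mean()), se_qaly=se(qaly_d),
        death_fraction=float(dead.mean()), se_death_fraction=se(dead),
        mean_cost_undiscounted=float(cost.mean()),
        mean_qaly_undiscounted=float(qaly.mean()),
        dataset=dataset,
    )


# ---------------------------------------------------------------------------
# hazard-parameter recovery (censored discrete-time maximum likelihood)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExponentialFit:
    lam: float
    loglik: float
    n_events: int


@dataclass(frozen=True)
class WeibullFit:
    lam: float
    gamma_shape: float
    loglik: float
    n_events: int


def _select(dataset: EventTimeDataset, event: str):
    if event == "hospitalization":
        return np.asarray(dataset.hosp_time, float), np.asarray(dataset.hosp_observed, bool)
    if event == "cv_death":
        return np.asarray(dataset.cv_death_time, float), np.asarray(dataset.cv_death_observed, bool)
    raise ValueError(f"unknown event {event!r}")


def recover_exponential(dataset: EventTimeDataset, event: str = "cv_death") -> ExponentialFit:
    """Maximum-likelihood constant-rate fit on censored monthly event times.

    Under a geometric event-time model with monthly probability p the MLE is
    p = events / total at-risk months; returned as the signed log-survival
    coefficient lam = ln(1 - p), comparable to the configured value.
    Requires at least 100 uncensored events.
    """
    times, observed = _select(dataset, event)
    d = int(observed.sum())
    if d == 0:
        raise ValueError("no uncensored events: exponential rate is not estimable")
    if d < 100:
        raise ValueError(f"need >= 100 uncensored events, got {d}")
    exposure = float(times.sum())
    p = d / exposure
    loglik = d * math.log(p) + (exposure - d) * math.log(1.0 - p)
    return ExponentialFit(lam=math.log(1.0 - p), loglik=loglik, n_events=d)


def recover_weibull(dataset: EventTimeDataset, event: str = "hospitalization") -> WeibullFit:
    """Censored discrete-time ML fit of S(t) = exp(lam * t**gamma).

    The likelihood uses exact monthly interval probabilities
    S(t-1) - S(t) for events and S(t) for censored records; optimization is
    over (log(-lam), log(gamma)).  Requires at least 500 uncensored events.
    """
    times, observed = _select(dataset, event)
    d = int(observed.sum())
    if d < 500:
        raise ValueError(f"need >= 500 uncensored events, got {d}")
    keep = times >= 1.0  # zero-time censored records carry no information
    times, observed = times[keep], observed[keep]

    # Collapse to counts per (time, status) for a fast likelihood.
    tab: dict[tuple[float, bool], int] = {}
    for t, o in zip(times, observed):
        tab[(float(t), bool(o))] = tab.get((float(t), bool(o)), 0) + 1
    t_arr = np.array([k[0] for k in tab])
    o_arr = np.array([k[1] for k in tab])
    w_arr = np.array([tab[k] for k in tab], dtype=float)

    def negloglik(x: np.ndarray) -> float:
        lam, g = -math.exp(x[0]), math.exp(x[1])
        s_prev = np.exp(lam * (t_arr - 1.0) ** g)
        s_curr = np.exp(lam * t_arr**g)
        lik = np.where(o_arr, np.maximum(s_prev - s_curr, 1e-300), s_curr)
        return -float(w_arr @ np.log(lik))

    exp_fit = recover_exponential(dataset, event) if d >= 100 else None
    lam0 = exp_fit.lam if exp_fit is not None else -d / float(times.sum())
    x0 = np.array([math.log(-lam0), 0.0])
    res = minimize(negloglik, x0, method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
    if not res.success:
        raise RuntimeError(f"Weibull fit did not converge: {res.message}")
    lam, g = -math.exp(res.x[0]), math.exp(res.x[1])
    return WeibullFit(lam=lam, gamma_shape=g, loglik=-float(res.fun), n_events=d)
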