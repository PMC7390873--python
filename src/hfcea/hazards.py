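"""Per-cycle transition probabilities and the row-stochastic transition matrix.

The clinical pathway has six states: NYHA functional classes I-IV plus two
absorbing death states (cardiovascular and non-cardiovascular), which are
re-aggregated to a single "death" wherever results are reported.  Baseline
monthly hospitalization follows a Weibull model fitted to the comparator
arm's trial survival curve and CV death an exponential model; treatment and
NYHA-class effects enter as hazard ratios on the rate scale (relative risks
multiply the probability directly).  Background non-CV mortality comes from
an age-indexed life table.

Competing events within a cycle resolve by conditional sequencing: CV death
first, then non-CV death among survivors, then a NYHA class change among
cycle survivors.  Hospitalization and 30-day readmission do not change the
health state; they are tracked in the event decomposition because they carry
one-time costs and disutilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import IntEnum

import numpy as np
from scipy.optimize import brentq

from .params import HazardModelSpec, ModelConfig, MortalityTable

__all__ = [
    "HealthState",
    "EventProbabilities",
    "TransitionMatrix",
    "ArmDynamics",
    "monthly_prob_exponential",
    "monthly_prob_weibull",
    "calibrate_weibull_lam",
    "apply_hazard_ratio",
    "background_mortality_monthly",
    "event_probabilities",
    "build_transition_matrix",
    "transition_matrices_frame",
]

# The anchor is defined as the mean monthly hospitalization probability over
# this fixed reference window (the 10-year base-case horizon), independent of
# the horizon actually simulated, so scenario runs share one hazard curve.
CALIBRATION_WINDOW_CYCLES = 120


class HealthState(IntEnum):
    NYHA_I = 0
    NYHA_II = 1
    NYHA_III = 2
    NYHA_IV = 3
    DEATH_CV = 4
    DEATH_NONCV = 5


N_STATES = 6
N_LIVING = 4


@dataclass(frozen=True)
class EventProbabilities:
    """Monthly event probabilities for one (arm, NYHA class, cycle, age).

    All are probabilities of the event for a patient in the class at the
    start of the cycle, before competing-event sequencing; hospitalization
    and readmission apply to cycle survivors.
    """

    p_hosp: float
    p_readmit: float
    p_cv_death: float
    p_noncv_death: float
    p_nyha_change: float


@dataclass(frozen=True)
class TransitionMatrix:
    """One cycle's 6x6 row-stochastic matrix plus its event decomposition."""

    arm: str
    cycle: int
    matrix: np.ndarray  # (6, 6)
    events: tuple[EventProbabilities, ...]  # per living origin class


# ---------------------------------------------------------------------------
# elementary conversions
# ---------------------------------------------------------------------------

def monthly_prob_exponential(model: HazardModelSpec, cycle: int = 1) -> float:
    """Constant monthly event probability of an exponential survival model.

    With S(t) = exp(lam * t) and lam < 0 the per-cycle conditional event
    probability is 1 - exp(lam), independent of the cycle (memorylessness).
    """
    if model.family != "exponential":
        raise ValueError(f"expected exponential model, got {model.family!r}")
    if model.lam >= 0:
        raise ValueError(f"lam must be negative for decaying survival, got {model.lam}")
    return 1.0 - math.exp(model.lam)


def _weibull_increments(gamma_shape: float, cycles: np.ndarray) -> np.ndarray:
    return cycles ** gamma_shape - (cycles - 1.0) ** gamma_shape


def monthly_prob_weibull(model: HazardModelSpec, cycle: int) -> float:
    """Conditional event probability in cycle t of a Weibull survival model.

    Under S(t) = exp(lam * t**gamma) the probability of the event in month t
    given event-free survival to t-1 is 1 - exp(lam * (t**gamma -
    (t-1)**gamma)); strictly increasing in t when gamma > 1.
    """
    if model.family != "weibull":
        raise ValueError(f"expected weibull model, got {model.family!r}")
    if cycle < 1:
        raise ValueError(f"cycle must be >= 1, got {cycle}")
    if model.lam >= 0:
        raise ValueError(f"lam must be negative for decaying survival, got {model.lam}")
    g = model.gamma_shape if model.gamma_shape is not None else 1.0
    p = 1.0 - math.exp(model.lam * (cycle ** g - (cycle - 1) ** g))
    if not 0.0 < p < 1.0:
        raise ValueError(f"monthly probability {p} outside (0, 1)")
    return p


def calibrate_weibull_lam(
    gamma_shape: float,
    anchor: float,
    n_cycles: int = CALIBRATION_WINDOW_CYCLES,
) -> float:
    """Scale coefficient making the window-mean monthly probability hit ``anchor``.

    Solves lam < 0 such that mean over t=1..n_cycles of
    1 - exp(lam * (t**gamma - (t-1)**gamma)) equals ``anchor``.  Used because
    the published Weibull coefficients are not on the same scale as the
    published plausible band for the monthly hospitalization probability; the
    band is the usable cross-check, so the scale is re-solved against it.
    """
    if anchor == 0.0:
        return 0.0  # degenerate: no hospitalization hazard at all
    if not 0.0 < anchor < 1.0:
        raise ValueError(f"anchor must be in [0, 1), got {anchor}")
    incr = _weibull_increments(gamma_shape, np.arange(1, n_cycles + 1, dtype=float))

    def mean_p(lam: float) -> float:
        return float(np.mean(1.0 - np.exp(lam * incr))) - anchor

    # Bracket: mean p is monotone decreasing in lam on (-inf, 0).  The upper
    # end must stay above the root even for extremely small anchors.
    lo, hi = -1.0, -1e-300
    while mean_p(lo) < 0:
        lo *= 4.0
        if lo < -1e6:  # pragma: no cover - unreachable for anchor < 1
            raise ValueError("failed to bracket calibration root")
    return float(brentq(mean_p, lo, hi, xtol=1e-15, rtol=1e-14))


def apply_hazard_ratio(p: float, hr: float) -> float:
    """Apply a hazard ratio on the rate scale: p' = 1 - (1 - p)**hr."""
    if hr <= 0:
        raise ValueError(f"hazard ratio must be > 0, got {hr}")
    if not 0.0 <= p < 1.0:
        if p == 1.0 and hr == 1.0:
            return 1.0
        raise ValueError(f"probability must be in [0, 1), got {p}")
    return 1.0 - (1.0 - p) ** hr


def background_mortality_monthly(table: MortalityTable, age: float) -> float:
    """Monthly non-CV death probability at ``age`` from the annual life table.

    The annual probability is a left step function of age; conversion to a
    monthly probability assumes a constant hazard within the year,
    p_month = 1 - (1 - p_year)**(1/12).  At age >= 100 death is certain.
    """
    p_annual = table.annual_prob(age)
    if p_annual >= 1.0:
        return 1.0
    return 1.0 - (1.0 - p_annual) ** (1.0 / 12.0)


# ---------------------------------------------------------------------------
# vectorized per-arm dynamics
# ---------------------------------------------------------------------------

def _scaled_prob(p, multiplier, hr_scale: str):
    """Multiplier applied per the configured scale; works on scalars/arrays."""
    if hr_scale == "rate":
        return 1.0 - (1.0 - p) ** multiplier
    return p * multiplier


class ArmDynamics:
    """Pre-computed per-cycle probabilities and matrices for one arm.

    Builds, for a given configuration and arm, arrays over cycles
    t = 1..horizon:

    - ``p_hosp[k, t-1]`` monthly hospitalization probability for living class
      k (arm and class hazard ratios applied on the configured scale);
    - ``p_cv[k]`` monthly CV-death probability (arm HR on rate scale, class
      relative risk multiplying the probability);
    - ``p_ncv[t-1]`` monthly background mortality at the cohort's age in t;
    - ``matrices[t-1]`` the 6x6 row-stochastic transition matrix;
    - ``survive[k, t-1]`` probability a class-k patient survives cycle t.

    This is the single source of event probabilities for both the cohort
    engine and the patient-level microsimulation.
    """

    def __init__(self, arm: str, config: ModelConfig, horizon_cycles: int | None = None):
        if arm not in config.arms:
            raise KeyError(f"unknown arm {arm!r}")
        self.arm = arm
        self.config = config
        spec = config.arms[arm]
        s = config.settings
        T = config.horizon_cycles if horizon_cycles is None else horizon_cycles
        self.horizon_cycles = T
        cycles = np.arange(1, T + 1, dtype=float)
        self.ages = config.start_age + (cycles - 1.0) / 12.0

        # Baseline monthly hospitalization probability path.
        wb = config.hazard_models["hospitalization_enalapril"]
        g = wb.gamma_shape if wb.gamma_shape is not None else 1.0
        if s.weibull_mode == "calibrated":
            lam = calibrate_weibull_lam(g, config.param("p_hosp_monthly"))
        else:
            lam = wb.lam
        self.weibull_lam = lam
        base_hosp = 1.0 - np.exp(lam * _weibull_increments(g, cycles))

        # Baseline monthly CV-death probability (constant; exponential model).
        base_cv = config.param("p_cv_death_monthly")

        # Arm-level hazard ratios (comparator arm: 1).
        hr_hosp = config.param(spec.hr_hosp_param) if spec.hr_hosp_param else 1.0
        hr_cv = config.param(spec.hr_cv_death_param) if spec.hr_cv_death_param else 1.0

        # Class multipliers relative to the NYHA I/II baseline.
        class_hr_hosp = np.array(
            [1.0, 1.0, config.param("hr_hosp_nyha3"), config.param("hr_hosp_nyha4")]
        )
        class_rr_cv = np.array(
            [1.0, 1.0, config.param("rr_cv_death_nyha3"), config.param("rr_cv_death_nyha4")]
        )

        # (4, T) hospitalization: chained HRs (arm then class) on one scale.
        self.p_hosp = _scaled_prob(
            base_hosp[None, :], (hr_hosp * class_hr_hosp)[:, None], s.hr_scale
        )
        # (4,) CV death: arm HR on the rate scale, class RR on the probability.
        self.p_cv = _scaled_prob(base_cv, hr_cv, s.hr_scale) * class_rr_cv
        # (T,) background non-CV mortality at the cohort's age each cycle.
        self.p_ncv = np.array(
            [background_mortality_monthly(config.mortality_table, a) for a in self.ages]
        )
        self.p_change = config.param(spec.nyha_progress_param)
        self.p_readmit = config.param("p_readmission")
        self.change_rows = np.asarray(config.nyha_change_matrix.rows, dtype=float)

        for label, arr in (("hospitalization", self.p_hosp), ("cv death", self.p_cv),
                           ("non-cv death", self.p_ncv)):
            if np.any(arr < 0.0) or np.any(arr > 1.0):
                raise ValueError(f"adjusted {label} probability outside [0, 1]")
        if not 0.0 <= self.p_change <= 1.0 or not 0.0 <= self.p_readmit <= 1.0:
            raise ValueError("NYHA-change or readmission probability outside [0, 1]")

        # Survival of the cycle (CV death first, then non-CV among survivors).
        self.survive = (1.0 - self.p_cv)[:, None] * (1.0 - self.p_ncv)[None, :]  # (4, T)

        # (T, 6, 6) transition matrices.
        M = np.zeros((T, N_STATES, N_STATES))
        M[:, HealthState.DEATH_CV, HealthState.DEATH_CV] = 1.0
        M[:, HealthState.DEATH_NONCV, HealthState.DEATH_NONCV] = 1.0
        for k in range(N_LIVING):
            M[:, k, HealthState.DEATH_CV] = self.p_cv[k]
            M[:, k, HealthState.DEATH_NONCV] = (1.0 - self.p_cv[k]) * self.p_ncv
            surv = self.survive[k]
            for j in range(N_LIVING):
                if j == k:
                    continue
                M[:, k, j] = surv * self.p_change * self.change_rows[k, j]
            M[:, k, k] = surv * (1.0 - self.p_change)
        self.matrices = M

        rowsums = M.sum(axis=2)
        if np.any(np.abs(rowsums - 1.0) > 1e-9):
            raise ValueError("transition matrix row sums deviate from 1 beyond 1e-9")

        # Unconditional per-cycle event masses for a class-k occupant.
        self.hosp_mass = self.survive * self.p_hosp  # (4, T)
        if s.readmission_mode == "per_hospitalization":
            self.readmit_mass = self.hosp_mass * self.p_readmit
        else:  # unconditional: every cycle survivor is at risk
            self.readmit_mass = self.survive * self.p_readmit

    def event_probabilities(self, nyha_class: int, cycle: int) -> EventProbabilities:
        """Event probabilities for one living class (0-based) and cycle (1-based)."""
        if not 0 <= nyha_class < N_LIVING:
            raise ValueError(f"nyha_class must be 0..3, got {nyha_class}")
        if not 1 <= cycle <= self.horizon_cycles:
            raise ValueError(f"cycle must be 1..{self.horizon_cycles}, got {cycle}")
        t = cycle - 1
        return EventProbabilities(
            p_hosp=float(self.p_hosp[nyha_class, t]),
            p_readmit=float(self.p_readmit),
            p_cv_death=float(self.p_cv[nyha_class]),
            p_noncv_death=float(self.p_ncv[t]),
            p_nyha_change=float(self.p_change),
        )


# ---------------------------------------------------------------------------
# single-cycle API
# ---------------------------------------------------------------------------

def event_probabilities(
    arm: str, nyha_class: int, cycle: int, config: ModelConfig
) -> EventProbabilities:
    """Monthly event probabilities for one (arm, class, cycle) under ``config``.

    ``nyha_class`` is 0-based (0 = NYHA I).  The cohort age in the cycle is
    implied by the configured start age.
    """
    dyn = ArmDynamics(arm, config, horizon_cycles=max(cycle, 1))
    return dyn.event_probabilities(nyha_class, cycle)


def build_transition_matrix(arm: str, cycle: int, config: ModelConfig) -> TransitionMatrix:
    """The 6x6 row-stochastic matrix for one cycle, with event decomposition."""
    dyn = ArmDynamics(arm, config, horizon_cycles=max(cycle, 1))
    return TransitionMatrix(
        arm=arm,
        cycle=cycle,
        matrix=dyn.matrices[cycle - 1].copy(),
        events=tuple(dyn.event_probabilities(k, cycle) for k in range(N_LIVING)),
    )


def transition_matrices_frame(arm: str, config: ModelConfig):
    """All per-cycle matrices in long form (cycle, from, to, probability).

    Returns a :class:`pandas.DataFrame` suitable for CSV export and audit.
    """
    import pandas as pd

    dyn = ArmDynamics(arm, config)
    names = [s.name for s in HealthState]
    T = dyn.horizon_cycles
    cyc = np.repeat(np.arange(1, T + 1), N_STATES * N_STATES)
    frm = np.tile(np.repeat(np.arange(N_STATES), N_STATES), T)
    to = np.tile(np.arange(N_STATES), T * N_STATES)
    return pd.DataFrame(
        {
            "cycle": cyc,
            "from": [names[i] for i in frm],
            "to": [names[i] for i in to],
            "probability": dyn.matrices.reshape(-1),
        }
    )
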