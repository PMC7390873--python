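"""Comparative cost-effectiveness: ICER, net monetary benefit, price thresholds.

Incrementals are always intervention minus comparator.  The ICER is reported
only when the increments share a quadrant that admits a ratio; strict
dominance (more effect for less cost, or the reverse) is flagged instead,
following standard CEA conventions.  Net monetary benefit at a
willingness-to-pay w is NMB(w) = w * dQALY - dCost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy.optimize import brentq

from .cohort import CohortResult, run_cohort
from .params import ModelConfig, with_parameter_values

__all__ = ["CEResult", "ThresholdResult", "icer", "nmb", "breakeven_price", "two_way_grid"]


@dataclass(frozen=True)
class CEResult:
    """Incremental cost-effectiveness summary of intervention vs comparator."""

    intervention: str
    comparator: str
    cost_intervention: float
    cost_comparator: float
    qaly_intervention: float
    qaly_comparator: float
    d_cost: float
    d_qaly: float
    icer: float | None          # None when undefined or dominated/dominant
    dominance: str              # "", "dominant", "dominated", "undefined"
    nmb: dict[float, float] = field(default_factory=dict)


@dataclass(frozen=True)
class ThresholdResult:
    """Break-even intervention price at one willingness-to-pay threshold."""

    wtp: float
    comparator_monthly_cost: float
    breakeven_monthly_cost: float
    converged: bool             # False: no sign change, boundary reported
    nmb_at_breakeven: float


def nmb(wtp: float, d_qaly: float, d_cost: float) -> float:
    """Incremental net monetary benefit at willingness-to-pay ``wtp``."""
    return wtp * d_qaly - d_cost


def icer(
    intervention: CohortResult,
    comparator: CohortResult,
    wtp_thresholds: tuple[float, ...] = (),
) -> CEResult:
    """Incremental comparison of two cohort runs (same config, different arm)."""
    d_cost = intervention.total_cost - comparator.total_cost
    d_qaly = intervention.total_qaly - comparator.total_qaly

    dominance = ""
    ratio: float | None = None
    if d_qaly == 0.0:
        dominance = "undefined"
    elif d_qaly > 0 and d_cost < 0:
        dominance = "dominant"
    elif d_qaly < 0 and d_cost > 0:
        dominance = "dominated"
    else:
        ratio = d_cost / d_qaly

    return CEResult(
        intervention=intervention.arm,
        comparator=comparator.arm,
        cost_intervention=intervention.total_cost,
        cost_comparator=comparator.total_cost,
        qaly_intervention=intervention.total_qaly,
        qaly_comparator=comparator.total_qaly,
        d_cost=d_cost,
        d_qaly=d_qaly,
        icer=ratio,
        dominance=dominance,
        nmb={w: nmb(w, d_qaly, d_cost) for w in wtp_thresholds},
    )


def _nmb_at_prices(
    config: ModelConfig,
    intervention_cost: float,
    comparator_cost: float,
    wtp: float,
    _comparator_cache: dict | None = None,
) -> float:
    """NMB from full paired model runs at the given monthly patient costs."""
    i_arm, c_arm = config.intervention_arm, config.comparator_arm
    i_param = config.arms[i_arm].drug_cost_param
    c_param = config.arms[c_arm].drug_cost_param
    cfg = with_parameter_values(
        config, {i_param: intervention_cost, c_param: comparator_cost}
    )
    res_i = run_cohort(i_arm, cfg)
    if _comparator_cache is not None and comparator_cost in _comparator_cache:
        res_c = _comparator_cache[comparator_cost]
    else:
        res_c = run_cohort(c_arm, cfg)
        if _comparator_cache is not None:
            _comparator_cache[comparator_cost] = res_c
    ce = icer(res_i, res_c)
    return nmb(wtp, ce.d_qaly, ce.d_cost)


def breakeven_price(
    wtp: float,
    comparator_monthly_cost: float,
    config: ModelConfig,
    price_bracket: tuple[float, float] = (0.0, 150.0),
    tol: float = 0.01,
) -> ThresholdResult:
    """Intervention monthly patient cost at which NMB(wtp) crosses zero.

    Bracketed root finding over full paired model runs; the search operates
    on the patient-borne monthly cost (the decision quantity under the
    reimbursement scheme).  When NMB does not change sign inside the bracket,
    the nearer boundary is reported with ``converged=False``.
    """
    if wtp < 0:
        raise ValueError(f"wtp must be >= 0, got {wtp}")
    cache: dict = {}

    def f(price: float) -> float:
        return _nmb_at_prices(config, price, comparator_monthly_cost, wtp, cache)

    lo, hi = price_bracket
    f_lo, f_hi = f(lo), f(hi)
    if f_lo * f_hi > 0:
        # NMB is decreasing in the intervention price: positive everywhere
        # means even the top price is cost-effective, and vice versa.
        price = hi if f_lo > 0 else lo
        return ThresholdResult(wtp, comparator_monthly_cost, price, False, f(price))
    root = float(brentq(f, lo, hi, xtol=tol / 10.0))
    return ThresholdResult(wtp, comparator_monthly_cost, root, True, f(root))


def two_way_grid(
    intervention_costs,
    comparator_costs,
    wtp_thresholds,
    config: ModelConfig,
):
    """Cost-effectiveness labels over a grid of the two monthly drug prices.

    Returns a long-format :class:`pandas.DataFrame` with columns
    ``intervention_cost``, ``comparator_cost``, ``wtp``, ``nmb``,
    ``cost_effective``.  QALYs do not depend on drug prices, so each axis
    value requires a single cohort run.
    """
    import pandas as pd

    i_arm, c_arm = config.intervention_arm, config.comparator_arm
    i_param = config.arms[i_arm].drug_cost_param
    c_param = config.arms[c_arm].drug_cost_param

    runs_i = {
        a: run_cohort(i_arm, with_parameter_values(config, {i_param: float(a)}))
        for a in intervention_costs
    }
    runs_c = {
        b: run_cohort(c_arm, with_parameter_values(config, {c_param: float(b)}))
        for b in comparator_costs
    }
    rows = []
    for a, res_i in runs_i.items():
        for b, res_c in runs_c.items():
            ce = icer(res_i, res_c)
            for w in wtp_thresholds:
                value = nmb(w, ce.d_qaly, ce.d_cost)
                rows.append(
                    {
                        "intervention_cost": float(a),
                        "comparator_cost": float(b),
                        "wtp": float(w),
                        "nmb": value,
                        "cost_effective": value > 0,
                    }
                )
    return pd.DataFrame(rows)
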