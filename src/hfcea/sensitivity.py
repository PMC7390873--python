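"""Deterministic and probabilistic sensitivity analyses.

One-way analysis re-runs the paired model at each parameter's published
bounds and orders parameters by the spread of the resulting ICERs (tornado
ordering).  The probabilistic analysis fits a sampling distribution to every
non-fixed parameter — beta for probabilities and utilities, log-normal for
hazard/risk ratios, gamma for costs — by moment matching, treating the
published range as a 95% interval (sd = (up - low) / (2 * 1.96)); log-normal
ratios keep the point estimate as the median.  Event disutilities are
sampled as a beta-distributed magnitude rescaled to the published band.
All parameters vary independently and simultaneously across draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cohort import run_cohort
from .economics import icer, nmb
from .params import ModelConfig, ParameterSpec, with_parameter_values

__all__ = [
    "TornadoEntry",
    "DistributionSpec",
    "PSASample",
    "PSAResult",
    "CEACPoint",
    "one_way_dsa",
    "fit_beta",
    "fit_gamma",
    "fit_lognormal",
    "fit_distribution",
    "run_psa",
    "ceac",
]

_Z95 = 2.0 * 1.959963984540054  # full width of a 95% normal interval, in sds


@dataclass(frozen=True)
class TornadoEntry:
    """One-way sensitivity result for a single parameter."""

    name: str
    icer_low: float     # ICER with the parameter at its low bound (nan if undefined)
    icer_high: float    # ICER at the high bound
    span: float         # |icer_high - icer_low|
    skipped: str | None = None  # reason the parameter could not be evaluated


@dataclass(frozen=True)
class DistributionSpec:
    """A fitted sampling distribution for one parameter.

    ``loc``/``scale`` rescale the beta family to a non-unit support and
    ``negate`` flips the sign after sampling (used for disutilities, which
    are sampled as a positive magnitude on the published band).
    """

    family: str                      # "beta" | "lognormal" | "gamma" | "fixed"
    params: dict[str, float]
    source: tuple[float, float, float]  # (mean/point, low, up)
    loc: float = 0.0
    scale: float = 1.0
    negate: bool = False

    def mean(self) -> float:
        if self.family == "beta":
            a, b = self.params["alpha"], self.params["beta"]
            m = a / (a + b)
        elif self.family == "gamma":
            m = self.params["shape"] * self.params["scale"]
        elif self.family == "lognormal":
            m = math.exp(self.params["mu"] + self.params["sigma"] ** 2 / 2.0)
        else:
            m = self.params["value"]
        m = self.loc + self.scale * m
        return -m if self.negate else m

    def sample(self, rng: np.random.Generator, size=None):
        if self.family == "beta":
            x = rng.beta(self.params["alpha"], self.params["beta"], size=size)
        elif self.family == "gamma":
            x = rng.gamma(self.params["shape"], self.params["scale"], size=size)
        elif self.family == "lognormal":
            x = rng.lognormal(self.params["mu"], self.params["sigma"], size=size)
        else:  # fixed
            x = self.params["value"] if size is None else np.full(size, self.params["value"])
        x = self.loc + self.scale * x
        return -x if self.negate else x


@dataclass(frozen=True)
class PSASample:
    """One Monte Carlo draw: sampled parameters and paired-arm outcomes."""

    index: int
    values: dict[str, float]
    cost_intervention: float
    cost_comparator: float
    qaly_intervention: float
    qaly_comparator: float

    @property
    def d_cost(self) -> float:
        return self.cost_intervention - self.cost_comparator

    @property
    def d_qaly(self) -> float:
        return self.qaly_intervention - self.qaly_comparator


@dataclass(frozen=True)
class CEACPoint:
    """Probability the intervention is cost-effective at one WTP value."""

    wtp: float
    probability: float


@dataclass
class PSAResult:
    """All draws of a probabilistic sensitivity analysis plus summaries."""

    seed: int
    samples: list[PSASample]

    def frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "draw": [s.index for s in self.samples],
                "cost_intervention": [s.cost_intervention for s in self.samples],
                "cost_comparator": [s.cost_comparator for s in self.samples],
                "qaly_intervention": [s.qaly_intervention for s in self.samples],
                "qaly_comparator": [s.qaly_comparator for s in self.samples],
                "d_cost": [s.d_cost for s in self.samples],
                "d_qaly": [s.d_qaly for s in self.samples],
            }
        )

    def summary(self):
        """Mean and 2.5/97.5 percentiles of cost and QALY per arm."""
        import pandas as pd

        df = self.frame()
        rows = []
        for arm, cost_col, qaly_col in (
            ("intervention", "cost_intervention", "qaly_intervention"),
            ("comparator", "cost_comparator", "qaly_comparator"),
        ):
            for quantity, col in (("cost", cost_col), ("qaly", qaly_col)):
                x = df[col].to_numpy()
                rows.append(
                    {
                        "arm": arm,
                        "quantity": quantity,
                        "mean": float(x.mean()),
                        "p2.5": float(np.percentile(x, 2.5)),
                        "p97.5": float(np.percentile(x, 97.5)),
                    }
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# distribution fitting
# ---------------------------------------------------------------------------

def _range_sd(low: float, up: float) -> float:
    return (up - low) / _Z95


def fit_beta(mean: float, low: float, up: float) -> DistributionSpec:
    """Beta by moment matching on [0, 1]; degenerate range gives a point mass."""
    if not 0.0 <= mean <= 1.0:
        raise ValueError(f"beta mean must be in [0, 1], got {mean}")
    sd = _range_sd(low, up)
    if sd <= 0.0 or mean in (0.0, 1.0):
        return DistributionSpec("fixed", {"value": mean}, (mean, low, up))
    nu = mean * (1.0 - mean) / sd**2 - 1.0
    if nu <= 0.0:
        raise ValueError(f"beta moment matching infeasible: mean={mean}, sd={sd}")
    return DistributionSpec(
        "beta", {"alpha": mean * nu, "beta": (1.0 - mean) * nu}, (mean, low, up)
    )


def fit_gamma(mean: float, low: float, up: float) -> DistributionSpec:
    """Gamma by moment matching; degenerate range gives a point mass."""
    if mean < 0.0:
        raise ValueError(f"gamma mean must be >= 0, got {mean}")
    sd = _range_sd(low, up)
    if sd <= 0.0 or mean == 0.0:
        return DistributionSpec("fixed", {"value": mean}, (mean, low, up))
    return DistributionSpec(
        "gamma", {"shape": mean**2 / sd**2, "scale": sd**2 / mean}, (mean, low, up)
    )


def fit_lognormal(point: float, ci_low: float, ci_up: float) -> DistributionSpec:
    """Log-normal with the point estimate as median and the CI setting sigma."""
    if point <= 0.0 or ci_low <= 0.0 or ci_up <= 0.0:
        raise ValueError("log-normal requires positive point and bounds")
    if ci_low == ci_up:
        return DistributionSpec("fixed", {"value": point}, (point, ci_low, ci_up))
    return DistributionSpec(
        "lognormal",
        {"mu": math.log(point), "sigma": (math.log(ci_up) - math.log(ci_low)) / _Z95},
        (point, ci_low, ci_up),
    )


def fit_distribution(p: ParameterSpec) -> DistributionSpec:
    """Fit the configured sampling distribution for one parameter."""
    if p.dist == "fixed":
        return DistributionSpec("fixed", {"value": p.value}, (p.value, p.low, p.up))
    if p.kind == "disutility":
        # Sample the magnitude as a beta on the published band, then negate.
        lo_mag, up_mag = -p.up, -p.low
        width = up_mag - lo_mag
        if width <= 0.0:
            return DistributionSpec("fixed", {"value": p.value}, (p.value, p.low, p.up))
        mean_unit = (-p.value - lo_mag) / width
        sd_unit = _range_sd(p.low, p.up) / width
        nu = mean_unit * (1.0 - mean_unit) / sd_unit**2 - 1.0
        if nu <= 0.0:
            raise ValueError(f"disutility beta infeasible for {p.name}")
        return DistributionSpec(
            "beta",
            {"alpha": mean_unit * nu, "beta": (1.0 - mean_unit) * nu},
            (p.value, p.low, p.up),
            loc=lo_mag,
            scale=width,
            negate=True,
        )
    if p.dist == "beta":
        return fit_beta(p.value, p.low, p.up)
    if p.dist == "gamma":
        return fit_gamma(p.value, p.low, p.up)
    if p.dist == "lognormal":
        return fit_lognormal(p.value, p.low, p.up)
    raise ValueError(f"unknown distribution {p.dist!r} for {p.name}")


# ---------------------------------------------------------------------------
# one-way deterministic sensitivity (tornado)
# ---------------------------------------------------------------------------

def _paired_icer(config: ModelConfig) -> float:
    ce = icer(run_cohort(config.intervention_arm, config),
              run_cohort(config.comparator_arm, config))
    return math.nan if ce.icer is None else ce.icer


def one_way_dsa(config: ModelConfig, parameters=None) -> list[TornadoEntry]:
    """One-way sensitivity of the ICER to each parameter's published bounds.

    For every parameter (or the given subset), both arms are re-run with the
    parameter at its low and at its high bound, everything else at base case.
    Entries are sorted by descending ICER span; parameters whose bounds make
    the model infeasible are returned last with a skip reason.
    """
    names = list(parameters) if parameters is not None else list(config.parameters)
    entries: list[TornadoEntry] = []
    for name in names:
        p = config.parameters[name]
        if config.settings.weibull_mode == "raw" and name == "p_hosp_monthly":
            entries.append(TornadoEntry(name, math.nan, math.nan, math.nan,
                                        "anchor unused in raw weibull mode"))
            continue
        try:
            lo = _paired_icer(with_parameter_values(config, {name: p.low}))
            hi = _paired_icer(with_parameter_values(config, {name: p.up}))
        except (ValueError, KeyError) as exc:
            entries.append(TornadoEntry(name, math.nan, math.nan, math.nan, str(exc)))
            continue
        span = abs(hi - lo)
        entries.append(TornadoEntry(name, lo, hi, span))
    entries.sort(key=lambda e: (e.skipped is not None, -(e.span if e.span == e.span else -1.0)))
    return entries


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

_MAX_REJECTION_RETRIES = 100


def _sample_parameters(
    specs: dict[str, tuple[ParameterSpec, DistributionSpec]],
    rng: np.random.Generator,
) -> dict[str, float]:
    values: dict[str, float] = {}
    for name in specs:  # dict order is the registry order: deterministic
        p, dist = specs[name]
        for _ in range(_MAX_REJECTION_RETRIES):
            x = float(dist.sample(rng))
            if p.kind == "probability" and not 0.0 < x < 1.0:
                continue
            values[name] = x
            break
        else:
            raise RuntimeError(f"rejection sampling failed for {name}")
    return values


def run_psa(config: ModelConfig, n_draws: int | None = None, seed: int | None = None) -> PSAResult:
    """Second-order Monte Carlo PSA: all parameters vary simultaneously.

    Every non-fixed parameter is drawn independently from its fitted
    distribution; both arms are run per draw.  Draws use per-draw random
    substreams spawned from the master seed, so results are reproducible and
    independent of evaluation order.
    """
    n = config.psa_draws if n_draws is None else int(n_draws)
    if n < 1:
        raise ValueError(f"n_draws must be >= 1, got {n}")
    master = config.seed if seed is None else int(seed)

    specs = {
        name: (p, fit_distribution(p))
        for name, p in config.parameters.items()
        if p.dist != "fixed"
    }
    streams = np.random.SeedSequence(master).spawn(n)
    samples: list[PSASample] = []
    i_arm, c_arm = config.intervention_arm, config.comparator_arm
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        values = _sample_parameters(specs, rng)
        cfg = with_parameter_values(config, values)
        res_i = run_cohort(i_arm, cfg)
        res_c = run_cohort(c_arm, cfg)
        samples.append(
            PSASample(
                index=i,
                values=values,
                cost_intervention=res_i.total_cost,
                cost_comparator=res_c.total_cost,
                qaly_intervention=res_i.total_qaly,
                qaly_comparator=res_c.total_qaly,
            )
        )
    return PSAResult(seed=master, samples=samples)


def ceac(samples: list[PSASample], wtp_grid) -> list[CEACPoint]:
    """Cost-effectiveness acceptability curve from PSA draws.

    At each willingness-to-pay value, the fraction of draws with positive
    incremental net monetary benefit.
    """
    if not samples:
        raise ValueError("ceac requires at least one PSA sample")
    d_qaly = np.array([s.d_qaly for s in samples])
    d_cost = np.array([s.d_cost for s in samples])
    points = []
    for w in wtp_grid:
        frac = float(np.mean(nmb(float(w), d_qaly, d_cost) > 0.0))
        points.append(CEACPoint(wtp=float(w), probability=frac))
    return points
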