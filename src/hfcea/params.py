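"""Model inputs: parameter registry, configuration loading and validation.

Every quantity the model reads — baseline event probabilities, treatment
hazard ratios, NYHA-class relative risks, utilities, one-time event
disutilities, drug and healthcare costs, the background non-cardiovascular
mortality life table and the NYHA class-change destination matrix — lives in
a single :class:`ModelConfig`.  The packaged default configuration
(``hfcea/data/default_config.yaml``) holds the published base-case values for
the sacubitril-valsartan vs enalapril comparison in the Chinese setting; any
run-time variation (scenario overrides, deterministic and probabilistic
sensitivity analyses) goes through copies of that object, never mutation.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "ParameterSpec",
    "HazardModelSpec",
    "MortalityTable",
    "NyhaChangeMatrix",
    "DrugCostSpec",
    "ArmSpec",
    "Settings",
    "ModelConfig",
    "Finding",
    "ConfigError",
    "default_config",
    "load_config",
    "save_config",
    "config_to_dict",
    "config_from_dict",
    "validate",
    "with_parameter_values",
    "with_overrides",
]

DISTRIBUTIONS = ("beta", "lognormal", "gamma", "fixed")
KINDS = (
    "probability",
    "hazard_ratio",
    "relative_risk",
    "utility",
    "disutility",
    "cost",
    "rate",
)

NYHA_CLASSES = ("I", "II", "III", "IV")


class ConfigError(ValueError):
    """Raised when a configuration file cannot be parsed or fails validation."""


@dataclass(frozen=True)
class Finding:
    """One validation finding: the offending parameter and the violated rule."""

    parameter: str
    rule: str
    message: str
    severity: str = "error"  # "error" | "warning"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.severity}] {self.parameter}: {self.rule} — {self.message}"


@dataclass(frozen=True)
class ParameterSpec:
    """A scalar model input with its plausible range and PSA distribution.

    ``value`` is the base case; ``low``/``up`` bound the deterministic
    sensitivity range (95% CI or the stated ±5/10/20% band); ``dist`` names
    the probabilistic-sensitivity family (``fixed`` parameters are never
    sampled); ``kind`` drives validation and distribution fitting.
    """

    name: str
    value: float
    low: float
    up: float
    dist: str
    kind: str


@dataclass(frozen=True)
class HazardModelSpec:
    """A parametric monthly survival model, S(t) = exp(lam * t**gamma_shape).

    ``lam`` is the signed coefficient as published (negative for decaying
    survival).  ``gamma_shape`` is the Weibull shape; ``None`` for the
    exponential family (equivalent to shape 1).
    """

    family: str  # "weibull" | "exponential"
    lam: float
    gamma_shape: float | None = None


@dataclass(frozen=True)
class MortalityTable:
    """Age-indexed annual background (non-cardiovascular) death probabilities.

    Lookup is a left step function: the entry with the greatest tabulated age
    not exceeding the query age applies.
    """

    entries: tuple[tuple[float, float], ...]

    def annual_prob(self, age: float) -> float:
        ages = [a for a, _ in self.entries]
        if age < ages[0]:
            raise ValueError(f"age {age} below first tabulated age {ages[0]}")
        idx = bisect_right(ages, age) - 1
        return self.entries[idx][1]


@dataclass(frozen=True)
class NyhaChangeMatrix:
    """Conditional destination distribution of a NYHA class change.

    ``rows[i][j]`` is the probability that a patient in class i+1 who changes
    class this cycle lands in class j+1.  Diagonals are structurally zero; a
    change always moves the patient.
    """

    rows: tuple[tuple[float, float, float, float], ...]


@dataclass(frozen=True)
class DrugCostSpec:
    """Published drug pricing: list price, reimbursement, patient-borne cost.

    ``copay_ratio`` is the reimbursed share of the monthly list price, so the
    monthly patient-borne cost is ``monthly_price * (1 - copay_ratio)``.
    """

    unit_price: float
    copay_ratio: float
    monthly_price: float
    monthly_cost: float


@dataclass(frozen=True)
class ArmSpec:
    """One treatment arm: its drug pricing and the parameters it reads.

    The ``*_param`` fields name entries of ``ModelConfig.parameters`` so that
    sensitivity analyses vary a single registry, not per-arm copies.
    ``hr_hosp_param``/``hr_cv_death_param`` are ``None`` for the comparator
    arm (multiplier 1).
    """

    name: str
    drug: DrugCostSpec
    drug_cost_param: str
    nyha_progress_param: str
    hr_hosp_param: str | None = None
    hr_cv_death_param: str | None = None


@dataclass(frozen=True)
class Settings:
    """Model conventions that the source description leaves open.

    weibull_mode
        ``"calibrated"`` (default): the Weibull scale coefficient for
        hospitalization is re-solved so the mean monthly hospitalization
        probability over the 120-cycle reference window equals the
        ``p_hosp_monthly`` parameter (the anchor).  ``"raw"``: use the
        published coefficient verbatim (audit mode; the anchor is ignored).
    hr_scale
        ``"rate"``: hazard ratios act on the log-survival (rate) scale,
        p' = 1 - (1 - p)**hr.  ``"probability"``: plain multiplication.
    readmission_mode
        ``"per_hospitalization"`` (default): each hospitalization carries the
        30-day readmission probability within the same cycle.
        ``"unconditional"``: every cycle survivor is at risk of readmission.
    disutility_mode
        ``"per_event"`` (default): the one-time event disutility is a full
        QALY decrement per expected event.  ``"per_month"``: decrement spread
        over one month (value / 12).
    inpatient_copay_is_patient_share
        True (default): the inpatient copay ratio is the fraction of event
        costs the patient pays.  False: it is the reimbursed fraction.
    """

    weibull_mode: str = "calibrated"
    hr_scale: str = "rate"
    readmission_mode: str = "per_hospitalization"
    disutility_mode: str = "per_event"
    inpatient_copay_is_patient_share: bool = True


@dataclass(frozen=True)
class ModelConfig:
    """The complete, immutable input set for one model run."""

    horizon_cycles: int
    start_age: float
    discount_rate_annual: float
    initial_nyha_distribution: tuple[float, float, float, float]
    wtp_thresholds: tuple[float, ...]
    psa_draws: int
    seed: int
    settings: Settings
    parameters: Mapping[str, ParameterSpec]
    hazard_models: Mapping[str, HazardModelSpec]
    mortality_table: MortalityTable
    nyha_change_matrix: NyhaChangeMatrix
    arms: Mapping[str, ArmSpec]

    # -- convenience accessors -------------------------------------------------
    def param(self, name: str) -> float:
        return self.parameters[name].value

    @property
    def intervention_arm(self) -> str:
        return "sacval"

    @property
    def comparator_arm(self) -> str:
        return "enalapril"


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_TOP_KEYS = {
    "horizon_cycles",
    "start_age",
    "discount_rate_annual",
    "initial_nyha_distribution",
    "wtp_thresholds",
    "psa_draws",
    "seed",
    "settings",
    "parameters",
    "hazard_models",
    "mortality_table",
    "nyha_change_matrix",
    "arms",
}

_SETTINGS_KEYS = {
    "weibull_mode",
    "hr_scale",
    "readmission_mode",
    "disutility_mode",
    "inpatient_copay_is_patient_share",
}
_PARAM_KEYS = {"value", "low", "up", "dist", "kind"}
_HAZARD_KEYS = {"family", "lam", "gamma_shape"}
_DRUG_KEYS = {"unit_price", "copay_ratio", "monthly_price", "monthly_cost"}
_ARM_KEYS = {
    "drug",
    "drug_cost_param",
    "nyha_progress_param",
    "hr_hosp_param",
    "hr_cv_death_param",
}


def _reject_unknown(mapping: Mapping, allowed: set[str], where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}")


def config_to_dict(config: ModelConfig) -> dict:
    """Plain-dict (YAML/JSON ready) form of a configuration."""
    return {
        "horizon_cycles": config.horizon_cycles,
        "start_age": config.start_age,
        "discount_rate_annual": config.discount_rate_annual,
        "initial_nyha_distribution": list(config.initial_nyha_distribution),
        "wtp_thresholds": list(config.wtp_thresholds),
        "psa_draws": config.psa_draws,
        "seed": config.seed,
        "settings": {
            "weibull_mode": config.settings.weibull_mode,
            "hr_scale": config.settings.hr_scale,
            "readmission_mode": config.settings.readmission_mode,
            "disutility_mode": config.settings.disutility_mode,
            "inpatient_copay_is_patient_share": config.settings.inpatient_copay_is_patient_share,
        },
        "parameters": {
            name: {
                "value": p.value,
                "low": p.low,
                "up": p.up,
                "dist": p.dist,
                "kind": p.kind,
            }
            for name, p in config.parameters.items()
        },
        "hazard_models": {
            name: (
                {"family": h.family, "lam": h.lam}
                | ({"gamma_shape": h.gamma_shape} if h.gamma_shape is not None else {})
            )
            for name, h in config.hazard_models.items()
        },
        "mortality_table": [list(e) for e in config.mortality_table.entries],
        "nyha_change_matrix": [list(r) for r in config.nyha_change_matrix.rows],
        "arms": {
            name: {
                "drug": {
                    "unit_price": a.drug.unit_price,
                    "copay_ratio": a.drug.copay_ratio,
                    "monthly_price": a.drug.monthly_price,
                    "monthly_cost": a.drug.monthly_cost,
                },
                "drug_cost_param": a.drug_cost_param,
                "nyha_progress_param": a.nyha_progress_param,
                "hr_hosp_param": a.hr_hosp_param,
                "hr_cv_death_param": a.hr_cv_death_param,
            }
            for name, a in config.arms.items()
        },
    }


def config_from_dict(data: Mapping) -> ModelConfig:
    """Build a :class:`ModelConfig` from a plain mapping, rejecting unknown keys."""
    if not isinstance(data, Mapping):
        raise ConfigError("configuration root must be a mapping")
    _reject_unknown(data, _TOP_KEYS, "configuration root")
    missing = _TOP_KEYS - set(data)
    if missing:
        raise ConfigError(f"missing configuration key(s) {sorted(missing)}")

    settings_d = data["settings"]
    _reject_unknown(settings_d, _SETTINGS_KEYS, "settings")
    settings = Settings(**settings_d)

    params = {}
    for name, pd in data["parameters"].items():
        _reject_unknown(pd, _PARAM_KEYS, f"parameters.{name}")
        params[name] = ParameterSpec(name=name, **{k: pd[k] for k in _PARAM_KEYS})

    hazards = {}
    for name, hd in data["hazard_models"].items():
        _reject_unknown(hd, _HAZARD_KEYS, f"hazard_models.{name}")
        hazards[name] = HazardModelSpec(
            family=hd["family"], lam=float(hd["lam"]),
            gamma_shape=(float(hd["gamma_shape"]) if hd.get("gamma_shape") is not None else None),
        )

    arms = {}
    for name, ad in data["arms"].items():
        _reject_unknown(ad, _ARM_KEYS, f"arms.{name}")
        dd = ad["drug"]
        _reject_unknown(dd, _DRUG_KEYS, f"arms.{name}.drug")
        arms[name] = ArmSpec(
            name=name,
            drug=DrugCostSpec(**{k: float(dd[k]) for k in _DRUG_KEYS}),
            drug_cost_param=ad["drug_cost_param"],
            nyha_progress_param=ad["nyha_progress_param"],
            hr_hosp_param=ad.get("hr_hosp_param"),
            hr_cv_death_param=ad.get("hr_cv_death_param"),
        )

    init = tuple(float(x) for x in data["initial_nyha_distribution"])
    if len(init) != 4:
        raise ConfigError("initial_nyha_distribution must have 4 entries")

    return ModelConfig(
        horizon_cycles=int(data["horizon_cycles"]),
        start_age=float(data["start_age"]),
        discount_rate_annual=float(data["discount_rate_annual"]),
        initial_nyha_distribution=init,  # type: ignore[arg-type]
        wtp_thresholds=tuple(float(w) for w in data["wtp_thresholds"]),
        psa_draws=int(data["psa_draws"]),
        seed=int(data["seed"]),
        settings=settings,
        parameters=params,
        hazard_models=hazards,
        mortality_table=MortalityTable(
            entries=tuple((float(a), float(p)) for a, p in data["mortality_table"])
        ),
        nyha_change_matrix=NyhaChangeMatrix(
            rows=tuple(tuple(float(x) for x in r) for r in data["nyha_change_matrix"])
        ),
        arms=arms,
    )


def default_config() -> ModelConfig:
    """The packaged base-case configuration (all published table values)."""
    text = resources.files("hfcea.data").joinpath("default_config.yaml").read_text()
    return config_from_dict(yaml.safe_load(text))


def load_config(path: str | Path, fill_defaults: bool = False) -> ModelConfig:
    """Load and validate a configuration file (YAML; JSON is a YAML subset).

    Unknown keys are rejected.  Missing top-level keys are an error unless
    ``fill_defaults`` is set, in which case they are taken from the packaged
    default configuration.  Raises :class:`ConfigError` on parse failure or
    on any error-severity validation finding.
    """
    path = Path(path)
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:  # pragma: no cover - message plumbing
        mark = getattr(exc, "problem_mark", None)
        line = f" at line {mark.line + 1}" if mark is not None else ""
        raise ConfigError(f"cannot parse {path}{line}: {exc}") from exc
    if fill_defaults:
        base = config_to_dict(default_config())
        if not isinstance(data, Mapping):
            raise ConfigError("configuration root must be a mapping")
        merged = dict(base)
        for key, value in data.items():
            if key in ("parameters", "settings", "arms", "hazard_models") and isinstance(value, Mapping):
                sub = dict(base[key])
                for k, v in value.items():
                    if key == "parameters" and k in sub and isinstance(v, Mapping):
                        sub[k] = {**sub[k], **v}
                    else:
                        sub[k] = v
                merged[key] = sub
            else:
                merged[key] = value
        data = merged
    config = config_from_dict(data)
    errors = [f for f in validate(config) if f.severity == "error"]
    if errors:
        raise ConfigError("; ".join(str(f) for f in errors))
    return config


def save_config(config: ModelConfig, path: str | Path) -> None:
    """Serialize a configuration to YAML (round-trips through load_config)."""
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

# Parameters whose published sensitivity band is printed on a different scale
# than the base value (the hospitalization band is a monthly-probability range
# while the base value derives from the published Weibull coefficients); the
# low <= value <= up warning does not apply to them.
RANGE_SCALE_EXEMPT = frozenset({"p_hosp_monthly"})


def _check_param(p: ParameterSpec, findings: list[Finding]) -> None:
    if p.dist not in DISTRIBUTIONS:
        findings.append(Finding(p.name, "dist", f"unknown distribution {p.dist!r}"))
    if p.kind not in KINDS:
        findings.append(Finding(p.name, "kind", f"unknown kind {p.kind!r}"))
    if p.name not in RANGE_SCALE_EXEMPT and not (p.low <= p.value <= p.up):
        findings.append(
            Finding(p.name, "range", f"value {p.value} outside [{p.low}, {p.up}]",
                    severity="warning")
        )
    if p.kind == "probability":
        for label, v in (("value", p.value), ("low", p.low), ("up", p.up)):
            if not 0.0 <= v <= 1.0:
                findings.append(Finding(p.name, "probability-bounds",
                                        f"{label} {v} outside [0, 1]"))
    elif p.kind == "utility":
        if not 0.0 <= p.value <= 1.0:
            findings.append(Finding(p.name, "utility-bounds",
                                    f"value {p.value} outside [0, 1]"))
    elif p.kind == "disutility":
        if not -1.0 <= p.value <= 0.0:
            findings.append(Finding(p.name, "disutility-bounds",
                                    f"value {p.value} outside [-1, 0]"))
    elif p.kind == "cost":
        if p.value < 0:
            findings.append(Finding(p.name, "cost-nonnegative",
                                    f"value {p.value} < 0"))


def validate(config: ModelConfig) -> list[Finding]:
    """Check every structural invariant; returns findings, raises nothing."""
    f: list[Finding] = []

    if config.horizon_cycles < 1:
        f.append(Finding("horizon_cycles", "horizon", "must be >= 1"))
    if config.discount_rate_annual < 0:
        f.append(Finding("discount_rate_annual", "discount", "must be >= 0"))
    if config.psa_draws < 1:
        f.append(Finding("psa_draws", "psa-draws", "must be >= 1"))

    init = config.initial_nyha_distribution
    if any(x < 0 for x in init):
        f.append(Finding("initial_nyha_distribution", "nonnegative", f"entries {init}"))
    if abs(sum(init) - 1.0) > 1e-9:
        f.append(Finding("initial_nyha_distribution", "sum-to-one",
                         f"sums to {sum(init)!r}"))

    for name, p in config.parameters.items():
        _check_param(p, f)

    for name, h in config.hazard_models.items():
        if h.family not in ("weibull", "exponential"):
            f.append(Finding(name, "hazard-family", f"unknown family {h.family!r}"))
        if h.family == "exponential" and h.gamma_shape is not None:
            f.append(Finding(name, "hazard-shape", "exponential model carries a shape"))
        if h.family == "weibull" and h.gamma_shape is None:
            f.append(Finding(name, "hazard-shape", "weibull model missing shape"))
        if h.lam >= 0:
            f.append(Finding(name, "hazard-sign", f"lam {h.lam} must be < 0"))

    entries = config.mortality_table.entries
    ages = [a for a, _ in entries]
    if ages != sorted(set(ages)):
        f.append(Finding("mortality_table", "ages-increasing", f"ages {ages}"))
    if not entries or entries[-1] != (100.0, 1.0):
        f.append(Finding("mortality_table", "terminal-entry",
                         "final entry must be (100, 1.0)"))
    for a, p in entries:
        if not 0.0 <= p <= 1.0:
            f.append(Finding("mortality_table", "probability-bounds",
                             f"annual prob {p} at age {a}"))

    for i, row in enumerate(config.nyha_change_matrix.rows):
        if abs(sum(row) - 1.0) > 1e-9:
            f.append(Finding(f"nyha_change_matrix.row_{NYHA_CLASSES[i]}",
                             "row-sum", f"sums to {sum(row)!r}"))
        if row[i] != 0.0:
            f.append(Finding(f"nyha_change_matrix.row_{NYHA_CLASSES[i]}",
                             "diagonal-zero", f"diagonal entry {row[i]}"))
        if any(x < 0 for x in row):
            f.append(Finding(f"nyha_change_matrix.row_{NYHA_CLASSES[i]}",
                             "nonnegative", f"row {row}"))

    for name, arm in config.arms.items():
        d = arm.drug
        expected = d.monthly_price * (1.0 - d.copay_ratio)
        if abs(d.monthly_cost - expected) > 0.01:
            f.append(Finding(f"arms.{name}.drug", "copay-arithmetic",
                             f"monthly_cost {d.monthly_cost} != "
                             f"monthly_price*(1-copay) = {expected:.4f}"))
        if not 0.0 <= d.copay_ratio <= 1.0:
            f.append(Finding(f"arms.{name}.drug", "copay-bounds",
                             f"copay_ratio {d.copay_ratio}"))
        for label, ref in (
            ("drug_cost_param", arm.drug_cost_param),
            ("nyha_progress_param", arm.nyha_progress_param),
            ("hr_hosp_param", arm.hr_hosp_param),
            ("hr_cv_death_param", arm.hr_cv_death_param),
        ):
            if ref is not None and ref not in config.parameters:
                f.append(Finding(f"arms.{name}.{label}", "parameter-ref",
                                 f"references unknown parameter {ref!r}"))

    s = config.settings
    for label, v, allowed in (
        ("weibull_mode", s.weibull_mode, ("calibrated", "raw")),
        ("hr_scale", s.hr_scale, ("rate", "probability")),
        ("readmission_mode", s.readmission_mode, ("per_hospitalization", "unconditional")),
        ("disutility_mode", s.disutility_mode, ("per_event", "per_month")),
    ):
        if v not in allowed:
            f.append(Finding(f"settings.{label}", "enum", f"{v!r} not in {allowed}"))

    return f


# ---------------------------------------------------------------------------
# functional updates
# ---------------------------------------------------------------------------

def with_parameter_values(config: ModelConfig, values: Mapping[str, float]) -> ModelConfig:
    """Copy of ``config`` with the base-case values of named parameters replaced."""
    params = dict(config.parameters)
    for name, value in values.items():
        if name not in params:
            raise KeyError(f"unknown parameter {name!r}")
        params[name] = replace(params[name], value=float(value))
    return replace(config, parameters=params)


def with_overrides(config: ModelConfig, **kwargs) -> ModelConfig:
    """Copy of ``config`` with top-level fields replaced (e.g. horizon_cycles)."""
    if "initial_nyha_distribution" in kwargs:
        kwargs["initial_nyha_distribution"] = tuple(kwargs["initial_nyha_distribution"])
    if "settings" in kwargs and isinstance(kwargs["settings"], Mapping):
        kwargs["settings"] = replace(config.settings, **kwargs["settings"])
    return replace(config, **kwargs)
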