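"""Model parameterization for the NET imaging cost-effectiveness model.

This module defines the full parameter set of the decision model — diagnostic
test performance, acute and yearly costs, health-state utilities, annual
transition probabilities and global run settings — together with validation,
a YAML config dialect that merges partial files over the built-in defaults,
and the beta/gamma moment-matching helpers used by the probabilistic
sensitivity analysis.

The built-in defaults describe the published base case: a cohort of
30-year-olds with a 5% pre-test probability of a somatostatin-receptor
positive neuroendocrine tumor, worked up with one of three imaging
strategies (CT alone, ¹¹¹In-pentetreotide SPECT/CT, ⁶⁸Ga-DOTA-TATE PET/CT),
evaluated over a lifetime horizon at a 3% annual discount rate against a
willingness-to-pay of $100,000 per QALY.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Iterable, Mapping

import yaml

__all__ = [
    "ConfigError",
    "TestPerformance",
    "DiagnosticStrategy",
    "CostSet",
    "UtilitySet",
    "TransitionSet",
    "UncertainParam",
    "ModelConfig",
    "default_net_config",
    "validate_config",
    "load_config",
    "save_config",
    "config_to_dict",
    "config_from_dict",
    "beta_params_from_mean",
    "gamma_params_from_mean",
]


class ConfigError(ValueError):
    """Raised when a configuration violates an invariant or cannot be parsed."""


@dataclass(frozen=True)
class TestPerformance:
    """Sensitivity/specificity pair of a diagnostic test, both in [0, 1]."""

    sensitivity: float
    specificity: float


@dataclass(frozen=True)
class DiagnosticStrategy:
    """An imaging strategy: a name, its acute imaging cost (USD) and accuracy."""

    name: str
    imaging_cost: float
    performance: TestPerformance


@dataclass(frozen=True)
class CostSet:
    """Acute (one-off) and yearly (per-cycle) costs in 2020 USD.

    Acute costs attach to the diagnostic outcome at model entry: timely surgery
    plus treatment for true positives, delayed surgery plus treatment for false
    negatives, an unnecessary confirmatory biopsy for false positives, and a
    (zero) cost for true negatives.  ``biopsy`` is the confirmatory workup every
    test-positive receives before treatment.  Yearly costs accrue per health
    state per annual cycle.
    """

    timely_treatment: float = 85068.0
    delayed_treatment: float = 127602.0
    unnecessary_biopsy: float = 1375.0
    true_negative_acute: float = 0.0
    biopsy: float = 1375.0
    yearly_no_burden: float = 0.0
    yearly_treated_non_relevant: float = 2107.0
    yearly_clinically_relevant: float = 61375.0


@dataclass(frozen=True)
class UtilitySet:
    """Health-state utility weights in [0, 1] (1 = perfect health, 0 = death).

    ``without_treatment_alt`` (0.690) is recorded from the source utility set
    but is not wired into the default model: the untreated clinically relevant
    state uses the disease-progression utility 0.612, which is what the
    published one-cycle outcomes imply.
    """

    no_burden: float = 1.0
    no_clinically_relevant_burden: float = 0.779
    clinically_relevant_treated: float = 0.768
    progression_untreated: float = 0.612
    without_treatment_alt: float = 0.690
    death: float = 0.0


@dataclass(frozen=True)
class TransitionSet:
    """Annual transition probabilities of the Markov model.

    Disease-specific death risks (timely-treated 4.0%, delayed-treated 4.5%,
    untreated 12.12%) and the competing-cause risk (2.5%) are combined with the
    age-specific life-table background risk as independent competing risks.
    ``relative_risk_other_death`` multiplies the life-table probability.
    """

    p_death_timely: float = 0.04
    p_death_delayed: float = 0.045
    p_death_untreated: float = 0.1212
    p_death_competing: float = 0.025
    p_progression: float = 0.088
    p_untreated_to_treated: float = 1.0
    relative_risk_other_death: float = 1.0


@dataclass(frozen=True)
class UncertainParam:
    """A second-order uncertain parameter: mean, distribution family, spread.

    ``spread`` is the effective sample size for the beta family and the
    coefficient of variation for the gamma family; it is ignored for fixed
    parameters.
    """

    mean: float
    family: str  # "beta" | "gamma" | "fixed"
    spread: float | None = None

    def __post_init__(self) -> None:
        if self.family not in ("beta", "gamma", "fixed"):
            raise ConfigError(f"unknown distribution family {self.family!r}")


@dataclass(frozen=True)
class ModelConfig:
    """Complete model configuration: parameters plus run settings."""

    prevalence: float = 0.05
    start_age: int = 30
    horizon_age: int = 100
    discount_rate: float = 0.03
    wtp: float = 100_000.0
    cycle_length: float = 1.0
    strategies: tuple[DiagnosticStrategy, ...] = (
        DiagnosticStrategy("CT", 787.0, TestPerformance(0.77, 0.86)),
        DiagnosticStrategy("SPECT/CT", 1242.0, TestPerformance(0.70, 0.96)),
        DiagnosticStrategy("PET/CT", 1375.0, TestPerformance(0.91, 0.92)),
    )
    costs: CostSet = field(default_factory=CostSet)
    utilities: UtilitySet = field(default_factory=UtilitySet)
    transitions: TransitionSet = field(default_factory=TransitionSet)
    life_table_ref: str = "bundled"
    psa_iterations: int = 30_000
    seed: int = 20210218
    # Every test-positive (TP and FP) undergoes the confirmatory biopsy before
    # the treatment decision; set False to charge it to false positives only.
    charge_biopsy_to_test_positives: bool = True
    # PSA dispersion defaults: effective sample size for beta-distributed
    # parameters and coefficient of variation for gamma-distributed costs,
    # overridable per parameter name.
    psa_ess: float = 100.0
    psa_cv: float = 0.2
    psa_spread_overrides: Mapping[str, float] = field(default_factory=dict)
    # One-way sensitivity analysis default half-range, as a fraction of the
    # base value (clipped to each parameter's domain).
    dsa_fraction: float = 0.2

    @property
    def n_cycles(self) -> int:
        return int(round((self.horizon_age - self.start_age) / self.cycle_length))

    def strategy(self, name: str) -> DiagnosticStrategy:
        for s in self.strategies:
            if s.name == name:
                return s
        raise KeyError(f"no strategy named {name!r}")

    def replace(self, **kwargs: Any) -> "ModelConfig":
        return replace(self, **kwargs)


def default_net_config() -> ModelConfig:
    """Return the base-case configuration with every published default."""
    return ModelConfig()


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def _check_prob(violations: list[str], name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        violations.append(f"{name} = {value!r} outside [0, 1]")


def _check_nonneg(violations: list[str], name: str, value: float) -> None:
    if value < 0.0:
        violations.append(f"{name} = {value!r} is negative")


def validate_config(config: ModelConfig) -> list[str]:
    """Return a list of invariant violations (empty when the config is valid)."""
    v: list[str] = []
    if not (0.0 < config.prevalence < 1.0):
        v.append(f"prevalence = {config.prevalence!r} outside (0, 1)")
    if config.horizon_age <= config.start_age:
        v.append("horizon_age must exceed start_age")
    if config.discount_rate < 0.0:
        v.append("discount_rate is negative")
    if config.cycle_length <= 0.0:
        v.append("cycle_length must be positive")
    if config.wtp < 0.0:
        v.append("wtp is negative")
    if len(config.strategies) < 2:
        v.append("at least 2 strategies are required")
    names = [s.name for s in config.strategies]
    if len(set(names)) != len(names):
        v.append("strategy names must be unique")
    for s in config.strategies:
        _check_prob(v, f"{s.name}.sensitivity", s.performance.sensitivity)
        _check_prob(v, f"{s.name}.specificity", s.performance.specificity)
        _check_nonneg(v, f"{s.name}.imaging_cost", s.imaging_cost)
    for f_ in dataclasses.fields(config.costs):
        _check_nonneg(v, f"costs.{f_.name}", getattr(config.costs, f_.name))
    for f_ in dataclasses.fields(config.utilities):
        _check_prob(v, f"utilities.{f_.name}", getattr(config.utilities, f_.name))
    if config.utilities.death != 0.0:
        v.append("utilities.death must be 0")
    tr = config.transitions
    for f_ in dataclasses.fields(tr):
        value = getattr(tr, f_.name)
        if f_.name == "relative_risk_other_death":
            _check_nonneg(v, f"transitions.{f_.name}", value)
        else:
            _check_prob(v, f"transitions.{f_.name}", value)
    if config.psa_iterations < 1:
        v.append("psa_iterations must be >= 1")
    if config.psa_ess <= 0:
        v.append("psa_ess must be positive")
    if config.psa_cv <= 0:
        v.append("psa_cv must be positive")
    if not (0.0 <= config.dsa_fraction <= 1.0):
        v.append("dsa_fraction must be in [0, 1]")
    return v


def _require_valid(config: ModelConfig) -> ModelConfig:
    violations = validate_config(config)
    if violations:
        raise ConfigError("invalid configuration: " + "; ".join(violations))
    return config


# ---------------------------------------------------------------------------
# Serialization / config dialect
# ---------------------------------------------------------------------------

def config_to_dict(config: ModelConfig) -> dict[str, Any]:
    """Serialize a config to the plain nested-dict form of the YAML dialect."""
    return {
        "prevalence": config.prevalence,
        "start_age": config.start_age,
        "horizon_age": config.horizon_age,
        "discount_rate": config.discount_rate,
        "wtp": config.wtp,
        "cycle_length": config.cycle_length,
        "strategies": [
            {
                "name": s.name,
                "imaging_cost": s.imaging_cost,
                "sensitivity": s.performance.sensitivity,
                "specificity": s.performance.specificity,
            }
            for s in config.strategies
        ],
        "costs": dataclasses.asdict(config.costs),
        "utilities": dataclasses.asdict(config.utilities),
        "transitions": dataclasses.asdict(config.transitions),
        "life_table_ref": config.life_table_ref,
        "psa_iterations": config.psa_iterations,
        "seed": config.seed,
        "charge_biopsy_to_test_positives": config.charge_biopsy_to_test_positives,
        "psa_ess": config.psa_ess,
        "psa_cv": config.psa_cv,
        "psa_spread_overrides": dict(config.psa_spread_overrides),
        "dsa_fraction": config.dsa_fraction,
    }


def _merge_section(cls: type, base: Any, override: Mapping[str, Any], where: str) -> Any:
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(override) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}")
    return replace(base, **dict(override))


def _merge_strategies(
    base: Iterable[DiagnosticStrategy], overrides: list[Mapping[str, Any]]
) -> tuple[DiagnosticStrategy, ...]:
    by_name = {s.name: s for s in base}
    order = list(by_name)
    for item in overrides:
        if "name" not in item:
            raise ConfigError("each strategy entry needs a 'name'")
        unknown = set(item) - {"name", "imaging_cost", "sensitivity", "specificity"}
        if unknown:
            raise ConfigError(
                f"unknown key(s) {sorted(unknown)} in strategy {item['name']!r}"
            )
        name = item["name"]
        if name in by_name:
            s = by_name[name]
            perf = TestPerformance(
                sensitivity=item.get("sensitivity", s.performance.sensitivity),
                specificity=item.get("specificity", s.performance.specificity),
            )
            by_name[name] = DiagnosticStrategy(
                name, item.get("imaging_cost", s.imaging_cost), perf
            )
        else:
            missing = {"imaging_cost", "sensitivity", "specificity"} - set(item)
            if missing:
                raise ConfigError(
                    f"new strategy {name!r} is missing {sorted(missing)}"
                )
            by_name[name] = DiagnosticStrategy(
                name,
                item["imaging_cost"],
                TestPerformance(item["sensitivity"], item["specificity"]),
            )
            order.append(name)
    return tuple(by_name[n] for n in order)


_SCALAR_KEYS = {
    "prevalence",
    "start_age",
    "horizon_age",
    "discount_rate",
    "wtp",
    "cycle_length",
    "life_table_ref",
    "psa_iterations",
    "seed",
    "charge_biopsy_to_test_positives",
    "psa_ess",
    "psa_cv",
    "dsa_fraction",
}


def config_from_dict(
    data: Mapping[str, Any], base: ModelConfig | None = None
) -> ModelConfig:
    """Build a config by merging ``data`` over ``base`` (defaults if None).

    Unknown keys raise :class:`ConfigError`; the merged config is re-validated.
    """
    config = base if base is not None else default_net_config()
    unknown = set(data) - _SCALAR_KEYS - {
        "strategies",
        "costs",
        "utilities",
        "transitions",
        "psa_spread_overrides",
    }
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    updates: dict[str, Any] = {k: data[k] for k in _SCALAR_KEYS if k in data}
    if "costs" in data:
        updates["costs"] = _merge_section(CostSet, config.costs, data["costs"], "costs")
    if "utilities" in data:
        updates["utilities"] = _merge_section(
            UtilitySet, config.utilities, data["utilities"], "utilities"
        )
    if "transitions" in data:
        updates["transitions"] = _merge_section(
            TransitionSet, config.transitions, data["transitions"], "transitions"
        )
    if "strategies" in data:
        updates["strategies"] = _merge_strategies(config.strategies, data["strategies"])
    if "psa_spread_overrides" in data:
        updates["psa_spread_overrides"] = dict(
            config.psa_spread_overrides, **data["psa_spread_overrides"]
        )
    return _require_valid(config.replace(**updates))


def load_config(path: str | Path) -> ModelConfig:
    """Load a (possibly partial) YAML config file merged over the defaults."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    data = yaml.safe_load(path.read_text()) or {}
    if not isinstance(data, Mapping):
        raise ConfigError(f"config file {path} must contain a mapping")
    return config_from_dict(data)


def save_config(config: ModelConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))


# ---------------------------------------------------------------------------
# PSA distribution parameterization (moment matching)
# ---------------------------------------------------------------------------

def beta_params_from_mean(mean: float, ess: float) -> tuple[float, float]:
    """Beta shape pair (alpha, beta) with the given mean and effective sample size.

    alpha = mean * ess, beta = (1 - mean) * ess; the resulting Beta(alpha, beta)
    has expectation exactly ``mean`` and concentration controlled by ``ess``.
    """
    if not (0.0 < mean < 1.0):
        raise ValueError(f"beta mean must lie in (0, 1), got {mean!r}")
    if ess <= 0.0:
        raise ValueError(f"effective sample size must be positive, got {ess!r}")
    return mean * ess, (1.0 - mean) * ess


def gamma_params_from_mean(mean: float, cv: float) -> tuple[float, float]:
    """Gamma (shape, scale) with the given mean and coefficient of variation.

    shape = 1/cv**2 and scale = mean*cv**2, so the distribution's mean is
    ``mean`` and its standard deviation ``mean * cv``.
    """
    if mean <= 0.0:
        raise ValueError(f"gamma mean must be positive, got {mean!r}")
    if cv <= 0.0:
        raise ValueError(f"coefficient of variation must be positive, got {cv!r}")
    shape = 1.0 / cv**2
    return shape, mean * cv**2
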