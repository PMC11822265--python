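"""Decision-model configuration for the rotator-cuff cost-utility model.

The model compares four surgical strategies for massive irreparable rotator
cuff tears — superior capsular reconstruction (SCR), lower trapezius tendon
transfer (LTTT), subacromial balloon spacer (SABS) and reverse shoulder
arthroplasty (RSA).  A configuration bundles the global simulation settings
(horizon, cycle length, discount rate, willingness-to-pay, microsimulation
sizes, uncertainty rules) with one parameter block per strategy: upfront
procedure cost, annual probabilities of arthroscopic revision and of
conversion to RSA, and per-year health-state utilities derived from
Constant-Murley scores.

Configurations are plain frozen dataclasses, serialisable to a strict YAML
document (unknown keys are rejected).  :func:`builtin_irct_config` returns
the published base case, which also ships as ``data/irct_base_case.yaml``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Any, Mapping, Optional, Sequence

import yaml

__all__ = [
    "ConfigError",
    "ModelSettings",
    "StrategyParams",
    "ModelConfig",
    "builtin_irct_config",
    "builtin_config_path",
    "utility_from_cms",
    "validate_config",
    "load_config",
    "save_config",
]

STRATEGY_NAMES = ("SCR", "LTTT", "SABS", "RSA")


class ConfigError(ValueError):
    """A configuration document or object violates the model contract."""


@dataclass(frozen=True)
class ModelSettings:
    """Global settings of the decision model.

    Attributes
    ----------
    horizon_years : int
        Number of annual Markov cycles simulated (base case 10).
    cycle_length_years : float
        Duration of one cycle in years (base case 1).
    discount_rate : float
        Annual discount rate applied to both costs and QALYs (base 0.03).
    wtp : float
        Willingness-to-pay threshold in $/QALY (base 50,000).
    n_patients : int
        Patients per microsimulation arm (base 1,000).
    n_iterations : int
        Probabilistic sensitivity analysis iterations (base 1,000).
    revision_cost_uplift : float
        Surcharge on revision procedures relative to the primary procedure
        cost (base 0.05, i.e. revisions cost 5% more).
    rsa_revision_cost_uplift : float or None
        Optional separate surcharge for revision RSA; ``None`` means the
        generic ``revision_cost_uplift`` applies.
    sd_fraction_costs, sd_fraction_probs : float
        Standard deviation of cost / probability inputs as a fraction of the
        mean, used to build PSA distributions (base 0.20).
    sd_utilities : float
        Absolute standard deviation of utility inputs (base 0.05).
    allow_repeat_events : bool
        If True, patients return to an at-risk state after a revision so
        repeat events are possible; off by default (single-event pathways).
    rng_seed : int
        Master seed for all stochastic components.
    """

    horizon_years: int = 10
    cycle_length_years: float = 1.0
    discount_rate: float = 0.03
    wtp: float = 50_000.0
    n_patients: int = 1000
    n_iterations: int = 1000
    revision_cost_uplift: float = 0.05
    rsa_revision_cost_uplift: Optional[float] = None
    sd_fraction_costs: float = 0.20
    sd_fraction_probs: float = 0.20
    sd_utilities: float = 0.05
    allow_repeat_events: bool = False
    rng_seed: int = 0


@dataclass(frozen=True)
class StrategyParams:
    """Parameters of one surgical strategy.

    ``p_reoperation`` is the annual probability of arthroscopic revision
    (for RSA itself: the annual probability of revision RSA) while the
    patient is at risk; ``p_conversion`` is the annual probability of
    conversion to RSA (0 for RSA).  ``u_success`` and ``u_failure`` are
    per-year utilities in [0, 1]; ``u_failure`` is accrued in the cycle a
    complication occurs.
    """

    name: str
    upfront_cost: float
    p_reoperation: float
    p_conversion: float
    u_success: float
    u_failure: float


@dataclass(frozen=True)
class ModelConfig:
    """Full specification of the decision problem."""

    settings: ModelSettings
    strategies: tuple[StrategyParams, ...]
    conversion_target: str = "RSA"

    def strategy(self, name: str) -> StrategyParams:
        for s in self.strategies:
            if s.name == name:
                return s
        raise KeyError(f"unknown strategy {name!r}")

    @property
    def strategy_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.strategies)

    @property
    def target(self) -> StrategyParams:
        return self.strategy(self.conversion_target)


def utility_from_cms(cms_score: float) -> float:
    """Convert a Constant-Murley score (0-100) to a utility in [0, 1].

    The 100-point shoulder-function scale is mapped linearly onto the
    0 (death) - 1 (perfect health) utility scale by dividing by 100.
    """
    if not 0 <= cms_score <= 100:
        raise ValueError(f"cms_score must be in [0, 100], got {cms_score}")
    return cms_score / 100.0


# --------------------------------------------------------------------------
# validation

def _check(cond: bool, path: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"{path}: {msg}")


def _validate_settings(s: ModelSettings, path: str = "settings") -> None:
    _check(isinstance(s.horizon_years, int) and s.horizon_years >= 1,
           f"{path}.horizon_years", f"must be an integer >= 1 (got {s.horizon_years})")
    _check(s.cycle_length_years > 0, f"{path}.cycle_length_years",
           f"must be positive (got {s.cycle_length_years})")
    _check(0 <= s.discount_rate < 1, f"{path}.discount_rate",
           f"must be in [0, 1) (got {s.discount_rate})")
    _check(s.wtp >= 0, f"{path}.wtp", f"must be >= 0 (got {s.wtp})")
    _check(isinstance(s.n_patients, int) and s.n_patients >= 1,
           f"{path}.n_patients", f"must be an integer >= 1 (got {s.n_patients})")
    _check(isinstance(s.n_iterations, int) and s.n_iterations >= 1,
           f"{path}.n_iterations", f"must be an integer >= 1 (got {s.n_iterations})")
    _check(s.revision_cost_uplift >= 0, f"{path}.revision_cost_uplift",
           f"must be >= 0 (got {s.revision_cost_uplift})")
    if s.rsa_revision_cost_uplift is not None:
        _check(s.rsa_revision_cost_uplift >= 0, f"{path}.rsa_revision_cost_uplift",
               f"must be >= 0 (got {s.rsa_revision_cost_uplift})")
    _check(0 < s.sd_fraction_costs < 1, f"{path}.sd_fraction_costs",
           f"must be in (0, 1) (got {s.sd_fraction_costs})")
    _check(0 < s.sd_fraction_probs < 1, f"{path}.sd_fraction_probs",
           f"must be in (0, 1) (got {s.sd_fraction_probs})")
    _check(0 < s.sd_utilities < 0.5, f"{path}.sd_utilities",
           f"must be in (0, 0.5) (got {s.sd_utilities})")


def _validate_strategy(p: StrategyParams, path: str) -> None:
    _check(isinstance(p.name, str) and p.name != "", f"{path}.name", "must be a non-empty string")
    _check(p.upfront_cost > 0, f"{path}.upfront_cost",
           f"must be > 0 (got {p.upfront_cost})")
    _check(0 <= p.p_reoperation <= 1, f"{path}.p_reoperation",
           f"must be in [0, 1] (got {p.p_reoperation})")
    _check(0 <= p.p_conversion <= 1, f"{path}.p_conversion",
           f"must be in [0, 1] (got {p.p_conversion})")
    _check(p.p_reoperation + p.p_conversion <= 1, f"{path}.p_reoperation",
           "p_reoperation + p_conversion must not exceed 1 "
           f"(got {p.p_reoperation} + {p.p_conversion})")
    _check(0 <= p.u_success <= 1, f"{path}.u_success",
           f"must be in [0, 1] (got {p.u_success})")
    _check(0 <= p.u_failure <= 1, f"{path}.u_failure",
           f"must be in [0, 1] (got {p.u_failure})")
    _check(p.u_failure <= p.u_success, f"{path}.u_failure",
           f"must not exceed u_success (got {p.u_failure} > {p.u_success})")


def validate_config(config: ModelConfig) -> ModelConfig:
    """Validate all invariants; return the config unchanged if valid."""
    _validate_settings(config.settings)
    names = [s.name for s in config.strategies]
    _check(len(config.strategies) >= 2, "strategies", "need at least 2 strategies")
    _check(len(set(names)) == len(names), "strategies",
           f"strategy names must be unique (got {names})")
    for i, s in enumerate(config.strategies):
        _validate_strategy(s, f"strategies[{i}]")
    _check(config.conversion_target in names, "conversion_target",
           f"{config.conversion_target!r} is not one of the strategies {names}")
    return config


# --------------------------------------------------------------------------
# base case

def builtin_irct_config() -> ModelConfig:
    """The published base case for irreparable rotator cuff tears.

    Upfront costs (2024 US$), annual event probabilities and success
    utilities (Constant-Murley score / 100) per strategy, with a shared
    complication-year utility of 0.35.
    """
    u_fail = 0.35
    strategies = (
        StrategyParams("SCR", 20837.0, 0.069, 0.017, 0.76, u_fail),
        StrategyParams("LTTT", 16915.0, 0.075, 0.05, 0.67, u_fail),
        StrategyParams("SABS", 9058.0, 0.069, 0.05, 0.69, u_fail),
        StrategyParams("RSA", 17210.0, 0.08, 0.0, 0.59, u_fail),
    )
    return validate_config(
        ModelConfig(settings=ModelSettings(), strategies=strategies,
                    conversion_target="RSA")
    )


def builtin_config_path() -> Path:
    """Path of the shipped YAML fixture reproducing the base case."""
    return Path(resources.files("irct_cea").joinpath("data/irct_base_case.yaml"))  # type: ignore[arg-type]


# --------------------------------------------------------------------------
# serialisation (strict YAML)

_SETTINGS_FIELDS: dict[str, type] = {
    "horizon_years": int,
    "cycle_length_years": float,
    "discount_rate": float,
    "wtp": float,
    "n_patients": int,
    "n_iterations": int,
    "revision_cost_uplift": float,
    "rsa_revision_cost_uplift": float,
    "sd_fraction_costs": float,
    "sd_fraction_probs": float,
    "sd_utilities": float,
    "allow_repeat_events": bool,
    "rng_seed": int,
}

_STRATEGY_FIELDS: dict[str, type] = {
    "name": str,
    "upfront_cost": float,
    "p_reoperation": float,
    "p_conversion": float,
    "u_success": float,
    "u_failure": float,
}


def _coerce(value: Any, typ: type, path: str) -> Any:
    if typ is float:
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise ConfigError(f"{path}: expected a number, got {value!r}")
        return float(value)
    if typ is int:
        if isinstance(value, bool) or not isinstance(value, int):
            raise ConfigError(f"{path}: expected an integer, got {value!r}")
        return value
    if typ is bool:
        if not isinstance(value, bool):
            raise ConfigError(f"{path}: expected a boolean, got {value!r}")
        return value
    if typ is str:
        if not isinstance(value, str):
            raise ConfigError(f"{path}: expected a string, got {value!r}")
        return value
    raise AssertionError(typ)


def _parse_block(raw: Any, schema: Mapping[str, type], path: str,
                 optional: Sequence[str] = (), defaults: Mapping[str, Any] | None = None,
                 ) -> dict[str, Any]:
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a mapping, got {type(raw).__name__}")
    defaults = dict(defaults or {})
    out: dict[str, Any] = {}
    for key in raw:
        if key not in schema:
            raise ConfigError(f"{path}.{key}: unknown key {key!r}")
    for key, typ in schema.items():
        if key in raw:
            if raw[key] is None and key in optional:
                out[key] = None
            else:
                out[key] = _coerce(raw[key], typ, f"{path}.{key}")
        elif key in defaults:
            out[key] = defaults[key]
        elif key in optional:
            out[key] = None
        else:
            raise ConfigError(f"{path}.{key}: missing required field {key!r}")
    return out


def config_from_dict(doc: Any) -> ModelConfig:
    """Build and validate a :class:`ModelConfig` from a parsed document."""
    if not isinstance(doc, dict):
        raise ConfigError("document: expected a top-level mapping")
    allowed = {"settings", "strategies", "conversion_target", "u_failure"}
    for key in doc:
        if key not in allowed:
            raise ConfigError(f"document.{key}: unknown key {key!r}")
    settings_defaults = {f.name: f.default for f in dataclasses.fields(ModelSettings)}
    settings_raw = doc.get("settings", {})
    settings = ModelSettings(**_parse_block(
        settings_raw, _SETTINGS_FIELDS, "settings",
        optional=("rsa_revision_cost_uplift",), defaults=settings_defaults))

    if "strategies" not in doc:
        raise ConfigError("document.strategies: missing required field 'strategies'")
    raw_strats = doc["strategies"]
    if not isinstance(raw_strats, list):
        raise ConfigError("strategies: expected a list of strategy blocks")

    # a single top-level u_failure may be shared by all strategies
    shared_u_fail = doc.get("u_failure")
    if shared_u_fail is not None:
        shared_u_fail = _coerce(shared_u_fail, float, "u_failure")

    strategies = []
    for i, raw in enumerate(raw_strats):
        path = f"strategies[{i}]"
        defaults = {"u_failure": shared_u_fail} if shared_u_fail is not None else None
        block = _parse_block(raw, _STRATEGY_FIELDS, path, defaults=defaults)
        strategies.append(StrategyParams(**block))

    if "conversion_target" not in doc:
        raise ConfigError("document.conversion_target: missing required field "
                          "'conversion_target'")
    target = _coerce(doc["conversion_target"], str, "conversion_target")
    return validate_config(ModelConfig(settings=settings,
                                       strategies=tuple(strategies),
                                       conversion_target=target))


def config_to_dict(config: ModelConfig) -> dict[str, Any]:
    """Plain-dict form of a config (inverse of :func:`config_from_dict`)."""
    return {
        "settings": dataclasses.asdict(config.settings),
        "conversion_target": config.conversion_target,
        "strategies": [dataclasses.asdict(s) for s in config.strategies],
    }


def load_config(path: str | Path) -> ModelConfig:
    """Load and validate a YAML model configuration."""
    with open(path, "r", encoding="utf-8") as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"{path}: not valid YAML ({exc})") from exc
    return config_from_dict(doc)


def save_config(config: ModelConfig, path: str | Path) -> None:
    """Write a config as YAML such that ``load_config`` restores it exactly."""
    validate_config(config)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)
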