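"""Sampling distributions for probabilistic sensitivity analysis.

Each uncertain model input is given a parametric distribution matched to its
base-case mean and a standard-deviation rule by the method of moments:

* costs: gamma, SD = ``sd_fraction_costs`` x mean (base 20%),
* probabilities: beta, SD = ``sd_fraction_probs`` x mean (base 20%),
* utilities: normal, SD = ``sd_utilities`` (base 0.05, absolute).

A probability whose base value is exactly 0 (RSA has no conversion) carries
no uncertainty and becomes a point mass.  All draws within one PSA
iteration are mutually independent.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model_config import ModelConfig, StrategyParams, validate_config

__all__ = [
    "DistributionError",
    "DistributionSpec",
    "beta_params_from_moments",
    "gamma_params_from_moments",
    "build_psa_specs",
    "sample_parameter_set",
    "quantile_range",
    "specs_table",
    "write_specs_csv",
]


class DistributionError(ValueError):
    """Requested moments are infeasible for the requested family."""


def beta_params_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Beta shape parameters (alpha, beta) with the given mean and SD.

    Method of moments: with nu = mean(1-mean)/sd^2 - 1,
    alpha = mean * nu and beta = (1-mean) * nu.  Feasible only when
    sd^2 < mean(1-mean).
    """
    if not 0 < mean < 1:
        raise DistributionError(f"beta mean must be in (0, 1), got {mean}")
    if sd <= 0:
        raise DistributionError(f"beta sd must be positive, got {sd}")
    if sd * sd >= mean * (1 - mean):
        raise DistributionError(
            f"infeasible beta moments: require sd^2 < mean*(1-mean), "
            f"got sd^2 = {sd * sd:g} >= {mean * (1 - mean):g}")
    nu = mean * (1 - mean) / (sd * sd) - 1
    return mean * nu, (1 - mean) * nu


def gamma_params_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Gamma (shape, scale) with the given mean and SD.

    shape = (mean/sd)^2, scale = sd^2/mean; in particular any SD equal to a
    fixed fraction f of the mean gives shape 1/f^2 (20% -> shape 25).
    """
    if mean <= 0:
        raise DistributionError(f"gamma mean must be positive, got {mean}")
    if sd <= 0:
        raise DistributionError(f"gamma sd must be positive, got {sd}")
    return (mean / sd) ** 2, sd * sd / mean


@dataclass(frozen=True)
class DistributionSpec:
    """One input's PSA distribution: family, target moments, shape params.

    ``family`` is one of ``beta``, ``gamma``, ``normal`` or ``point`` (a
    degenerate point mass used for inputs with no uncertainty, whose ``sd``
    is 0).
    """

    family: str
    mean: float
    sd: float
    shape_params: tuple[float, ...]

    def frozen(self):
        """The scipy frozen distribution (None for a point mass)."""
        if self.family == "beta":
            a, b = self.shape_params
            return stats.beta(a, b)
        if self.family == "gamma":
            shape, scale = self.shape_params
            return stats.gamma(shape, scale=scale)
        if self.family == "normal":
            loc, scale = self.shape_params
            return stats.norm(loc, scale)
        if self.family == "point":
            return None
        raise DistributionError(f"unknown family {self.family!r}")

    def analytic_moments(self) -> tuple[float, float]:
        """(mean, sd) of the constructed distribution."""
        if self.family == "point":
            return self.mean, 0.0
        d = self.frozen()
        return float(d.mean()), float(d.std())

    def sample(self, rng: np.random.Generator, size=None):
        if self.family == "beta":
            a, b = self.shape_params
            return rng.beta(a, b, size=size)
        if self.family == "gamma":
            shape, scale = self.shape_params
            return rng.gamma(shape, scale, size=size)
        if self.family == "normal":
            loc, scale = self.shape_params
            return rng.normal(loc, scale, size=size)
        if self.family == "point":
            return self.mean if size is None else np.full(size, self.mean)
        raise DistributionError(f"unknown family {self.family!r}")

    def quantile(self, q: float) -> float:
        if self.family == "point":
            return self.mean
        return float(self.frozen().ppf(q))


def _make_spec(family: str, mean: float, sd: float, name: str) -> DistributionSpec:
    try:
        if family == "beta":
            if mean == 0.0:
                return DistributionSpec("point", 0.0, 0.0, (0.0,))
            params = beta_params_from_moments(mean, sd)
        elif family == "gamma":
            params = gamma_params_from_moments(mean, sd)
        elif family == "normal":
            params = (mean, sd)
        else:
            raise DistributionError(f"unknown family {family!r}")
    except DistributionError as exc:
        raise DistributionError(f"{name}: {exc}") from exc
    return DistributionSpec(family, mean, sd, tuple(float(p) for p in params))


def build_psa_specs(config: ModelConfig) -> dict[str, DistributionSpec]:
    """Distribution specs for every uncertain input of ``config``.

    Keys are ``cost_<name>``, ``reoperation_<name>``, ``conversion_<name>``
    and ``u_success_<name>`` per strategy, plus a single ``u_failure`` when
    the complication-year utility is shared (or ``u_failure_<name>``
    otherwise).  Iteration order is fixed, which pins down the sampling
    order of :func:`sample_parameter_set`.
    """
    validate_config(config)
    s = config.settings
    specs: dict[str, DistributionSpec] = {}
    for strat in config.strategies:
        n = strat.name
        specs[f"cost_{n}"] = _make_spec(
            "gamma", strat.upfront_cost, s.sd_fraction_costs * strat.upfront_cost,
            f"cost_{n}")
        specs[f"reoperation_{n}"] = _make_spec(
            "beta", strat.p_reoperation, s.sd_fraction_probs * strat.p_reoperation,
            f"reoperation_{n}")
        specs[f"conversion_{n}"] = _make_spec(
            "beta", strat.p_conversion, s.sd_fraction_probs * strat.p_conversion,
            f"conversion_{n}")
        specs[f"u_success_{n}"] = _make_spec(
            "normal", strat.u_success, s.sd_utilities, f"u_success_{n}")
    fail_values = {strat.u_failure for strat in config.strategies}
    if len(fail_values) == 1:
        specs["u_failure"] = _make_spec(
            "normal", fail_values.pop(), s.sd_utilities, "u_failure")
    else:
        for strat in config.strategies:
            specs[f"u_failure_{strat.name}"] = _make_spec(
                "normal", strat.u_failure, s.sd_utilities,
                f"u_failure_{strat.name}")
    return specs


def sample_parameter_set(config: ModelConfig,
                         specs: dict[str, DistributionSpec],
                         rng: np.random.Generator) -> ModelConfig:
    """Draw one full parameter set and return it as a valid ModelConfig.

    One independent draw per input.  Utilities are clipped into [0, 1] and
    the complication-year utility is capped at the success utility; both
    clips fire with negligible probability at base-case SDs.  If a sampled
    (p_reoperation + p_conversion) exceeds 1 the pair is rescaled
    proportionally (never triggered at base-case magnitudes).
    """
    draws = {name: float(spec.sample(rng)) for name, spec in specs.items()}
    shared_fail = draws.get("u_failure")
    new_strats = []
    for strat in config.strategies:
        n = strat.name
        cost = draws[f"cost_{n}"]
        p_reop = draws[f"reoperation_{n}"]
        p_conv = draws[f"conversion_{n}"]
        total = p_reop + p_conv
        if total > 1.0:
            p_reop, p_conv = p_reop / total, p_conv / total
        u_succ = float(np.clip(draws[f"u_success_{n}"], 0.0, 1.0))
        u_fail = shared_fail if shared_fail is not None else draws[f"u_failure_{n}"]
        u_fail = float(np.clip(u_fail, 0.0, u_succ))
        new_strats.append(dataclasses.replace(
            strat, upfront_cost=cost, p_reoperation=p_reop,
            p_conversion=p_conv, u_success=u_succ, u_failure=u_fail))
    return validate_config(
        dataclasses.replace(config, strategies=tuple(new_strats)))


def quantile_range(spec: DistributionSpec, lo: float = 0.10,
                   hi: float = 0.90) -> tuple[float, float]:
    """Analytic (q_lo, q_hi) quantiles of a spec's distribution."""
    return spec.quantile(lo), spec.quantile(hi)


def specs_table(specs: dict[str, DistributionSpec], lo: float = 0.10,
                hi: float = 0.90) -> pd.DataFrame:
    """Tabulate all specs with their quantile ranges for reconciliation."""
    rows = []
    for name, spec in specs.items():
        q_lo, q_hi = quantile_range(spec, lo, hi)
        rows.append({"input": name, "base_value": spec.mean,
                     "family": spec.family, "sd": spec.sd,
                     f"q{int(round(lo * 100))}": q_lo,
                     f"q{int(round(hi * 100))}": q_hi})
    return pd.DataFrame(rows)


def write_specs_csv(specs: dict[str, DistributionSpec], path) -> None:
    specs_table(specs).to_csv(path, index=False)
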