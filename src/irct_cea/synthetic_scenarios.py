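"""Random model configurations and an exhaustive trajectory oracle.

:func:`generate_random_config` draws structurally valid decision problems
(2-6 strategies, bounded hazards, utility ordering respected) so every
pipeline stage can be exercised without the published base case.

:func:`enumerate_trajectories` lists every distinguishable patient pathway
of the default single-event structure together with its exact probability
and discounted accruals.  Over a horizon of T cycles the outcome space is
small — one event-free path, T arthroscopic-revision timings, and T
conversion timings each followed by at most one revision-RSA timing — so
the enumeration is an exact, independent ground truth for both the
stochastic engine and the cohort-expectation oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_config import (ModelConfig, ModelSettings, StrategyParams,
                           validate_config)

__all__ = [
    "ScenarioSpec",
    "generate_random_config",
    "Outcome",
    "TrajectoryDistribution",
    "enumerate_trajectories",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """Sampling ranges for random decision problems.

    Ranges are inclusive (lo, hi) pairs; a zero-width range fixes the value
    at its midpoint.  ``u_failure_range`` must lie at or below
    ``u_success_range`` so the utility ordering always holds.
    """

    n_strategies: int = 3
    cost_range: tuple[float, float] = (5_000.0, 30_000.0)
    p_reoperation_range: tuple[float, float] = (0.0, 0.15)
    p_conversion_range: tuple[float, float] = (0.0, 0.15)
    u_success_range: tuple[float, float] = (0.5, 0.9)
    u_failure_range: tuple[float, float] = (0.2, 0.45)
    horizon_years: int = 10
    discount_rate: float = 0.03
    seed: int = 0

    def validate(self) -> "ScenarioSpec":
        if not 2 <= self.n_strategies <= 6:
            raise ValueError(f"n_strategies must be in [2, 6], got {self.n_strategies}")
        for name in ("cost_range", "p_reoperation_range", "p_conversion_range",
                     "u_success_range", "u_failure_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name}: lo must not exceed hi (got {lo}, {hi})")
        if self.cost_range[0] <= 0:
            raise ValueError("cost_range must be strictly positive")
        if not 0 <= self.p_reoperation_range[0]:
            raise ValueError("p_reoperation_range must be nonnegative")
        if not 0 <= self.p_conversion_range[0]:
            raise ValueError("p_conversion_range must be nonnegative")
        if self.u_failure_range[1] > self.u_success_range[0]:
            raise ValueError(
                "u_failure_range must lie at or below u_success_range "
                f"(got {self.u_failure_range} vs {self.u_success_range})")
        if self.u_success_range[1] > 1 or self.u_failure_range[0] < 0:
            raise ValueError("utility ranges must lie within [0, 1]")
        return self


def _draw(rng: np.random.Generator, lo: float, hi: float) -> float:
    if lo == hi:
        return lo  # midpoint of a zero-width range
    return float(rng.uniform(lo, hi))


def generate_random_config(spec: ScenarioSpec) -> ModelConfig:
    """One random, valid decision problem, reproducible from ``spec.seed``.

    Event probabilities are rescaled so p_reoperation + p_conversion never
    exceeds 0.5, keeping event-free pathways common.  One strategy is
    designated the conversion target and gets p_conversion = 0 (conversion
    routes into it, as RSA does in the base case).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    u_fail = _draw(rng, *spec.u_failure_range)
    target_idx = int(rng.integers(spec.n_strategies))
    strategies = []
    for i in range(spec.n_strategies):
        p_reop = _draw(rng, *spec.p_reoperation_range)
        p_conv = _draw(rng, *spec.p_conversion_range)
        if i == target_idx:
            p_conv = 0.0
        total = p_reop + p_conv
        if total > 0.5:
            p_reop *= 0.5 / total
            p_conv *= 0.5 / total
        strategies.append(StrategyParams(
            name=f"S{i + 1}",
            upfront_cost=_draw(rng, *spec.cost_range),
            p_reoperation=p_reop,
            p_conversion=p_conv,
            u_success=_draw(rng, *spec.u_success_range),
            u_failure=u_fail))
    settings = ModelSettings(horizon_years=spec.horizon_years,
                             discount_rate=spec.discount_rate,
                             n_patients=100, n_iterations=10,
                             rng_seed=spec.seed)
    return validate_config(ModelConfig(
        settings=settings, strategies=tuple(strategies),
        conversion_target=strategies[target_idx].name))


@dataclass(frozen=True)
class Outcome:
    """One distinguishable pathway: its probability and discounted totals.

    ``events`` lists (event name, cycle) pairs in chronological order; the
    event-free pathway has an empty tuple.
    """

    probability: float
    total_cost: float
    total_qaly: float
    events: tuple[tuple[str, int], ...]


@dataclass(frozen=True)
class TrajectoryDistribution:
    outcomes: tuple[Outcome, ...]

    def total_probability(self) -> float:
        return float(sum(o.probability for o in self.outcomes))

    def expectation(self) -> tuple[float, float]:
        """Exact expected (cost, qaly) over the outcome distribution."""
        cost = sum(o.probability * o.total_cost for o in self.outcomes)
        qaly = sum(o.probability * o.total_qaly for o in self.outcomes)
        return float(cost), float(qaly)


def enumerate_trajectories(config: ModelConfig,
                           strategy: str) -> TrajectoryDistribution:
    """Exact outcome distribution of one arm (single-event structure only)."""
    validate_config(config)
    s = config.settings
    if s.allow_repeat_events:
        raise ValueError("enumeration requires the single-event structure "
                         "(allow_repeat_events must be False)")
    strat = config.strategy(strategy)
    target = config.target
    T = s.horizon_years
    delta = 1.0 / (1.0 + s.discount_rate)
    p1, p2 = strat.p_reoperation, strat.p_conversion
    pr = target.p_reoperation

    uplift = s.revision_cost_uplift
    rsa_uplift = (s.rsa_revision_cost_uplift
                  if s.rsa_revision_cost_uplift is not None else uplift)
    c_rev = (1.0 + uplift) * strat.upfront_cost
    c_conv = target.upfront_cost
    c_rsarev = (1.0 + rsa_uplift) * target.upfront_cost

    disc = np.array([delta ** t for t in range(T + 1)])  # disc[t] for cycle t

    def totals(events: tuple[tuple[str, int], ...]) -> tuple[float, float]:
        cost = strat.upfront_cost
        qaly = 0.0
        event_at = dict((cyc, name) for name, cyc in events)
        conv_cycle = next((cyc for name, cyc in events
                           if name == "conversion_to_rsa"), None)
        for t in range(1, T + 1):
            ev = event_at.get(t)
            if ev == "arthroscopic_revision":
                cost += c_rev * disc[t]
                qaly += strat.u_failure * disc[t]
            elif ev == "conversion_to_rsa":
                cost += c_conv * disc[t]
                qaly += strat.u_failure * disc[t]
            elif ev == "rsa_revision":
                cost += c_rsarev * disc[t]
                qaly += strat.u_failure * disc[t]
            elif conv_cycle is not None and t > conv_cycle:
                qaly += target.u_success * disc[t]
            else:
                qaly += strat.u_success * disc[t]
        return float(cost), float(qaly)

    outcomes: list[Outcome] = []

    def add(prob: float, events: tuple[tuple[str, int], ...]) -> None:
        cost, qaly = totals(events)
        outcomes.append(Outcome(probability=float(prob), total_cost=cost,
                                total_qaly=qaly, events=events))

    survive = 1.0 - p1 - p2
    # no index event over the whole horizon
    add(survive ** T, ())
    for i in range(1, T + 1):
        pre = survive ** (i - 1)
        # arthroscopic revision at cycle i (absorbing success afterwards)
        if p1 > 0:
            add(pre * p1, (("arthroscopic_revision", i),))
        # conversion at cycle i, then at risk of revision RSA
        if p2 > 0:
            p_conv_i = pre * p2
            add(p_conv_i * (1.0 - pr) ** (T - i), (("conversion_to_rsa", i),))
            if pr > 0:
                for j in range(i + 1, T + 1):
                    add(p_conv_i * (1.0 - pr) ** (j - i - 1) * pr,
                        (("conversion_to_rsa", i), ("rsa_revision", j)))
    return TrajectoryDistribution(outcomes=tuple(outcomes))
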