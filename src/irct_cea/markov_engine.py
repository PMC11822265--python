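"""Patient-level Markov simulation of the post-surgical pathway.

Each simulated patient pays the strategy's upfront cost at time zero and
then moves through annual cycles.  While in the index success state the
patient faces two competing annual hazards: arthroscopic revision (cost =
(1 + uplift) x the strategy's upfront cost) and conversion to RSA (cost =
the conversion target's upfront cost).  After conversion the patient faces
an annual revision-RSA hazard (cost = (1 + uplift) x the target's upfront
cost).  In the default single-event structure, post-revision states are
absorbing.  A cycle with an event accrues the complication-year utility
``u_failure``; any other cycle accrues the utility of the current state
(the strategy's success utility before conversion, the target's after).
Costs and QALYs of cycle t are discounted by (1 + discount_rate)^-t; the
index cost is booked undiscounted at t = 0.  There is no background
mortality and no half-cycle correction.

:func:`cohort_expectation` propagates the state-occupancy distribution of
the same chain deterministically and serves as the exact oracle for the
stochastic engine.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .model_config import ModelConfig, StrategyParams

__all__ = [
    "HealthState",
    "Event",
    "CycleRecord",
    "PatientTrajectory",
    "ArmResult",
    "simulate_patient",
    "simulate_arm",
    "cohort_expectation",
]


class HealthState(IntEnum):
    INDEX_SUCCESS = 0
    POST_REVISION_SUCCESS = 1
    POST_CONVERSION_RSA = 2
    POST_RSA_REVISION_SUCCESS = 3

    @property
    def at_risk(self) -> bool:
        """Whether further events can occur from this state (default structure)."""
        return self in (HealthState.INDEX_SUCCESS, HealthState.POST_CONVERSION_RSA)


class Event(IntEnum):
    NONE = 0
    ARTHROSCOPIC_REVISION = 1
    CONVERSION_TO_RSA = 2
    RSA_REVISION = 3


@dataclass(frozen=True)
class CycleRecord:
    """What happened in one annual cycle (undiscounted accruals)."""

    cycle: int
    state_entering: HealthState
    event: Event
    cycle_utility: float
    cycle_cost: float


@dataclass(frozen=True)
class PatientTrajectory:
    """One patient's full pathway with discounted totals."""

    strategy: str
    records: tuple[CycleRecord, ...]
    total_cost: float
    total_qaly: float

    def recompute_totals(self, upfront_cost: float,
                         discount_rate: float) -> tuple[float, float]:
        """Recompute discounted totals from the per-cycle records."""
        delta = 1.0 / (1.0 + discount_rate)
        cost = upfront_cost
        qaly = 0.0
        for rec in self.records:
            disc = delta ** rec.cycle
            cost += rec.cycle_cost * disc
            qaly += rec.cycle_utility * disc
        return cost, qaly


@dataclass(frozen=True)
class ArmResult:
    """Averages over the simulated patients of one strategy arm."""

    strategy: str
    mean_cost: float
    mean_qaly: float
    n_patients: int
    sd_cost: float = 0.0
    sd_qaly: float = 0.0


def _event_costs(strategy: StrategyParams, target: StrategyParams,
                 settings) -> tuple[float, float, float]:
    """Costs booked for (arthroscopic revision, conversion, RSA revision)."""
    uplift = settings.revision_cost_uplift
    rsa_uplift = (settings.rsa_revision_cost_uplift
                  if settings.rsa_revision_cost_uplift is not None else uplift)
    return ((1.0 + uplift) * strategy.upfront_cost,
            target.upfront_cost,
            (1.0 + rsa_uplift) * target.upfront_cost)


def _simulate_arrays(config: ModelConfig, strategy_name: str, n: int,
                     rng: np.random.Generator):
    """Vectorised simulation of ``n`` patients of one arm.

    Returns (states_entering, events, cycle_costs, cycle_utils, total_cost,
    total_qaly); the first four are (n, T) arrays, the totals are (n,)
    discounted sums including the upfront cost.  One uniform variate is
    drawn for every patient in every cycle regardless of state so that the
    stream consumption is independent of the realised pathways.
    """
    strategy = config.strategy(strategy_name)
    target = config.target
    s = config.settings
    T = s.horizon_years
    repeat = s.allow_repeat_events

    p1, p2 = strategy.p_reoperation, strategy.p_conversion
    pr = target.p_reoperation
    c_rev, c_conv, c_rsarev = _event_costs(strategy, target, s)
    delta = 1.0 / (1.0 + s.discount_rate)

    state = np.full(n, int(HealthState.INDEX_SUCCESS), dtype=np.int8)
    states_entering = np.empty((n, T), dtype=np.int8)
    events = np.zeros((n, T), dtype=np.int8)
    cycle_costs = np.zeros((n, T))
    cycle_utils = np.empty((n, T))

    total_cost = np.full(n, strategy.upfront_cost)
    total_qaly = np.zeros(n)

    for t in range(T):
        states_entering[:, t] = state
        u = rng.random(n)
        at_index = state == HealthState.INDEX_SUCCESS
        at_conv = state == HealthState.POST_CONVERSION_RSA
        ev_rev = at_index & (u < p1)
        ev_conv = at_index & ~ev_rev & (u < p1 + p2)
        ev_rsarev = at_conv & (u < pr)

        events[ev_rev, t] = Event.ARTHROSCOPIC_REVISION
        events[ev_conv, t] = Event.CONVERSION_TO_RSA
        events[ev_rsarev, t] = Event.RSA_REVISION

        cost_t = np.zeros(n)
        cost_t[ev_rev] = c_rev
        cost_t[ev_conv] = c_conv
        cost_t[ev_rsarev] = c_rsarev

        util_t = np.where(
            (state == HealthState.INDEX_SUCCESS)
            | (state == HealthState.POST_REVISION_SUCCESS),
            strategy.u_success, target.u_success)
        any_event = ev_rev | ev_conv | ev_rsarev
        util_t = np.where(any_event, strategy.u_failure, util_t)

        disc = delta ** (t + 1)
        cycle_costs[:, t] = cost_t
        cycle_utils[:, t] = util_t
        total_cost += cost_t * disc
        total_qaly += util_t * disc

        state = state.copy()
        state[ev_rev] = (HealthState.INDEX_SUCCESS if repeat
                         else HealthState.POST_REVISION_SUCCESS)
        state[ev_conv] = HealthState.POST_CONVERSION_RSA
        state[ev_rsarev] = (HealthState.POST_CONVERSION_RSA if repeat
                            else HealthState.POST_RSA_REVISION_SUCCESS)

    return states_entering, events, cycle_costs, cycle_utils, total_cost, total_qaly


def simulate_patient(config: ModelConfig, strategy: str,
                     rng: np.random.Generator) -> PatientTrajectory:
    """Simulate one patient and return the full per-cycle trajectory."""
    states, events, costs, utils, total_cost, total_qaly = _simulate_arrays(
        config, strategy, 1, rng)
    records = tuple(
        CycleRecord(cycle=t + 1,
                    state_entering=HealthState(int(states[0, t])),
                    event=Event(int(events[0, t])),
                    cycle_utility=float(utils[0, t]),
                    cycle_cost=float(costs[0, t]))
        for t in range(config.settings.horizon_years))
    return PatientTrajectory(strategy=strategy, records=records,
                             total_cost=float(total_cost[0]),
                             total_qaly=float(total_qaly[0]))


def simulate_arm(config: ModelConfig, strategy: str, n_patients: int,
                 rng: np.random.Generator) -> ArmResult:
    """Simulate ``n_patients`` independent trajectories and average them."""
    if n_patients < 1:
        raise ValueError(f"n_patients must be >= 1, got {n_patients}")
    *_, total_cost, total_qaly = _simulate_arrays(
        config, strategy, n_patients, rng)
    ddof = 1 if n_patients > 1 else 0
    return ArmResult(
        strategy=strategy,
        mean_cost=float(total_cost.mean()),
        mean_qaly=float(total_qaly.mean()),
        n_patients=n_patients,
        sd_cost=float(total_cost.std(ddof=ddof)) if n_patients > 1 else 0.0,
        sd_qaly=float(total_qaly.std(ddof=ddof)) if n_patients > 1 else 0.0)


def cohort_expectation(config: ModelConfig, strategy: str,
                       return_occupancy: bool = False):
    """Exact expected (cost, QALY) of one arm by forward propagation.

    Propagates the state-occupancy distribution of the chain over the
    horizon, accruing expected discounted cost and utility each cycle; no
    sampling is involved.  With ``return_occupancy=True`` also returns the
    (T+1, 4) occupancy history (row 0 is the initial distribution).
    """
    strat = config.strategy(strategy)
    target = config.target
    s = config.settings
    T = s.horizon_years
    repeat = s.allow_repeat_events

    p1, p2 = strat.p_reoperation, strat.p_conversion
    pr = target.p_reoperation
    c_rev, c_conv, c_rsarev = _event_costs(strat, target, s)
    delta = 1.0 / (1.0 + s.discount_rate)

    occ = np.array([1.0, 0.0, 0.0, 0.0])
    history = np.empty((T + 1, 4))
    history[0] = occ
    cost = strat.upfront_cost
    qaly = 0.0
    for t in range(1, T + 1):
        disc = delta ** t
        e_cost = occ[0] * (p1 * c_rev + p2 * c_conv) + occ[2] * pr * c_rsarev
        e_util = (occ[0] * ((1 - p1 - p2) * strat.u_success
                            + (p1 + p2) * strat.u_failure)
                  + occ[1] * strat.u_success
                  + occ[2] * ((1 - pr) * target.u_success + pr * strat.u_failure)
                  + occ[3] * target.u_success)
        cost += e_cost * disc
        qaly += e_util * disc
        if repeat:
            # revisions return to their at-risk state; only conversion moves
            occ = np.array([occ[0] * (1 - p2),
                            0.0,
                            occ[2] + occ[0] * p2,
                            0.0])
        else:
            occ = np.array([occ[0] * (1 - p1 - p2),
                            occ[1] + occ[0] * p1,
                            occ[2] * (1 - pr) + occ[0] * p2,
                            occ[3] + occ[2] * pr])
        history[t] = occ
    if return_occupancy:
        return (float(cost), float(qaly)), history
    return float(cost), float(qaly)
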