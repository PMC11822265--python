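"""Probabilistic sensitivity analysis driver.

Each PSA iteration draws one full parameter set from the input
distributions and microsimulates every strategy arm with a fresh cohort of
patients, recording the arm means.  Random streams are derived from the
master seed through a spawned seed tree with one branch per iteration and,
inside an iteration, one branch for parameter sampling plus one per
strategy arm, so every result is reproducible and independent of
evaluation order.
"""

from __future__ import annotations

import sys
from typing import Optional

import numpy as np

from .cea_stats import IterationResult
from .markov_engine import simulate_arm
from .model_config import ModelConfig, validate_config
from .psa_distributions import build_psa_specs, sample_parameter_set

__all__ = ["run_psa"]


def run_psa(config: ModelConfig, *, seed: Optional[int] = None,
            n_iterations: Optional[int] = None,
            n_patients: Optional[int] = None,
            progress: bool = False) -> list[IterationResult]:
    """Run the full PSA and return one :class:`IterationResult` per iteration.

    ``seed``, ``n_iterations`` and ``n_patients`` default to the values in
    ``config.settings``.
    """
    validate_config(config)
    s = config.settings
    seed = s.rng_seed if seed is None else seed
    n_iterations = s.n_iterations if n_iterations is None else n_iterations
    n_patients = s.n_patients if n_patients is None else n_patients
    if n_iterations < 1 or n_patients < 1:
        raise ValueError("n_iterations and n_patients must be >= 1")

    specs = build_psa_specs(config)
    names = config.strategy_names
    master = np.random.SeedSequence(seed)
    results: list[IterationResult] = []
    for i, iteration_seed in enumerate(master.spawn(n_iterations)):
        branches = iteration_seed.spawn(1 + len(names))
        param_rng = np.random.default_rng(branches[0])
        sampled = sample_parameter_set(config, specs, param_rng)
        costs: dict[str, float] = {}
        qalys: dict[str, float] = {}
        for k, name in enumerate(names):
            arm = simulate_arm(sampled, name, n_patients,
                               np.random.default_rng(branches[1 + k]))
            costs[name] = arm.mean_cost
            qalys[name] = arm.mean_qaly
        results.append(IterationResult(iteration=i, costs=costs, qalys=qalys))
        if progress and (i + 1) % 100 == 0:
            print(f"  PSA iteration {i + 1}/{n_iterations}",
                  file=sys.stderr, flush=True)
    return results
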