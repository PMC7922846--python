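"""Synthetic inputs and an individual-level oracle for the cohort engine.

Everything the pipeline needs can be generated here with no download:
randomized but always-valid model configurations (for property tests and
fuzzing) and a Monte Carlo microsimulation that replays the exact same
transition matrices and rewards as the cohort engine on individual annual
trajectories.  Agreement between the microsimulation mean and the cohort
expectation (within Monte Carlo error) validates the cohort propagation and
discount algebra.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .life_tables import LifeTable
from .markov import HealthState, N_STATES, reward_vectors, transition_matrix
from .params import ModelConfig, default_net_config
from .sensitivity import get_parameter, set_parameter, uncertain_parameters

__all__ = [
    "default_random_bounds",
    "random_config",
    "MicrosimResult",
    "simulate_individuals",
]


def default_random_bounds(config: ModelConfig | None = None) -> dict[str, tuple[float, float]]:
    """Sampling bounds for :func:`random_config`, per dotted parameter name.

    Uncertain model parameters vary ±20% around their base value (clipped to
    the unit interval for probabilities); ages and the discount rate get
    plausible clinical ranges.  Override any entry, or collapse a bound to a
    point, by passing a modified mapping to :func:`random_config`.
    """
    config = config or default_net_config()
    bounds: dict[str, tuple[float, float]] = {}
    for name, up in uncertain_parameters(config).items():
        base = get_parameter(config, name)
        if up.family == "fixed":
            bounds[name] = (base, base)
        elif up.family == "beta":
            bounds[name] = (0.8 * base, min(1.2 * base, 1.0))
        else:
            bounds[name] = (0.8 * base, 1.2 * base)
    bounds["start_age"] = (25, 45)
    bounds["horizon_age"] = (60, 100)
    bounds["discount_rate"] = (0.0, 0.05)
    return bounds


def random_config(
    seed: int, bounds: dict[str, tuple[float, float]] | None = None
) -> ModelConfig:
    """A uniformly sampled, always-valid model configuration.

    Each parameter is drawn independently and uniformly from its bounds;
    degenerate bounds (low == high) reproduce that value exactly, so bounds
    collapsed onto the defaults return the default configuration.
    """
    base = default_net_config()
    all_bounds = default_random_bounds(base)
    if bounds:
        unknown = set(bounds) - set(all_bounds)
        if unknown:
            raise ValueError(f"unknown bound name(s): {sorted(unknown)}")
        all_bounds.update(bounds)
    for name, (lo, hi) in all_bounds.items():
        if lo > hi:
            raise ValueError(f"infeasible bounds for {name!r}: ({lo}, {hi})")
    rng = np.random.default_rng(seed)

    config = base
    # Ages first (integers), keeping the horizon strictly beyond the start.
    lo, hi = all_bounds["start_age"]
    start_age = int(rng.integers(int(lo), int(hi) + 1))
    lo, hi = all_bounds["horizon_age"]
    lo = max(int(lo), start_age + 1)
    if lo > int(hi):
        raise ValueError("horizon_age bounds incompatible with sampled start_age")
    horizon_age = int(rng.integers(lo, int(hi) + 1))
    lo, hi = all_bounds["discount_rate"]
    config = config.replace(
        start_age=start_age,
        horizon_age=horizon_age,
        discount_rate=float(rng.uniform(lo, hi)),
        seed=int(seed),
    )
    for name in sorted(set(all_bounds) - {"start_age", "horizon_age", "discount_rate"}):
        lo, hi = all_bounds[name]
        config = set_parameter(config, name, float(rng.uniform(lo, hi)))
    return config


@dataclass(frozen=True)
class MicrosimResult:
    """Per-individual discounted outcomes and their Monte Carlo summaries."""

    n: int
    costs: np.ndarray  # (n,) discounted lifetime cost per individual
    qalys: np.ndarray  # (n,) discounted lifetime QALYs per individual

    @property
    def mean_cost(self) -> float:
        return float(self.costs.mean())

    @property
    def mean_qaly(self) -> float:
        return float(self.qalys.mean())

    @property
    def se_cost(self) -> float:
        return float(self.costs.std(ddof=1) / np.sqrt(self.n))

    @property
    def se_qaly(self) -> float:
        return float(self.qalys.std(ddof=1) / np.sqrt(self.n))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cost_disc": self.costs, "qaly_disc": self.qalys})


def simulate_individuals(
    config: ModelConfig,
    life_table: LifeTable,
    start_state: HealthState,
    reward_track: str = "baseline",
    acute_cost: float = 0.0,
    n: int = 10_000,
    seed: int = 0,
) -> MicrosimResult:
    """Simulate ``n`` independent annual state trajectories.

    Uses the same transition matrices, rewards and discount indexing as
    :func:`netcea.markov.run_cohort`; the sample mean is an unbiased Monte
    Carlo estimate of the cohort expectation, with standard errors from the
    per-individual sample standard deviation.
    """
    if n < 1:
        raise ValueError("need at least one simulated individual")
    if reward_track not in ("baseline", "post_workup"):
        raise ValueError(f"unknown reward track {reward_track!r}")
    rng = np.random.default_rng(seed)
    n_cycles = config.n_cycles
    states = np.full(n, int(start_state), dtype=np.int64)
    cost = np.full(n, float(acute_cost))
    qaly = np.zeros(n)
    for k in range(1, n_cycles + 1):
        age = config.start_age + k - 1
        state_costs, state_utils = reward_vectors(
            config, post_workup_cycle=(reward_track == "post_workup" and k == 1)
        )
        d = (1.0 + config.discount_rate) ** (-(k - 1))
        cost += d * state_costs[states]
        qaly += d * state_utils[states] * config.cycle_length
        P = transition_matrix(config, age, life_table)
        cum = np.cumsum(P, axis=1)
        cum[:, -1] = 1.0  # guard against cumulative rounding
        u = rng.random(n)
        states = (cum[states] <= u[:, None]).sum(axis=1)
    return MicrosimResult(n=n, costs=cost, qalys=qaly)
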