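"""Markov cohort engine: annual-cycle state propagation with reward accrual.

State space
-----------
The lifetime model distinguishes six states:

* ``NO_RELEVANT_BURDEN`` — disease-free at entry (true negatives and false
  positives); no yearly cost, utility 1 (false positives spend their first
  cycle on the post-workup track, utility 0.779).
* ``NO_BURDEN_POST_TREATMENT`` — remission after treated disease; yearly
  follow-up cost, utility 0.779; can recur.
* ``CLIN_REL_UNTREATED`` — clinically relevant tumor burden without treatment
  (false negatives); utility 0.612, highest disease mortality; survivors are
  picked up and treated (delayed track) after one cycle.
* ``CLIN_REL_TREATED_TIMELY`` / ``CLIN_REL_TREATED_DELAYED`` — clinically
  relevant burden under treatment, utility 0.768; the tracks differ only in
  the disease-specific death risk (4.0% vs 4.5%); survivors move to
  remission after the treatment year.
* ``DEATH`` — absorbing, zero reward.

Disease-specific death, the 2.5% competing-cause risk and the age-specific
life-table background risk combine as independent competing risks:
``p_die = 1 − (1−p_disease)(1−p_competing)(1−p_background)``.

Cycles are one year; rewards are credited to the state occupied at the start
of the cycle, the first cycle is undiscounted (cycle k is discounted by
``(1+r)^−(k−1)``), and no half-cycle correction is applied, so after one
cycle a treated true positive has accrued exactly the acute treatment cost
plus one year of disease-state cost, at the raw state utility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import IntEnum
from pathlib import Path

import numpy as np
import pandas as pd

from .life_tables import LifeTable
from .params import ModelConfig

logger = logging.getLogger(__name__)

__all__ = [
    "HealthState",
    "MarkovTrace",
    "transition_matrix",
    "reward_vectors",
    "discount_factor",
    "run_cohort",
    "expected_strategy_result",
]


class HealthState(IntEnum):
    NO_RELEVANT_BURDEN = 0
    NO_BURDEN_POST_TREATMENT = 1
    CLIN_REL_UNTREATED = 2
    CLIN_REL_TREATED_TIMELY = 3
    CLIN_REL_TREATED_DELAYED = 4
    DEATH = 5


N_STATES = len(HealthState)

_STATE_LABELS = [s.name.lower() for s in HealthState]


def combined_death_prob(*annual_risks: float) -> float:
    """Combine independent annual death risks: 1 − Π(1 − p_i), clamped to [0,1].

    Probabilities that would combine above 1 (possible only with invalid
    inputs) are clamped with a warning.
    """
    p = 1.0
    for risk in annual_risks:
        p *= 1.0 - risk
    out = 1.0 - p
    if out > 1.0 or out < 0.0:
        logger.warning("combined death probability %.6f clamped to [0, 1]", out)
        out = min(1.0, max(0.0, out))
    return out


def transition_matrix(
    config: ModelConfig, age: int, life_table: LifeTable
) -> np.ndarray:
    """Annual transition matrix at ``age`` (rows = from-state, sum to 1)."""
    tr = config.transitions
    q_bg = min(1.0, life_table.q(age) * tr.relative_risk_other_death)

    die_nb = combined_death_prob(tr.p_death_competing, q_bg)
    die_untr = combined_death_prob(tr.p_death_untreated, tr.p_death_competing, q_bg)
    die_tt = combined_death_prob(tr.p_death_timely, tr.p_death_competing, q_bg)
    die_td = combined_death_prob(tr.p_death_delayed, tr.p_death_competing, q_bg)

    P = np.zeros((N_STATES, N_STATES))
    s = HealthState
    # Disease-free states: background/competing death, then progression or
    # recurrence into treated (timely-track) disease.
    for state in (s.NO_RELEVANT_BURDEN, s.NO_BURDEN_POST_TREATMENT):
        P[state, s.DEATH] = die_nb
        P[state, s.CLIN_REL_TREATED_TIMELY] = (1.0 - die_nb) * tr.p_progression
        P[state, state] = (1.0 - die_nb) * (1.0 - tr.p_progression)
    # Untreated disease: high mortality; survivors are diagnosed and treated.
    P[s.CLIN_REL_UNTREATED, s.DEATH] = die_untr
    P[s.CLIN_REL_UNTREATED, s.CLIN_REL_TREATED_DELAYED] = (
        1.0 - die_untr
    ) * tr.p_untreated_to_treated
    P[s.CLIN_REL_UNTREATED, s.CLIN_REL_UNTREATED] = (1.0 - die_untr) * (
        1.0 - tr.p_untreated_to_treated
    )
    # Treated disease: treatment-year mortality; survivors reach remission.
    P[s.CLIN_REL_TREATED_TIMELY, s.DEATH] = die_tt
    P[s.CLIN_REL_TREATED_TIMELY, s.NO_BURDEN_POST_TREATMENT] = 1.0 - die_tt
    P[s.CLIN_REL_TREATED_DELAYED, s.DEATH] = die_td
    P[s.CLIN_REL_TREATED_DELAYED, s.NO_BURDEN_POST_TREATMENT] = 1.0 - die_td
    P[s.DEATH, s.DEATH] = 1.0
    return P


def reward_vectors(
    config: ModelConfig, post_workup_cycle: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """(yearly cost, utility) per state.

    ``post_workup_cycle`` switches the disease-free state to the post-workup
    utility (0.779) for the first cycle of a false-positive cohort.
    """
    c, u = config.costs, config.utilities
    costs = np.array(
        [
            c.yearly_no_burden,
            c.yearly_treated_non_relevant,
            c.yearly_clinically_relevant,
            c.yearly_clinically_relevant,
            c.yearly_clinically_relevant,
            0.0,
        ]
    )
    utils = np.array(
        [
            u.no_clinically_relevant_burden if post_workup_cycle else u.no_burden,
            u.no_clinically_relevant_burden,
            u.progression_untreated,
            u.clinically_relevant_treated,
            u.clinically_relevant_treated,
            u.death,
        ]
    )
    return costs, utils


def discount_factor(rate: float, cycle_index: int) -> float:
    """Discount multiplier for 1-based ``cycle_index``; cycle 1 is undiscounted."""
    if cycle_index < 1:
        raise ValueError("cycle_index is 1-based")
    return (1.0 + rate) ** (-(cycle_index - 1))


@dataclass(frozen=True)
class MarkovTrace:
    """Per-cycle cohort occupancy and reward accumulators of one cohort run."""

    frame: pd.DataFrame  # one row per cycle

    @property
    def total_discounted_cost(self) -> float:
        return float(self.frame["cum_cost_disc"].iloc[-1])

    @property
    def total_discounted_qaly(self) -> float:
        return float(self.frame["cum_qaly_disc"].iloc[-1])

    def occupancy(self) -> np.ndarray:
        return self.frame[_STATE_LABELS].to_numpy()

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


def run_cohort(
    config: ModelConfig,
    life_table: LifeTable,
    start_state: HealthState,
    reward_track: str = "baseline",
    acute_cost: float = 0.0,
) -> MarkovTrace:
    """Propagate a unit cohort from ``start_age`` to ``horizon_age``.

    ``acute_cost`` is added, undiscounted, in the first cycle.  The
    ``reward_track`` is ``"post_workup"`` for false-positive cohorts, whose
    first cycle in the disease-free state is rewarded at the post-workup
    utility instead of 1.
    """
    if reward_track not in ("baseline", "post_workup"):
        raise ValueError(f"unknown reward track {reward_track!r}")
    n_cycles = config.n_cycles
    if n_cycles < 1:
        raise ValueError("horizon_age must exceed start_age")
    # Raises if the life table does not cover the model ages.
    life_table.q_slice(config.start_age, config.horizon_age)

    occ = np.zeros(N_STATES)
    occ[int(start_state)] = 1.0
    rows = []
    cum_cost = cum_qaly = 0.0
    for k in range(1, n_cycles + 1):
        age = config.start_age + k - 1
        state_costs, state_utils = reward_vectors(
            config, post_workup_cycle=(reward_track == "post_workup" and k == 1)
        )
        d = discount_factor(config.discount_rate, k)
        cost = float(occ @ state_costs) + (acute_cost if k == 1 else 0.0)
        qaly = float(occ @ state_utils) * config.cycle_length
        cum_cost += cost * d
        cum_qaly += qaly * d
        rows.append(
            {
                "cycle": k,
                "age": age,
                **{lbl: occ[i] for i, lbl in enumerate(_STATE_LABELS)},
                "cost_undisc": cost,
                "qaly_undisc": qaly,
                "cost_disc": cost * d,
                "qaly_disc": qaly * d,
                "cum_cost_disc": cum_cost,
                "cum_qaly_disc": cum_qaly,
            }
        )
        occ = occ @ transition_matrix(config, age, life_table)
    return MarkovTrace(frame=pd.DataFrame(rows))


def expected_strategy_result(
    config: ModelConfig, strategy, life_table: LifeTable
):
    """Probability-weighted lifetime result of one strategy over its branches.

    Returns a :class:`netcea.cea.StrategyResult` with expected discounted
    lifetime cost (including acute diagnostic-outcome costs) and QALYs.
    """
    from .cea import StrategyResult
    from .diagnostic_tree import outcome_distribution

    dist = outcome_distribution(config, strategy)
    cost = qaly = 0.0
    for b in dist.branches:
        trace = run_cohort(
            config,
            life_table,
            start_state=b.state,
            reward_track=b.reward_track,
            acute_cost=b.acute_cost,
        )
        cost += b.probability * trace.total_discounted_cost
        qaly += b.probability * trace.total_discounted_qaly
    return StrategyResult(strategy=strategy.name, cost=cost, qaly=qaly)
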