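"""Diagnostic decision tree: from prevalence and test accuracy to model entry.

Each imaging strategy partitions the cohort into the four classic diagnostic
outcomes.  True positives enter the Markov model in the clinically relevant
treated state (timely track) after incurring imaging, confirmatory biopsy and
timely surgery + treatment costs.  False negatives enter untreated and later
incur the (more expensive) delayed surgery + treatment.  True negatives and
false positives both enter the no-relevant-tumor-burden state; false
positives additionally pay for an unnecessary biopsy and spend their first
cycle on the post-workup utility track.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .markov import HealthState
from .params import CostSet, DiagnosticStrategy, ModelConfig, TestPerformance

__all__ = [
    "Outcome",
    "OutcomeBranch",
    "OutcomeDistribution",
    "outcome_probabilities",
    "acute_cost",
    "acute_cost_components",
    "start_state",
    "outcome_distribution",
]


class Outcome(str, Enum):
    TP = "TP"
    FP = "FP"
    TN = "TN"
    FN = "FN"


#: Markov starting state and utility reward track for each diagnostic outcome.
_START = {
    Outcome.TP: (HealthState.CLIN_REL_TREATED_TIMELY, "baseline"),
    Outcome.FN: (HealthState.CLIN_REL_UNTREATED, "baseline"),
    Outcome.TN: (HealthState.NO_RELEVANT_BURDEN, "baseline"),
    Outcome.FP: (HealthState.NO_RELEVANT_BURDEN, "post_workup"),
}


def outcome_probabilities(
    prevalence: float, perf: TestPerformance
) -> dict[Outcome, float]:
    """Branch probabilities of the four diagnostic outcomes.

    p(TP) = prevalence·sens, p(FN) = prevalence·(1−sens),
    p(TN) = (1−prevalence)·spec, p(FP) = (1−prevalence)·(1−spec); the four
    always sum to one.
    """
    for name, value in (
        ("prevalence", prevalence),
        ("sensitivity", perf.sensitivity),
        ("specificity", perf.specificity),
    ):
        if not (0.0 <= value <= 1.0):
            raise ValueError(f"{name} = {value!r} outside [0, 1]")
    return {
        Outcome.TP: prevalence * perf.sensitivity,
        Outcome.FN: prevalence * (1.0 - perf.sensitivity),
        Outcome.TN: (1.0 - prevalence) * perf.specificity,
        Outcome.FP: (1.0 - prevalence) * (1.0 - perf.specificity),
    }


def acute_cost_components(
    strategy: DiagnosticStrategy,
    outcome: Outcome,
    costs: CostSet,
    charge_biopsy_to_test_positives: bool = True,
) -> dict[str, float]:
    """Acute-cost breakdown {imaging, workup, treatment} for one outcome.

    Imaging is always charged.  Test-positives (TP, FP) receive the
    confirmatory workup: the biopsy for TP (when
    ``charge_biopsy_to_test_positives``) and the unnecessary biopsy for FP.
    Treatment is timely surgery+treatment for TP and delayed for FN.
    """
    outcome = Outcome(outcome)
    workup = 0.0
    treatment = 0.0
    if outcome is Outcome.TP:
        if charge_biopsy_to_test_positives:
            workup = costs.biopsy
        treatment = costs.timely_treatment
    elif outcome is Outcome.FP:
        workup = costs.unnecessary_biopsy
    elif outcome is Outcome.FN:
        treatment = costs.delayed_treatment
    elif outcome is Outcome.TN:
        treatment = costs.true_negative_acute
    return {
        "imaging": strategy.imaging_cost,
        "workup": workup,
        "treatment": treatment,
    }


def acute_cost(
    strategy: DiagnosticStrategy,
    outcome: Outcome,
    costs: CostSet,
    charge_biopsy_to_test_positives: bool = True,
) -> float:
    """Total acute (cycle-1, undiscounted) cost of one diagnostic outcome."""
    return sum(
        acute_cost_components(
            strategy, outcome, costs, charge_biopsy_to_test_positives
        ).values()
    )


def start_state(outcome: Outcome) -> tuple[HealthState, str]:
    """(Markov starting state, utility reward track) for a diagnostic outcome."""
    return _START[Outcome(outcome)]


@dataclass(frozen=True)
class OutcomeBranch:
    outcome: Outcome
    probability: float
    acute_cost: float
    treatment_cost: float  # treatment component only (calibration view)
    state: HealthState
    reward_track: str


@dataclass(frozen=True)
class OutcomeDistribution:
    """The four diagnostic branches of one strategy, with entry conditions."""

    strategy: str
    branches: tuple[OutcomeBranch, ...]

    def branch(self, outcome: Outcome) -> OutcomeBranch:
        for b in self.branches:
            if b.outcome is Outcome(outcome):
                return b
        raise KeyError(outcome)


def outcome_distribution(
    config: ModelConfig, strategy: DiagnosticStrategy
) -> OutcomeDistribution:
    """Build the full outcome distribution of one strategy from a config."""
    probs = outcome_probabilities(config.prevalence, strategy.performance)
    branches = []
    for outcome, p in probs.items():
        comps = acute_cost_components(
            strategy, outcome, config.costs, config.charge_biopsy_to_test_positives
        )
        state, track = start_state(outcome)
        branches.append(
            OutcomeBranch(
                outcome=outcome,
                probability=p,
                acute_cost=sum(comps.values()),
                treatment_cost=comps["treatment"],
                state=state,
                reward_track=track,
            )
        )
    return OutcomeDistribution(strategy=strategy.name, branches=tuple(branches))
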