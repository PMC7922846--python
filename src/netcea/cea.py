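"""Cost-effectiveness comparisons: ICER, dominance, frontier, net benefit.

The incremental cost-effectiveness ratio between strategies a and b is
ICER = (C_a − C_b) / (E_a − E_b).  A strategy that is cheaper and more
effective dominates its comparator; ratios are never reported for dominance
quadrants (a negative ICER is ambiguous), only flags.  The efficiency
frontier sorts strategies by cost, removes dominated and extended-dominated
options and reports strictly increasing sequential ICERs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "StrategyResult",
    "ICERTableRow",
    "icer",
    "frontier",
    "net_monetary_benefit",
    "icer_table",
]

DOMINANT = "dominant"
DOMINATED = "dominated"
EXTENDED_DOMINATED = "extended-dominated"
EQUIVALENT = "equivalent"


@dataclass(frozen=True)
class StrategyResult:
    """Expected discounted lifetime cost (USD) and QALYs of one strategy."""

    strategy: str
    cost: float
    qaly: float

    def nmb(self, wtp: float) -> float:
        return net_monetary_benefit(self, wtp)


@dataclass(frozen=True)
class ICERTableRow:
    """One incremental comparison; ``icer`` and ``flag`` are mutually exclusive."""

    strategy: str
    comparator: str
    delta_cost: float
    delta_effect: float
    icer: float | None
    flag: str | None


def icer(a: StrategyResult, b: StrategyResult) -> ICERTableRow:
    """Incremental comparison of strategy ``a`` against comparator ``b``.

    Dominance quadrants (including the zero-increment edges) are reported as
    flags; a numeric ratio is returned only when both increments share sign.
    """
    dc = a.cost - b.cost
    de = a.qaly - b.qaly
    flag = None
    ratio = None
    if dc == 0.0 and de == 0.0:
        flag = EQUIVALENT
    elif dc <= 0.0 and de >= 0.0:
        flag = DOMINANT
    elif dc >= 0.0 and de <= 0.0:
        flag = DOMINATED
    else:
        ratio = dc / de
    return ICERTableRow(
        strategy=a.strategy,
        comparator=b.strategy,
        delta_cost=dc,
        delta_effect=de,
        icer=ratio,
        flag=flag,
    )


def net_monetary_benefit(r: StrategyResult, wtp: float) -> float:
    """NMB = wtp · QALY − cost; the NMB maximizer is the cost-effective choice."""
    if wtp < 0.0:
        raise ValueError("willingness-to-pay must be non-negative")
    return wtp * r.qaly - r.cost


def frontier(results: Sequence[StrategyResult]) -> list[StrategyResult]:
    """Efficiency frontier: non-dominated strategies in increasing cost order.

    Strategies are sorted by cost (ties broken by higher effect); strictly and
    extended-dominated strategies are removed so that sequential ICERs along
    the frontier are strictly increasing.  The output does not depend on the
    input order.
    """
    if not results:
        raise ValueError("frontier needs at least one strategy result")
    ordered = sorted(results, key=lambda r: (r.cost, -r.qaly, r.strategy))
    kept: list[StrategyResult] = []
    for cand in ordered:
        if kept and cand.qaly <= kept[-1].qaly:
            continue  # weakly dominated: costlier (or tied) and no more effective
        kept.append(cand)
        # Extended dominance: pop middle strategies whose sequential ICER is
        # not strictly below the ICER to the next option.
        while len(kept) >= 3:
            a, b, c = kept[-3], kept[-2], kept[-1]
            icer_ab = (b.cost - a.cost) / (b.qaly - a.qaly)
            icer_bc = (c.cost - b.cost) / (c.qaly - b.qaly)
            if icer_ab >= icer_bc:
                kept.pop(-2)
            else:
                break
    return kept


def icer_table(
    results: Iterable[StrategyResult], reference: str | None = None
) -> pd.DataFrame:
    """Incremental table of every strategy against a common comparator.

    The comparator defaults to the cheapest strategy.  Frontier membership is
    reported in an ``on_frontier`` column; strategies off the frontier that
    are not pairwise dominated are flagged ``extended-dominated``.
    """
    results = list(results)
    if reference is None:
        ref = min(results, key=lambda r: (r.cost, -r.qaly))
    else:
        ref = next(r for r in results if r.strategy == reference)
    front = {r.strategy for r in frontier(results)}
    rows = []
    for r in results:
        row = icer(r, ref)
        flag = row.flag
        if r.strategy not in front and flag not in (DOMINATED,):
            flag = EXTENDED_DOMINATED if flag is None else flag
        rows.append(
            {
                "strategy": r.strategy,
                "cost": r.cost,
                "qaly": r.qaly,
                "comparator": ref.strategy,
                "delta_cost": row.delta_cost,
                "delta_effect": row.delta_effect,
                "icer": row.icer,
                "flag": None if r.strategy == ref.strategy else flag,
                "on_frontier": r.strategy in front,
            }
        )
    return pd.DataFrame(rows)
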