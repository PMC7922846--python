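"""High-level modelling interface: build a decision model, run it, summarize.

`DecisionModel` bundles a :class:`~netcea.params.ModelConfig` with a life
table and exposes the three analyses as methods; `CEAResults` carries the
per-strategy expectations, the incremental table and the efficiency
frontier, with a human-readable ``summary()``.

Example
-------
>>> from netcea import DecisionModel
>>> model = DecisionModel()           # published base case, bundled life table
>>> res = model.run()
>>> print(res.summary())              # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import life_tables, sensitivity
from .cea import StrategyResult, frontier, icer_table
from .life_tables import LifeTable
from .markov import expected_strategy_result, run_cohort
from .params import ModelConfig, default_net_config, load_config, validate_config
from .params import ConfigError

__all__ = ["DecisionModel", "CEAResults"]


@dataclass(frozen=True)
class CEAResults:
    """Base-case results: expected lifetime cost and QALYs per strategy."""

    config: ModelConfig
    results: tuple[StrategyResult, ...]

    def result(self, name: str) -> StrategyResult:
        for r in self.results:
            if r.strategy == name:
                return r
        raise KeyError(f"no result for strategy {name!r}")

    @property
    def frontier(self) -> list[StrategyResult]:
        return frontier(self.results)

    def table(self, reference: str | None = None) -> pd.DataFrame:
        return icer_table(self.results, reference=reference)

    def summary(self) -> str:
        """Plain-text summary table (costs to the cent, QALYs to 3 decimals)."""
        df = self.table()
        lines = [
            "Cost-effectiveness analysis "
            f"(WTP ${self.config.wtp:,.0f}/QALY, "
            f"discount {self.config.discount_rate:.1%}, "
            f"ages {self.config.start_age}-{self.config.horizon_age})",
            "",
            f"{'strategy':<12}{'cost ($)':>14}{'QALYs':>9}"
            f"{'Δcost ($)':>14}{'ΔQALYs':>9}  {'ICER / status':<18}",
        ]
        for _, row in df.iterrows():
            if row["strategy"] == row["comparator"]:
                status = "(comparator)"
            elif row["flag"] is not None:
                status = str(row["flag"])
            else:
                status = f"{row['icer']:,.0f} $/QALY"
            lines.append(
                f"{row['strategy']:<12}{row['cost']:>14,.2f}{row['qaly']:>9.3f}"
                f"{row['delta_cost']:>14,.2f}{row['delta_effect']:>9.3f}  {status:<18}"
            )
        front = ", ".join(r.strategy for r in self.frontier)
        lines += ["", f"efficiency frontier: {front}"]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"strategy": r.strategy, "cost": r.cost, "qaly": r.qaly} for r in self.results]
        )


class DecisionModel:
    """The diagnostic-workup decision model: decision tree + Markov cohort.

    Parameters
    ----------
    config
        Model configuration; the published base case when omitted.
    life_table
        Background-mortality table; the bundled synthetic US-style table
        when omitted (or when ``config.life_table_ref`` is ``"bundled"``).
    """

    def __init__(
        self,
        config: ModelConfig | None = None,
        life_table: LifeTable | None = None,
    ) -> None:
        self.config = config if config is not None else default_net_config()
        violations = validate_config(self.config)
        if violations:
            raise ConfigError("invalid configuration: " + "; ".join(violations))
        if life_table is not None:
            self.life_table = life_table
        elif self.config.life_table_ref in ("bundled", "", None):
            self.life_table = life_tables.load_bundled()
        else:
            self.life_table = life_tables.load_life_table(self.config.life_table_ref)

    @classmethod
    def from_config(cls, path: str | Path) -> "DecisionModel":
        return cls(config=load_config(path))

    def run(self) -> CEAResults:
        """Evaluate every strategy's expected lifetime cost and QALYs."""
        results = tuple(
            expected_strategy_result(self.config, s, self.life_table)
            for s in self.config.strategies
        )
        return CEAResults(config=self.config, results=results)

    def cohort_trace(self, start_state, reward_track="baseline", acute_cost=0.0):
        """Markov trace of a single cohort (see :func:`netcea.markov.run_cohort`)."""
        return run_cohort(
            self.config, self.life_table, start_state, reward_track, acute_cost
        )

    def tornado(self, params=None, focal: str = "PET/CT") -> pd.DataFrame:
        return sensitivity.tornado(self.config, self.life_table, params, focal=focal)

    def psa(self, n: int | None = None, seed: int | None = None):
        return sensitivity.sample_psa(self.config, self.life_table, n=n, seed=seed)
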