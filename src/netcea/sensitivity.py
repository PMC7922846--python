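"""Deterministic (tornado) and probabilistic sensitivity analysis.

One-way deterministic analysis re-runs the full decision pipeline at the low
and high end of a parameter's range (default ±20% of the base value, clipped
to the parameter's domain) with everything else at base values, and records
the incremental net monetary benefit of the focal strategy against the best
comparator at the configured willingness-to-pay.

Probabilistic sensitivity analysis draws every uncertain parameter
independently from its second-order distribution — beta for probabilities
and utilities (moment-matched via an effective sample size), gamma for costs
(moment-matched via a coefficient of variation) — re-evaluates all
strategies per draw with a vectorized cohort engine, and summarizes the
draws as cost-effectiveness acceptability curves over a willingness-to-pay
grid and as incremental cost-effect scatters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import markov
from .cea import StrategyResult, net_monetary_benefit
from .life_tables import LifeTable
from .markov import HealthState, expected_strategy_result
from .params import (
    ModelConfig,
    UncertainParam,
    beta_params_from_mean,
    gamma_params_from_mean,
)

__all__ = [
    "uncertain_parameters",
    "get_parameter",
    "set_parameter",
    "default_dsa_parameters",
    "TornadoBar",
    "one_way_dsa",
    "tornado",
    "PSASamples",
    "sample_psa",
    "ceac",
    "incremental_scatter",
]

_S = HealthState


# ---------------------------------------------------------------------------
# Parameter registry (dotted names shared by DSA, PSA and the config fuzzer)
# ---------------------------------------------------------------------------

_COST_FIELDS = (
    "timely_treatment",
    "delayed_treatment",
    "unnecessary_biopsy",
    "true_negative_acute",
    "biopsy",
    "yearly_no_burden",
    "yearly_treated_non_relevant",
    "yearly_clinically_relevant",
)
_UTILITY_FIELDS = (
    "no_burden",
    "no_clinically_relevant_burden",
    "clinically_relevant_treated",
    "progression_untreated",
)
_TRANSITION_FIELDS = (
    "p_death_timely",
    "p_death_delayed",
    "p_death_untreated",
    "p_death_competing",
    "p_progression",
    "p_untreated_to_treated",
)


def get_parameter(config: ModelConfig, name: str) -> float:
    """Read a model parameter by its dotted registry name."""
    if name == "prevalence":
        return config.prevalence
    section, _, fld = name.partition(".")
    if section in ("costs", "utilities", "transitions"):
        obj = getattr(config, section)
        if not hasattr(obj, fld):
            raise KeyError(f"unknown parameter {name!r}")
        return getattr(obj, fld)
    strategy = config.strategy(section)
    if fld == "imaging_cost":
        return strategy.imaging_cost
    if fld in ("sensitivity", "specificity"):
        return getattr(strategy.performance, fld)
    raise KeyError(f"unknown parameter {name!r}")


def set_parameter(config: ModelConfig, name: str, value: float) -> ModelConfig:
    """Return a copy of ``config`` with one registry parameter replaced."""
    from dataclasses import replace

    if name == "prevalence":
        return config.replace(prevalence=float(value))
    section, _, fld = name.partition(".")
    if section in ("costs", "utilities", "transitions"):
        obj = getattr(config, section)
        if not hasattr(obj, fld):
            raise KeyError(f"unknown parameter {name!r}")
        return config.replace(**{section: replace(obj, **{fld: float(value)})})
    strategy = config.strategy(section)  # raises KeyError for unknown names
    if fld == "imaging_cost":
        new = replace(strategy, imaging_cost=float(value))
    elif fld in ("sensitivity", "specificity"):
        new = replace(
            strategy, performance=replace(strategy.performance, **{fld: float(value)})
        )
    else:
        raise KeyError(f"unknown parameter {name!r}")
    return config.replace(
        strategies=tuple(new if s.name == section else s for s in config.strategies)
    )


def parameter_domain(name: str) -> tuple[float, float]:
    """Admissible (low, high) range of a registry parameter."""
    if name == "prevalence" or name.split(".")[0] in ("utilities", "transitions"):
        return 0.0, 1.0
    if name.endswith((".sensitivity", ".specificity")):
        return 0.0, 1.0
    return 0.0, np.inf


def _spread(config: ModelConfig, name: str, family: str) -> float:
    overrides: Mapping[str, float] = config.psa_spread_overrides
    if name in overrides:
        return overrides[name]
    return config.psa_ess if family == "beta" else config.psa_cv


def uncertain_parameters(config: ModelConfig) -> dict[str, UncertainParam]:
    """Second-order distributions of every uncertain parameter.

    Probabilities and utilities are beta distributed, costs gamma distributed,
    following the published distribution assignments.  Parameters whose base
    value sits on the boundary of the family's support (utility 1, cost 0,
    transition probability 1) degenerate to point masses and are kept fixed.
    """
    params: dict[str, UncertainParam] = {}

    def add(name: str, mean: float, family: str) -> None:
        if family == "beta" and not (0.0 < mean < 1.0):
            family = "fixed"
        if family == "gamma" and mean <= 0.0:
            family = "fixed"
        spread = None if family == "fixed" else _spread(config, name, family)
        params[name] = UncertainParam(mean=mean, family=family, spread=spread)

    add("prevalence", config.prevalence, "beta")
    for s in config.strategies:
        add(f"{s.name}.sensitivity", s.performance.sensitivity, "beta")
        add(f"{s.name}.specificity", s.performance.specificity, "beta")
        add(f"{s.name}.imaging_cost", s.imaging_cost, "gamma")
    for fld in _COST_FIELDS:
        add(f"costs.{fld}", getattr(config.costs, fld), "gamma")
    for fld in _UTILITY_FIELDS:
        add(f"utilities.{fld}", getattr(config.utilities, fld), "beta")
    for fld in _TRANSITION_FIELDS:
        add(f"transitions.{fld}", getattr(config.transitions, fld), "beta")
    return params


def default_dsa_parameters(config: ModelConfig) -> list[str]:
    """The default tornado sweep: diagnostic accuracy and diagnostic costs."""
    names: list[str] = []
    for s in config.strategies:
        names += [f"{s.name}.sensitivity", f"{s.name}.specificity"]
    names += [f"{s.name}.imaging_cost" for s in config.strategies]
    names.append("costs.biopsy")
    return names


# ---------------------------------------------------------------------------
# Deterministic one-way sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TornadoBar:
    """Incremental-NMB swing of one parameter across its one-way range."""

    parameter: str
    base: float
    low: float
    high: float
    nmb_low: float
    nmb_high: float

    @property
    def width(self) -> float:
        return abs(self.nmb_high - self.nmb_low)


def _incremental_nmb(
    config: ModelConfig, life_table: LifeTable, focal: str
) -> float:
    """NMB of the focal strategy minus the best comparator NMB, at config.wtp."""
    nmbs = {
        s.name: net_monetary_benefit(
            expected_strategy_result(config, s, life_table), config.wtp
        )
        for s in config.strategies
    }
    focal_nmb = nmbs.pop(focal)
    return focal_nmb - max(nmbs.values())


def one_way_dsa(
    config: ModelConfig,
    life_table: LifeTable,
    param: str,
    low: float | None = None,
    high: float | None = None,
    focal: str = "PET/CT",
) -> TornadoBar:
    """Re-run the pipeline at both ends of one parameter's range.

    Unspecified bounds default to base ± ``config.dsa_fraction``·base, clipped
    to the parameter's domain.
    """
    base = get_parameter(config, param)  # raises for unknown names
    lo_dom, hi_dom = parameter_domain(param)
    if low is None:
        low = max(lo_dom, base * (1.0 - config.dsa_fraction))
    if high is None:
        high = min(hi_dom, base * (1.0 + config.dsa_fraction))
    if low > high:
        raise ValueError(f"low {low!r} exceeds high {high!r} for {param!r}")
    if not (lo_dom <= low <= hi_dom and lo_dom <= high <= hi_dom):
        raise ValueError(f"range [{low}, {high}] outside domain of {param!r}")
    nmb_low = _incremental_nmb(set_parameter(config, param, low), life_table, focal)
    nmb_high = _incremental_nmb(set_parameter(config, param, high), life_table, focal)
    return TornadoBar(
        parameter=param, base=base, low=low, high=high,
        nmb_low=nmb_low, nmb_high=nmb_high,
    )


def tornado(
    config: ModelConfig,
    life_table: LifeTable,
    params: Sequence[str] | None = None,
    focal: str = "PET/CT",
) -> pd.DataFrame:
    """One-way sweeps of all requested parameters, sorted by bar width."""
    if params is None:
        params = default_dsa_parameters(config)
    columns = [
        "parameter", "base", "low", "high",
        "incremental_nmb_low", "incremental_nmb_high", "width",
    ]
    if not params:
        import logging

        logging.getLogger(__name__).warning("empty DSA parameter list: empty tornado")
        return pd.DataFrame(columns=columns)
    bars = [one_way_dsa(config, life_table, p, focal=focal) for p in params]
    df = pd.DataFrame(
        [
            {
                "parameter": b.parameter,
                "base": b.base,
                "low": b.low,
                "high": b.high,
                "incremental_nmb_low": b.nmb_low,
                "incremental_nmb_high": b.nmb_high,
                "width": b.width,
            }
            for b in bars
        ]
    )
    return df.sort_values("width", ascending=False, kind="mergesort").reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis (vectorized over draws)
# ---------------------------------------------------------------------------

@dataclass
class PSASamples:
    """Monte Carlo parameter draws and the per-strategy results they imply."""

    seed: int
    draws: pd.DataFrame  # one column per sampled parameter, one row per draw
    costs: dict[str, np.ndarray]  # strategy -> (n,) expected cost per draw
    qalys: dict[str, np.ndarray]  # strategy -> (n,) expected QALYs per draw
    wtp: float = 100_000.0
    strategies: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        self.strategies = tuple(self.costs)

    @property
    def n(self) -> int:
        return len(self.draws)

    def nmb(self, wtp: float | None = None) -> pd.DataFrame:
        wtp = self.wtp if wtp is None else wtp
        return pd.DataFrame(
            {s: wtp * self.qalys[s] - self.costs[s] for s in self.strategies}
        )

    def results_frame(self) -> pd.DataFrame:
        """Long-format per-draw results (draw, strategy, cost, qaly)."""
        frames = [
            pd.DataFrame(
                {
                    "draw": np.arange(self.n),
                    "strategy": s,
                    "cost": self.costs[s],
                    "qaly": self.qalys[s],
                }
            )
            for s in self.strategies
        ]
        return pd.concat(frames, ignore_index=True)


def _batch_transition(
    q_bg: float,
    tr: Mapping[str, np.ndarray],
) -> np.ndarray:
    """(n, 6, 6) transition tensor for one model age across all draws."""
    n = len(tr["p_death_competing"])
    bg = np.minimum(1.0, q_bg * tr["relative_risk_other_death"])
    die_nb = 1.0 - (1.0 - tr["p_death_competing"]) * (1.0 - bg)
    die_untr = 1.0 - (1.0 - tr["p_death_untreated"]) * (1.0 - tr["p_death_competing"]) * (1.0 - bg)
    die_tt = 1.0 - (1.0 - tr["p_death_timely"]) * (1.0 - tr["p_death_competing"]) * (1.0 - bg)
    die_td = 1.0 - (1.0 - tr["p_death_delayed"]) * (1.0 - tr["p_death_competing"]) * (1.0 - bg)
    prog = tr["p_progression"]
    p_ut = tr["p_untreated_to_treated"]

    P = np.zeros((n, markov.N_STATES, markov.N_STATES))
    for st in (_S.NO_RELEVANT_BURDEN, _S.NO_BURDEN_POST_TREATMENT):
        P[:, st, _S.DEATH] = die_nb
        P[:, st, _S.CLIN_REL_TREATED_TIMELY] = (1.0 - die_nb) * prog
        P[:, st, st] = (1.0 - die_nb) * (1.0 - prog)
    P[:, _S.CLIN_REL_UNTREATED, _S.DEATH] = die_untr
    P[:, _S.CLIN_REL_UNTREATED, _S.CLIN_REL_TREATED_DELAYED] = (1.0 - die_untr) * p_ut
    P[:, _S.CLIN_REL_UNTREATED, _S.CLIN_REL_UNTREATED] = (1.0 - die_untr) * (1.0 - p_ut)
    P[:, _S.CLIN_REL_TREATED_TIMELY, _S.DEATH] = die_tt
    P[:, _S.CLIN_REL_TREATED_TIMELY, _S.NO_BURDEN_POST_TREATMENT] = 1.0 - die_tt
    P[:, _S.CLIN_REL_TREATED_DELAYED, _S.DEATH] = die_td
    P[:, _S.CLIN_REL_TREATED_DELAYED, _S.NO_BURDEN_POST_TREATMENT] = 1.0 - die_td
    P[:, _S.DEATH, _S.DEATH] = 1.0
    return P


def _lifetime_branches(
    config: ModelConfig,
    life_table: LifeTable,
    draw: Mapping[str, np.ndarray],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Discounted Markov (cost, qaly) per draw for each branch start.

    Returns arrays for the TP, FN, TN and FP starting conditions, excluding
    acute costs (added by the strategy aggregation).  The FP branch shares
    the TN trajectory; only its first-cycle utility differs.
    """
    n = len(draw["prevalence"])
    qx = life_table.q_slice(config.start_age, config.horizon_age)
    n_cycles = config.n_cycles
    disc = (1.0 + config.discount_rate) ** (-(np.arange(1, n_cycles + 1) - 1.0))

    tr = {k.split(".")[1]: draw[k] for k in draw if k.startswith("transitions.")}
    u_nb = draw["utilities.no_burden"]
    u_post = draw["utilities.no_clinically_relevant_burden"]
    state_costs = np.stack(
        [
            draw["costs.yearly_no_burden"],
            draw["costs.yearly_treated_non_relevant"],
            draw["costs.yearly_clinically_relevant"],
            draw["costs.yearly_clinically_relevant"],
            draw["costs.yearly_clinically_relevant"],
            np.zeros(n),
        ],
        axis=1,
    )
    state_utils = np.stack(
        [
            u_nb,
            u_post,
            draw["utilities.progression_untreated"],
            draw["utilities.clinically_relevant_treated"],
            draw["utilities.clinically_relevant_treated"],
            np.zeros(n),
        ],
        axis=1,
    )

    starts = {
        "TP": _S.CLIN_REL_TREATED_TIMELY,
        "FN": _S.CLIN_REL_UNTREATED,
        "TN": _S.NO_RELEVANT_BURDEN,
    }
    occ = np.zeros((len(starts), n, markov.N_STATES))
    for i, st in enumerate(starts.values()):
        occ[i, :, st] = 1.0
    cost_acc = np.zeros((len(starts), n))
    qaly_acc = np.zeros((len(starts), n))
    for k in range(n_cycles):
        cost_acc += disc[k] * np.einsum("snj,nj->sn", occ, state_costs)
        qaly_acc += disc[k] * np.einsum("snj,nj->sn", occ, state_utils) * config.cycle_length
        P = _batch_transition(qx[k], tr)
        occ = np.einsum("snj,njk->snk", occ, P)

    out = {label: (cost_acc[i], qaly_acc[i]) for i, label in enumerate(starts)}
    # FP: identical trajectory to TN, but the first (undiscounted) cycle is
    # rewarded at the post-workup utility instead of the disease-free utility.
    tn_cost, tn_qaly = out["TN"]
    out["FP"] = (tn_cost, tn_qaly - (u_nb - u_post) * config.cycle_length)
    return out


def sample_psa(
    config: ModelConfig,
    life_table: LifeTable,
    n: int | None = None,
    seed: int | None = None,
) -> PSASamples:
    """Draw ``n`` parameter sets and evaluate every strategy per draw.

    Draws are independent across parameters, reproducible under ``seed``
    (defaulting to ``config.seed``), and evaluated with a vectorized version
    of the cohort engine.
    """
    n = config.psa_iterations if n is None else int(n)
    if n < 1:
        raise ValueError("need at least one PSA iteration")
    seed = config.seed if seed is None else int(seed)
    rng = np.random.default_rng(seed)

    params = uncertain_parameters(config)
    draw: dict[str, np.ndarray] = {}
    for name, up in params.items():
        if up.family == "beta":
            a, b = beta_params_from_mean(up.mean, up.spread)
            draw[name] = rng.beta(a, b, n)
        elif up.family == "gamma":
            shape, scale = gamma_params_from_mean(up.mean, up.spread)
            draw[name] = rng.gamma(shape, scale, n)
        else:
            draw[name] = np.full(n, up.mean)
    # Parameters the model needs but that are not in the uncertain registry.
    draw.setdefault(
        "transitions.relative_risk_other_death",
        np.full(n, config.transitions.relative_risk_other_death),
    )
    draw.setdefault("utilities.no_burden", np.full(n, config.utilities.no_burden))

    branch = _lifetime_branches(config, life_table, draw)

    costs: dict[str, np.ndarray] = {}
    qalys: dict[str, np.ndarray] = {}
    prev = draw["prevalence"]
    for s in config.strategies:
        sens = draw[f"{s.name}.sensitivity"]
        spec = draw[f"{s.name}.specificity"]
        imaging = draw[f"{s.name}.imaging_cost"]
        p = {
            "TP": prev * sens,
            "FN": prev * (1.0 - sens),
            "TN": (1.0 - prev) * spec,
            "FP": (1.0 - prev) * (1.0 - spec),
        }
        biopsy_tp = (
            draw["costs.biopsy"]
            if config.charge_biopsy_to_test_positives
            else np.zeros(n)
        )
        acute = {
            "TP": imaging + biopsy_tp + draw["costs.timely_treatment"],
            "FN": imaging + draw["costs.delayed_treatment"],
            "TN": imaging + draw["costs.true_negative_acute"],
            "FP": imaging + draw["costs.unnecessary_biopsy"],
        }
        cost = np.zeros(n)
        qaly = np.zeros(n)
        for label in ("TP", "FN", "TN", "FP"):
            bc, bq = branch[label]
            cost += p[label] * (acute[label] + bc)
            qaly += p[label] * bq
        costs[s.name] = cost
        qalys[s.name] = qaly

    keep = [name for name, up in params.items() if up.family != "fixed"]
    return PSASamples(
        seed=seed,
        draws=pd.DataFrame({k: draw[k] for k in keep}),
        costs=costs,
        qalys=qalys,
        wtp=config.wtp,
    )


def ceac(samples: PSASamples, wtp_grid: Sequence[float]) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves over a willingness-to-pay grid.

    For each grid point, the fraction of draws in which each strategy attains
    the highest net monetary benefit; exact ties are split equally, so the
    probabilities sum to one at every grid point.
    """
    grid = np.asarray(list(wtp_grid), dtype=float)
    if grid.size == 0 or np.any(grid < 0.0):
        raise ValueError("WTP grid must be non-empty and non-negative")
    q = np.stack([samples.qalys[s] for s in samples.strategies])  # (k, n)
    c = np.stack([samples.costs[s] for s in samples.strategies])
    out = {"wtp": grid}
    nmb = grid[:, None, None] * q[None] - c[None]  # (g, k, n)
    best = nmb.max(axis=1, keepdims=True)
    is_best = nmb == best
    weights = is_best / is_best.sum(axis=1, keepdims=True)
    prob = weights.mean(axis=2)  # (g, k)
    for i, s in enumerate(samples.strategies):
        out[s] = prob[:, i]
    return pd.DataFrame(out)


def incremental_scatter(
    samples: PSASamples, strategy: str, comparator: str
) -> pd.DataFrame:
    """Per-draw (ΔQALY, Δcost) of ``strategy`` against ``comparator``."""
    for name in (strategy, comparator):
        if name not in samples.strategies:
            raise KeyError(f"strategy {name!r} not present in the PSA samples")
    return pd.DataFrame(
        {
            "delta_effect": samples.qalys[strategy] - samples.qalys[comparator],
            "delta_cost": samples.costs[strategy] - samples.costs[comparator],
        }
    )
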