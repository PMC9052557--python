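"""Pairwise incremental cost-effectiveness analysis and scenario runner."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

from .markov import CohortTrace, LifeTable, run_cohort
from .outcomes import CostBreakdown, OutcomeBreakdown, aggregate
from .parameters import ParameterSet, apply_overrides
from .transitions import strategy_matrices

__all__ = [
    "StrategyResult",
    "CEAResult",
    "compute_icer",
    "net_monetary_benefit",
    "run_strategy",
    "run_comparison",
    "run_scenario",
    "SCENARIOS",
]


@dataclass
class StrategyResult:
    strategy: str
    trace: CohortTrace
    outcomes: OutcomeBreakdown
    costs: CostBreakdown


@dataclass
class CEAResult:
    """Incremental result for intervention (A) vs comparator (B)."""

    intervention: str
    comparator: str
    results: dict[str, StrategyResult]
    delta_qalys: float
    delta_costs: float
    icer: float | None
    dominance: str
    nmb: float
    perspective: str
    horizon: int
    wtp: float

    def summary(self) -> dict[str, Any]:
        a = self.results[self.intervention]
        b = self.results[self.comparator]
        return {
            "intervention": self.intervention,
            "comparator": self.comparator,
            "perspective": self.perspective,
            "horizon": self.horizon,
            "life_years": {
                self.intervention: a.outcomes.life_years,
                self.comparator: b.outcomes.life_years,
            },
            "qalys": {
                self.intervention: a.outcomes.qalys,
                self.comparator: b.outcomes.qalys,
            },
            "total_costs": {
                self.intervention: a.costs.total,
                self.comparator: b.costs.total,
            },
            "delta_qalys": self.delta_qalys,
            "delta_costs": self.delta_costs,
            "icer": self.icer,
            "dominance": self.dominance,
            "nmb": self.nmb,
            "wtp": self.wtp,
        }


def compute_icer(
    delta_cost: float, delta_qaly: float
) -> tuple[float | None, str]:
    """Incremental ratio plus a dominance/quadrant label.

    ``dominant``: no fewer QALYs at no more cost (one strict);
    ``dominated`` is the mirror image.  A zero QALY difference leaves
    the ratio undefined and the label reflects the cost sign alone.
    """
    if delta_qaly == 0.0 and delta_cost == 0.0:
        return None, "equivalent"
    if delta_qaly >= 0.0 and delta_cost <= 0.0:
        label = "dominant"
    elif delta_qaly <= 0.0 and delta_cost >= 0.0:
        label = "dominated"
    elif delta_qaly > 0.0 and delta_cost > 0.0:
        label = "north-east quadrant"
    else:
        label = "south-west quadrant"
    if delta_qaly == 0.0:
        return None, "cost-saving" if delta_cost < 0 else "cost-increasing"
    return delta_cost / delta_qaly, label


def net_monetary_benefit(delta_cost: float, delta_qaly: float, wtp: float) -> float:
    return delta_qaly * wtp - delta_cost


def run_strategy(
    params: ParameterSet,
    strategy: str,
    life_table: LifeTable,
    perspective: str | None = None,
) -> StrategyResult:
    matrices = strategy_matrices(params, strategy)
    trace = run_cohort(strategy, params, matrices, life_table)
    outcome, costs = aggregate(trace, params, strategy, perspective)
    return StrategyResult(strategy=strategy, trace=trace, outcomes=outcome, costs=costs)


def run_comparison(
    params: ParameterSet,
    life_table: LifeTable,
    intervention: str | None = None,
    comparator: str | None = None,
    perspective: str | None = None,
) -> CEAResult:
    """Run both strategies on identical inputs and compare incrementally."""
    intervention = intervention or params.strategies[0]
    comparator = comparator or params.strategies[1]
    perspective = perspective or params.settings.perspective
    results = {
        s: run_strategy(params, s, life_table, perspective)
        for s in (intervention, comparator)
    }
    dq = results[intervention].outcomes.qalys - results[comparator].outcomes.qalys
    dc = results[intervention].costs.total - results[comparator].costs.total
    icer, label = compute_icer(dc, dq)
    return CEAResult(
        intervention=intervention,
        comparator=comparator,
        results=results,
        delta_qalys=dq,
        delta_costs=dc,
        icer=icer,
        dominance=label,
        nmb=net_monetary_benefit(dc, dq, params.settings.wtp),
        perspective=perspective,
        horizon=params.settings.horizon,
        wtp=params.settings.wtp,
    )


#: Named scenarios: setting overrides applied on top of the base case.
SCENARIOS: dict[str, dict[str, Any]] = {
    "base_nhs": {},
    "societal": {"settings.perspective": "societal"},
    "horizon40": {"settings.horizon": 40},
}


def run_scenario(
    params: ParameterSet,
    scenario: str | Mapping[str, Any] = "base_nhs",
    life_table: LifeTable | None = None,
) -> CEAResult:
    """Run a named scenario (or a mapping of dotted-path overrides)."""
    if isinstance(scenario, str):
        try:
            overrides = SCENARIOS[scenario]
        except KeyError:
            raise ValueError(f"unknown scenario: {scenario!r}") from None
    else:
        overrides = dict(scenario)
    if life_table is None:
        from .synthetic import default_life_table

        life_table = default_life_table()
    if overrides:
        params = apply_overrides(params, overrides)
    return run_comparison(params, life_table)
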