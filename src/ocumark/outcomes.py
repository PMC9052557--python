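"""Discounted life-years, QALYs and per-category costs from a cohort trace.

QALYs combine state utilities with the per-injection discomfort rule
(full utility loss for one day in half of patients), temporary
adverse-event disutilities and an optional bilateral-disease decrement.
Costs cover drug acquisition, administration, monitoring, adverse-event
management and vision-loss care; the societal perspective swaps the
direct blindness/low-vision costs for their direct-plus-indirect totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .markov import CohortTrace
from .parameters import (
    AEProfile,
    BLINDNESS_STATE,
    LOW_VISION_STATE,
    ParameterSet,
    UtilityInputs,
)

__all__ = [
    "OutcomeBreakdown",
    "CostBreakdown",
    "discount_factor",
    "annual_injection_disutility",
    "annual_ae_disutility",
    "annual_ae_cost",
    "cycle_qalys",
    "cycle_costs",
    "aggregate",
]

COST_CATEGORIES = (
    "acquisition",
    "administration",
    "monitoring",
    "ae_management",
    "blindness",
    "low_vision",
)


@dataclass
class OutcomeBreakdown:
    life_years: float
    qalys: float
    state_utility: float
    injection_disutility: float
    ae_disutility: float
    bilateral_decrement: float


@dataclass
class CostBreakdown:
    acquisition: float = 0.0
    administration: float = 0.0
    monitoring: float = 0.0
    ae_management: float = 0.0
    blindness: float = 0.0
    low_vision: float = 0.0

    @property
    def total(self) -> float:
        return sum(getattr(self, c) for c in COST_CATEGORIES)

    def as_dict(self) -> dict[str, float]:
        d = {c: getattr(self, c) for c in COST_CATEGORIES}
        d["total"] = self.total
        return d

    def __add__(self, other: "CostBreakdown") -> "CostBreakdown":
        return CostBreakdown(
            **{c: getattr(self, c) + getattr(other, c) for c in COST_CATEGORIES}
        )

    def scaled(self, factor: float) -> "CostBreakdown":
        return CostBreakdown(
            **{c: getattr(self, c) * factor for c in COST_CATEGORIES}
        )


def discount_factor(year: float, rate: float) -> float:
    """Present-value factor (1+rate)^-year for an outcome accruing at ``year``."""
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    if year < 0:
        raise ValueError("year must be >= 0")
    return (1.0 + rate) ** (-year)


def annual_injection_disutility(
    n_injections: float, utilities: UtilityInputs | None = None
) -> float:
    """QALY loss per on-treatment patient-year from injection discomfort."""
    if n_injections < 0:
        raise ValueError("n_injections must be >= 0")
    u = utilities or UtilityInputs(state_utilities=[])
    return (
        n_injections
        * u.injection_affected_fraction
        * u.injection_loss_days
        / u.days_per_year
    )


def annual_ae_disutility(profiles: list[AEProfile], strategy: str) -> float:
    """Expected QALY loss per on-treatment patient-year from adverse events."""
    return sum(
        ae.annual_incidence[strategy] * ae.disutility * ae.expected_duration_years
        for ae in profiles
    )


def annual_ae_cost(profiles: list[AEProfile], strategy: str) -> float:
    """Expected management cost per on-treatment patient-year."""
    return sum(ae.annual_incidence[strategy] * ae.unit_cost for ae in profiles)


def _injections(params: ParameterSet, strategy: str, cycle: int) -> float:
    table = params.costs.injections_per_year[strategy]
    if cycle <= 1:
        return table["year1"]
    if cycle == 2:
        return table["year2"]
    return table["subsequent"]


def cycle_qalys(
    occupancy: np.ndarray,
    on_mass: float,
    bilateral: float,
    params: ParameterSet,
    strategy: str,
    n_injections: float,
) -> dict[str, float]:
    """Undiscounted QALY components for one cycle.

    ``occupancy`` is living mass per VA state (on- plus off-treatment);
    injection and adverse-event decrements apply to on-treatment mass
    only, the bilateral decrement to all living mass.
    """
    u = params.utilities
    util = np.asarray(u.state_utilities, dtype=float)
    alive = float(np.sum(occupancy))
    state_utility = float(occupancy @ util)
    inj = on_mass * annual_injection_disutility(n_injections, u)
    ae = on_mass * annual_ae_disutility(params.adverse_events, strategy)
    bil = alive * bilateral * u.bilateral_decrement
    return {
        "state_utility": state_utility,
        "injection_disutility": inj,
        "ae_disutility": ae,
        "bilateral_decrement": bil,
        "qalys": state_utility - inj - ae - bil,
        "life_years": alive,
    }


def cycle_costs(
    occupancy: np.ndarray,
    on_mass: float,
    bilateral: float,
    params: ParameterSet,
    strategy: str,
    n_injections: float,
    perspective: str,
) -> CostBreakdown:
    """Undiscounted per-category costs for one cycle."""
    if perspective not in ("nhs", "societal"):
        raise ValueError(f"unknown perspective: {perspective!r}")
    c = params.costs
    alive = float(np.sum(occupancy))
    eye_factor = 1.0 + c.second_eye_cost_share * bilateral
    treated = on_mass * n_injections * eye_factor
    if perspective == "societal":
        blind_cost = c.blindness_total_annual
        lv_cost = c.low_vision_total_annual
    else:
        blind_cost = c.blindness_direct_annual
        lv_cost = c.low_vision_direct_annual
    return CostBreakdown(
        acquisition=c.vial_price[strategy] * treated,
        administration=c.administration_cost * treated,
        monitoring=c.monitoring_unit_cost * c.monitoring_per_year * alive,
        ae_management=on_mass * annual_ae_cost(params.adverse_events, strategy),
        blindness=blind_cost * float(occupancy[BLINDNESS_STATE]),
        low_vision=lv_cost * float(occupancy[LOW_VISION_STATE]),
    )


def aggregate(
    trace: CohortTrace,
    params: ParameterSet,
    strategy: str,
    perspective: str | None = None,
) -> tuple[OutcomeBreakdown, CostBreakdown]:
    """Discount and sum per-cycle outcomes and costs over the horizon.

    Cycle ``t`` (t = 1..horizon) accrues from the post-transition
    occupancy at row ``t`` and is discounted at year ``t``.  With the
    half-cycle correction enabled, accrual uses the mean of rows
    ``t-1`` and ``t`` instead.
    """
    s = params.settings
    perspective = perspective or s.perspective
    half = s.half_cycle_correction

    total_costs = CostBreakdown()
    ly = qaly = su = inj = aed = bil = 0.0
    for t in range(1, trace.n_cycles + 1):
        occ = trace.occupancy[t]
        on_mass = float(trace.on[t].sum())
        b = trace.bilateral[t]
        if half:
            occ = 0.5 * (trace.occupancy[t - 1] + occ)
            on_mass = 0.5 * (float(trace.on[t - 1].sum()) + on_mass)
            b = 0.5 * (trace.bilateral[t - 1] + b)
        n_inj = _injections(params, strategy, t)
        q = cycle_qalys(occ, on_mass, b, params, strategy, n_inj)
        cb = cycle_costs(occ, on_mass, b, params, strategy, n_inj, perspective)
        df_out = discount_factor(t, s.discount_rate_outcomes)
        df_cost = discount_factor(t, s.discount_rate_costs)
        ly += q["life_years"] * df_out
        qaly += q["qalys"] * df_out
        su += q["state_utility"] * df_out
        inj += q["injection_disutility"] * df_out
        aed += q["ae_disutility"] * df_out
        bil += q["bilateral_decrement"] * df_out
        total_costs = total_costs + cb.scaled(df_cost)

    outcome = OutcomeBreakdown(
        life_years=ly,
        qalys=qaly,
        state_utility=su,
        injection_disutility=inj,
        ae_disutility=aed,
        bilateral_decrement=bil,
    )
    return outcome, total_costs
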