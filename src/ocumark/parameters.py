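"""Model inputs: typed containers, defaults, validation and config I/O.

Every quantity the model consumes lives in a :class:`ParameterSet`:
treatment efficacy summaries, adverse-event profiles, health-state
utilities, unit costs and run settings.  Defaults reproduce the published
Italian base case for brolucizumab vs aflibercept.  Each uncertain input
additionally carries (distribution family, mean, SE) metadata consumed by
the deterministic and probabilistic sensitivity analyses.
"""

from __future__ import annotations

import copy
import io
from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Any, Iterator, Mapping, Sequence

import yaml

__all__ = [
    "VAState",
    "STRATEGIES",
    "PERIODS",
    "EfficacyInput",
    "AEProfile",
    "UtilityInputs",
    "CostInputs",
    "ModelSettings",
    "BaselineDistribution",
    "ParameterSet",
    "UncertainParameter",
    "default_parameter_set",
    "validate_parameters",
    "load_parameters",
    "serialize_parameters",
    "uncertain_parameters",
    "apply_overrides",
]

STRATEGIES = ("brolucizumab", "aflibercept")
PERIODS = ("year1", "year2plus")

_WEEKS_PER_YEAR = 52.0


class VAState(IntEnum):
    """Six on-treatment visual-acuity bands, best (0) to worst (5).

    Index 5 (<=25 ETDRS letters) is the blindness state.
    """

    VA_86_100 = 0
    VA_71_85 = 1
    VA_56_70 = 2
    VA_41_55 = 3
    VA_26_40 = 4
    VA_LE_25 = 5

    @property
    def label(self) -> str:
        return _STATE_LABELS[self]

    @property
    def is_blindness(self) -> bool:
        return self is VAState.VA_LE_25


_STATE_LABELS = {
    VAState.VA_86_100: "86-100",
    VAState.VA_71_85: "71-85",
    VAState.VA_56_70: "56-70",
    VAState.VA_41_55: "41-55",
    VAState.VA_26_40: "26-40",
    VAState.VA_LE_25: "<=25",
}

N_STATES = len(VAState)

BLINDNESS_STATE = VAState.VA_LE_25
LOW_VISION_STATE = VAState.VA_26_40


@dataclass
class EfficacyInput:
    """Arm-level BCVA-change summary for one strategy and period.

    ``mean``/``sd`` are ETDRS letters over ``observed_weeks`` weeks;
    ``n`` is the number of patients behind the summary.
    """

    strategy: str
    period: str
    mean: float
    sd: float
    n: int
    observed_weeks: int

    @property
    def se_of_mean(self) -> float:
        return self.sd / self.n**0.5


@dataclass
class AEProfile:
    """One serious ocular adverse event: incidence, disutility, cost.

    ``counts``/``arm_sizes`` are the trial observations over
    ``observed_weeks``; ``annual_incidence`` is the linear annualisation
    (proportion x 52/observed_weeks).  ``duration`` is a mixture of
    (weight, years) pairs; ``disutility`` is stored as a positive
    decrement.
    """

    name: str
    counts: dict[str, int]
    arm_sizes: dict[str, int]
    annual_incidence: dict[str, float]
    incidence_se: dict[str, float]
    disutility: float
    duration: tuple[tuple[float, float], ...]
    unit_cost: float
    observed_weeks: int = 96

    @property
    def expected_duration_years(self) -> float:
        return sum(w * d for w, d in self.duration)


@dataclass
class UtilityInputs:
    """Health-state utilities plus the injection-discomfort rule.

    The injection rule: a complete utility loss lasting
    ``injection_loss_days`` days for a fraction
    ``injection_affected_fraction`` of patients, per injection.
    """

    state_utilities: list[float]
    injection_affected_fraction: float = 0.5
    injection_loss_days: float = 1.0
    days_per_year: float = 365.25
    bilateral_decrement: float = 0.0


@dataclass
class CostInputs:
    vial_price: dict[str, float]
    injections_per_year: dict[str, dict[str, float]]
    administration_cost: float = 247.20
    monitoring_unit_cost: float = 36.07
    monitoring_per_year: float = 1.0
    blindness_direct_annual: float = 7856.0
    low_vision_direct_annual: float = 1964.0
    blindness_total_annual: float = 17897.0
    low_vision_total_annual: float = 4474.0
    # Share of second-eye drug/administration cost accrued by bilateral
    # patients: cycle cost factor = 1 + share * bilateral fraction.
    second_eye_cost_share: float = 1.0


@dataclass
class ModelSettings:
    horizon: int = 15
    cycle_years: float = 1.0
    discount_rate_costs: float = 0.03
    discount_rate_outcomes: float = 0.03
    perspective: str = "nhs"
    mean_age: float = 75.8
    pct_female: float = 0.563
    baseline_bilateral: float = 0.2714
    second_eye_annual_prob: float = 0.166
    discontinuation_annual: float = 0.0
    wtp: float = 50_000.0
    seed: int = 20220429
    # Cycle accrual uses the mean of start- and end-of-cycle occupancy.
    # End-of-cycle accounting cannot reproduce the published discounted
    # life-years under any plausible mortality; the half-cycle mean can.
    half_cycle_correction: bool = True
    # relative mortality risk per VA state (index 0 best .. 5 worst)
    mortality_rr: list[float] = field(default_factory=lambda: [1.0] * N_STATES)


@dataclass
class BaselineDistribution:
    """Cycle-0 occupancy fraction per VA state (best to worst)."""

    occupancy: list[float]

    def as_list(self) -> list[float]:
        return list(self.occupancy)


@dataclass
class ParameterSet:
    efficacy: dict[str, dict[str, EfficacyInput]]
    adverse_events: list[AEProfile]
    utilities: UtilityInputs
    costs: CostInputs
    settings: ModelSettings
    baseline: BaselineDistribution
    strategies: tuple[str, ...] = STRATEGIES

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)


# --------------------------------------------------------------------------
# defaults
# --------------------------------------------------------------------------

#: Trial BCVA-change summaries (letters) per strategy and period.
#: Year-1 means cover 52 weeks; Year-2 means cover the 44 weeks 53-96.
_DEFAULT_EFFICACY = {
    "brolucizumab": {
        "year1": dict(mean=6.50, sd=13.35, n=730, observed_weeks=52),
        "year2plus": dict(mean=-0.61, sd=7.18, n=730, observed_weeks=44),
    },
    "aflibercept": {
        "year1": dict(mean=7.12, sd=13.51, n=729, observed_weeks=52),
        "year2plus": dict(mean=-1.05, sd=8.09, n=729, observed_weeks=44),
    },
}

_MONTH_YEARS = 1.0 / 12.0

#: name -> (counts b/a, SEs of annual incidence b/a, disutility,
#:          duration mixture, unit management cost EUR)
_DEFAULT_AES: list[dict[str, Any]] = [
    dict(
        name="cataract",
        counts={"brolucizumab": 2, "aflibercept": 1},
        incidence_se={"brolucizumab": 0.0014, "aflibercept": 0.0010},
        disutility=0.14,
        duration=((1.0, _MONTH_YEARS),),
        unit_cost=994.00,
    ),
    dict(
        name="endophthalmitis",
        counts={"brolucizumab": 4, "aflibercept": 1},
        incidence_se={"brolucizumab": 0.002, "aflibercept": 0.0010},
        disutility=0.30,
        duration=((0.2, 1.0), (0.8, 1.5 * _MONTH_YEARS)),
        unit_cost=1522.00,
    ),
    dict(
        name="intraocular_inflammation",
        counts={"brolucizumab": 6, "aflibercept": 0},
        incidence_se={"brolucizumab": 0.002, "aflibercept": 0.0},
        disutility=0.04,
        duration=((1.0, _MONTH_YEARS),),
        unit_cost=20.66,
    ),
    dict(
        name="retinal_detachment",
        counts={"brolucizumab": 2, "aflibercept": 2},
        incidence_se={"brolucizumab": 0.001, "aflibercept": 0.0014},
        disutility=0.27,
        duration=((1.0, 3 * _MONTH_YEARS),),
        unit_cost=1491.00,
    ),
    dict(
        name="rpe_tear",
        counts={"brolucizumab": 2, "aflibercept": 0},
        incidence_se={"brolucizumab": 0.001, "aflibercept": 0.0},
        disutility=0.0,
        duration=(),
        unit_cost=1491.00,
    ),
    dict(
        name="retinal_tear",
        counts={"brolucizumab": 2, "aflibercept": 1},
        incidence_se={"brolucizumab": 0.001, "aflibercept": 0.0010},
        disutility=0.0,
        duration=(),
        unit_cost=1491.00,
    ),
]

_ARM_SIZES = {"brolucizumab": 730, "aflibercept": 729}

_DEFAULT_UTILITIES = [0.92, 0.82, 0.72, 0.63, 0.53, 0.40]

_DEFAULT_COSTS = dict(
    vial_price={"brolucizumab": 680.00, "aflibercept": 740.00},
    injections_per_year={
        "brolucizumab": {"year1": 6.66, "year2": 4.84, "subsequent": 4.84},
        "aflibercept": {"year1": 7.23, "year2": 5.58, "subsequent": 5.58},
    },
)


def default_parameter_set() -> ParameterSet:
    """Build the base-case :class:`ParameterSet`.

    All values are the published Italian inputs except the baseline VA
    distribution, which is a documented synthetic stand-in (see
    :func:`ocumark.synthetic.default_baseline_distribution`).
    """
    from .synthetic import default_baseline_distribution
    from .transitions import annualize_incidence

    efficacy = {
        strat: {
            per: EfficacyInput(strategy=strat, period=per, **kw)
            for per, kw in by_period.items()
        }
        for strat, by_period in _DEFAULT_EFFICACY.items()
    }
    aes = []
    for spec_ in _DEFAULT_AES:
        counts = spec_["counts"]
        incidence = {
            s: annualize_incidence(counts[s], _ARM_SIZES[s], 96) for s in STRATEGIES
        }
        aes.append(
            AEProfile(
                name=spec_["name"],
                counts=dict(counts),
                arm_sizes=dict(_ARM_SIZES),
                annual_incidence=incidence,
                incidence_se=dict(spec_["incidence_se"]),
                disutility=spec_["disutility"],
                duration=tuple(spec_["duration"]),
                unit_cost=spec_["unit_cost"],
            )
        )
    return ParameterSet(
        efficacy=efficacy,
        adverse_events=aes,
        utilities=UtilityInputs(state_utilities=list(_DEFAULT_UTILITIES)),
        costs=CostInputs(**copy.deepcopy(_DEFAULT_COSTS)),
        settings=ModelSettings(),
        baseline=default_baseline_distribution(),
    )


# --------------------------------------------------------------------------
# validation
# --------------------------------------------------------------------------

def validate_parameters(p: ParameterSet) -> list[str]:
    """Return a list of human-readable invariant violations (empty if valid)."""
    v: list[str] = []
    for strat, by_period in p.efficacy.items():
        for per, eff in by_period.items():
            where = f"efficacy.{strat}.{per}"
            if eff.sd <= 0:
                v.append(f"{where}.sd must be > 0")
            if eff.n <= 0:
                v.append(f"{where}.n must be > 0")
            if eff.observed_weeks not in (52, 44):
                v.append(f"{where}.observed_weeks must be 52 or 44")
    for ae in p.adverse_events:
        where = f"adverse_events.{ae.name}"
        for s, inc in ae.annual_incidence.items():
            if not 0.0 <= inc <= 1.0:
                v.append(f"{where}.annual_incidence.{s} out of [0,1]")
        if ae.duration:
            wsum = sum(w for w, _ in ae.duration)
            if abs(wsum - 1.0) > 1e-9:
                v.append(f"{where}.duration weights do not sum to 1")
        if ae.unit_cost < 0:
            v.append(f"{where}.unit_cost must be >= 0")
        if ae.disutility < 0:
            v.append(f"{where}.disutility must be stored as a positive decrement")
    u = p.utilities.state_utilities
    if len(u) != N_STATES:
        v.append("utilities.state_utilities must have six entries")
    else:
        for i, ui in enumerate(u):
            if not 0.0 <= ui <= 1.0:
                v.append(f"utilities.state_utilities[{i}] out of [0,1]")
        if any(u[i] <= u[i + 1] for i in range(N_STATES - 1)):
            v.append("utilities must strictly decrease with worsening VA state")
    if not 0.0 <= p.utilities.injection_affected_fraction <= 1.0:
        v.append("utilities.injection_affected_fraction out of [0,1]")
    c = p.costs
    for s, price in c.vial_price.items():
        if price < 0:
            v.append(f"costs.vial_price.{s} must be >= 0")
    for s, byper in c.injections_per_year.items():
        for per, ninj in byper.items():
            if ninj < 0:
                v.append(f"costs.injections_per_year.{s}.{per} must be >= 0")
    for name in (
        "administration_cost",
        "monitoring_unit_cost",
        "blindness_direct_annual",
        "low_vision_direct_annual",
        "blindness_total_annual",
        "low_vision_total_annual",
    ):
        if getattr(c, name) < 0:
            v.append(f"costs.{name} must be >= 0")
    s = p.settings
    if s.horizon < 1:
        v.append("settings.horizon must be >= 1")
    if s.discount_rate_costs < 0 or s.discount_rate_outcomes < 0:
        v.append("settings discount rates must be >= 0")
    if s.perspective not in ("nhs", "societal"):
        v.append("settings.perspective must be 'nhs' or 'societal'")
    for name in (
        "pct_female",
        "baseline_bilateral",
        "second_eye_annual_prob",
        "discontinuation_annual",
    ):
        val = getattr(s, name)
        if not 0.0 <= val <= 1.0:
            v.append(f"settings.{name} out of [0,1]")
    if len(s.mortality_rr) != N_STATES:
        v.append("settings.mortality_rr must have six entries")
    elif any(rr <= 0 for rr in s.mortality_rr):
        v.append("settings.mortality_rr entries must be > 0")
    occ = p.baseline.occupancy
    if len(occ) != N_STATES:
        v.append("baseline.occupancy must have six entries")
    else:
        if any(x < 0 for x in occ):
            v.append("baseline.occupancy entries must be >= 0")
        if abs(sum(occ) - 1.0) > 1e-9:
            v.append("baseline.occupancy does not sum to 1")
    return v


# --------------------------------------------------------------------------
# dict / config round-trip
# --------------------------------------------------------------------------

def parameters_to_dict(p: ParameterSet) -> dict[str, Any]:
    """Plain nested-dict representation (YAML/JSON friendly, lossless)."""
    return {
        "efficacy": {
            strat: {
                per: {
                    "mean": eff.mean,
                    "sd": eff.sd,
                    "n": eff.n,
                    "observed_weeks": eff.observed_weeks,
                }
                for per, eff in by_period.items()
            }
            for strat, by_period in p.efficacy.items()
        },
        "adverse_events": {
            ae.name: {
                "counts": dict(ae.counts),
                "arm_sizes": dict(ae.arm_sizes),
                "annual_incidence": dict(ae.annual_incidence),
                "incidence_se": dict(ae.incidence_se),
                "disutility": ae.disutility,
                "duration": [list(pair) for pair in ae.duration],
                "unit_cost": ae.unit_cost,
                "observed_weeks": ae.observed_weeks,
            }
            for ae in p.adverse_events
        },
        "utilities": {
            "state_utilities": list(p.utilities.state_utilities),
            "injection_affected_fraction": p.utilities.injection_affected_fraction,
            "injection_loss_days": p.utilities.injection_loss_days,
            "days_per_year": p.utilities.days_per_year,
            "bilateral_decrement": p.utilities.bilateral_decrement,
        },
        "costs": {
            "vial_price": dict(p.costs.vial_price),
            "injections_per_year": {
                s: dict(d) for s, d in p.costs.injections_per_year.items()
            },
            "administration_cost": p.costs.administration_cost,
            "monitoring_unit_cost": p.costs.monitoring_unit_cost,
            "monitoring_per_year": p.costs.monitoring_per_year,
            "blindness_direct_annual": p.costs.blindness_direct_annual,
            "low_vision_direct_annual": p.costs.low_vision_direct_annual,
            "blindness_total_annual": p.costs.blindness_total_annual,
            "low_vision_total_annual": p.costs.low_vision_total_annual,
            "second_eye_cost_share": p.costs.second_eye_cost_share,
        },
        "settings": {
            "horizon": p.settings.horizon,
            "cycle_years": p.settings.cycle_years,
            "discount_rate_costs": p.settings.discount_rate_costs,
            "discount_rate_outcomes": p.settings.discount_rate_outcomes,
            "perspective": p.settings.perspective,
            "mean_age": p.settings.mean_age,
            "pct_female": p.settings.pct_female,
            "baseline_bilateral": p.settings.baseline_bilateral,
            "second_eye_annual_prob": p.settings.second_eye_annual_prob,
            "discontinuation_annual": p.settings.discontinuation_annual,
            "wtp": p.settings.wtp,
            "seed": p.settings.seed,
            "half_cycle_correction": p.settings.half_cycle_correction,
            "mortality_rr": list(p.settings.mortality_rr),
        },
        "baseline": {"occupancy": list(p.baseline.occupancy)},
    }


def parameters_from_dict(d: Mapping[str, Any]) -> ParameterSet:
    efficacy = {
        strat: {
            per: EfficacyInput(strategy=strat, period=per, **kw)
            for per, kw in by_period.items()
        }
        for strat, by_period in d["efficacy"].items()
    }
    aes = [
        AEProfile(
            name=name,
            counts=dict(ae["counts"]),
            arm_sizes=dict(ae["arm_sizes"]),
            annual_incidence=dict(ae["annual_incidence"]),
            incidence_se=dict(ae["incidence_se"]),
            disutility=ae["disutility"],
            duration=tuple(tuple(pair) for pair in ae["duration"]),
            unit_cost=ae["unit_cost"],
            observed_weeks=ae.get("observed_weeks", 96),
        )
        for name, ae in d["adverse_events"].items()
    ]
    return ParameterSet(
        efficacy=efficacy,
        adverse_events=aes,
        utilities=UtilityInputs(**d["utilities"]),
        costs=CostInputs(**d["costs"]),
        settings=ModelSettings(**d["settings"]),
        baseline=BaselineDistribution(**d["baseline"]),
    )


class ConfigError(ValueError):
    pass


def _merge(base: dict[str, Any], override: Mapping[str, Any], path: str) -> None:
    for key, val in override.items():
        here = f"{path}.{key}" if path else str(key)
        if isinstance(base, dict):
            if key not in base:
                raise ConfigError(f"unknown configuration key: {here}")
            if isinstance(base[key], dict) and isinstance(val, Mapping):
                _merge(base[key], val, here)
            else:
                base[key] = val
        else:  # pragma: no cover - guarded by the dict check above
            raise ConfigError(f"cannot override scalar at {here}")


def load_parameters(config: str | Mapping[str, Any] | None = None) -> ParameterSet:
    """Merge a YAML document (or mapping) of overrides onto the defaults.

    Unknown keys raise :class:`ConfigError`; the merged set must pass
    :func:`validate_parameters`.
    """
    if isinstance(config, str):
        parsed = yaml.safe_load(config)
        if parsed is None:
            parsed = {}
        if not isinstance(parsed, Mapping):
            raise ConfigError("configuration document must be a mapping")
        config = parsed
    base = parameters_to_dict(default_parameter_set())
    if config:
        _merge(base, config, "")
    p = parameters_from_dict(base)
    violations = validate_parameters(p)
    if violations:
        raise ConfigError("invalid parameters: " + "; ".join(violations))
    return p


def serialize_parameters(p: ParameterSet) -> str:
    """YAML rendering of the full resolved parameter set."""
    return yaml.safe_dump(parameters_to_dict(p), sort_keys=True)


def parameters_to_csv(p: ParameterSet) -> str:
    """Flat ``key,value`` CSV export of the resolved set, for audit."""
    rows = ["parameter,value"]

    def walk(prefix: str, node: Any) -> None:
        if isinstance(node, dict):
            for k in node:
                walk(f"{prefix}.{k}" if prefix else str(k), node[k])
        elif isinstance(node, (list, tuple)):
            for i, item in enumerate(node):
                walk(f"{prefix}[{i}]", item)
        else:
            rows.append(f"{prefix},{node}")

    walk("", parameters_to_dict(p))
    return "\n".join(rows) + "\n"


# --------------------------------------------------------------------------
# uncertainty metadata
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class UncertainParameter:
    """One scalar model input with its sampling distribution.

    ``path`` addresses the value inside :func:`parameters_to_dict`;
    ``family`` is ``beta`` / ``gamma`` / ``normal``.  ``se_assumed`` marks
    SEs imputed as 10% of the mean (no reported uncertainty), which the
    one-way DSA treats as a plain +/-10% variation.  ``dsa_pct``, when
    set, forces a +/-pct one-way variation even though the probabilistic
    analysis samples from ``se``.
    """

    path: str
    family: str
    mean: float
    se: float
    lo: float = float("-inf")
    hi: float = float("inf")
    se_assumed: bool = False
    dsa_pct: float | None = None


def _path_parts(path: str) -> list[Any]:
    return [int(p) if p.lstrip("-").isdigit() else p for p in path.split(".")]


def get_by_path(d: Mapping[str, Any], path: str) -> Any:
    node: Any = d
    for part in _path_parts(path):
        node = node[part]
    return node


def set_by_path(d: dict[str, Any], path: str, value: Any) -> None:
    parts = _path_parts(path)
    node: Any = d
    for part in parts[:-1]:
        node = node[part]
    node[parts[-1]] = value


def apply_overrides(p: ParameterSet, values: Mapping[str, float]) -> ParameterSet:
    """Return a new ParameterSet with dotted-path values replaced."""
    d = parameters_to_dict(p)
    for path, value in values.items():
        set_by_path(d, path, value)
    return parameters_from_dict(d)


def uncertain_parameters(p: ParameterSet) -> list[UncertainParameter]:
    """Enumerate every input varied in the sensitivity analyses.

    Families follow the published convention: beta for probabilities and
    incidences, gamma for costs and rates, normal for utilities and
    BCVA-change means.  Where no SE is reported it is imputed as 10% of
    the mean.
    """
    out: list[UncertainParameter] = []

    def add(path, family, mean, se, lo=float("-inf"), hi=float("inf"),
            assumed=False, dsa_pct=None):
        out.append(UncertainParameter(path, family, mean, se, lo, hi,
                                      assumed, dsa_pct))

    for strat, by_period in p.efficacy.items():
        for per, eff in by_period.items():
            # All means are sampled with the trial SE (SD/sqrt(n)).  The
            # Year-2+ means are partial-year extrapolations whose one-way
            # variation is capped at +/-10%, consistent with the
            # published tornado ranges staying in the dominant quadrant.
            add(f"efficacy.{strat}.{per}.mean", "normal", eff.mean,
                eff.se_of_mean,
                dsa_pct=None if per == "year1" else 0.10)
    for ae in p.adverse_events:
        base = f"adverse_events.{ae.name}"
        for s in p.strategies:
            inc = ae.annual_incidence[s]
            se = ae.incidence_se[s]
            if inc > 0:
                add(f"{base}.annual_incidence.{s}", "beta", inc, se, 0.0, 1.0)
        if ae.disutility > 0:
            add(f"{base}.disutility", "normal", ae.disutility,
                0.1 * ae.disutility, 0.0, 1.0, assumed=True)
        add(f"{base}.unit_cost", "gamma", ae.unit_cost,
            0.1 * ae.unit_cost, 0.0, assumed=True)
    for i, u in enumerate(p.utilities.state_utilities):
        add(f"utilities.state_utilities.{i}", "normal", u, 0.1 * u,
            0.0, 1.0, assumed=True)
    add("utilities.injection_affected_fraction", "beta",
        p.utilities.injection_affected_fraction,
        0.1 * p.utilities.injection_affected_fraction, 0.0, 1.0, assumed=True)
    c = p.costs
    for s in p.strategies:
        add(f"costs.vial_price.{s}", "gamma", c.vial_price[s],
            0.1 * c.vial_price[s], 0.0, assumed=True)
        for per in ("year1", "year2", "subsequent"):
            n = c.injections_per_year[s][per]
            add(f"costs.injections_per_year.{s}.{per}", "gamma", n,
                0.1 * n, 0.0, assumed=True)
    for name in (
        "administration_cost",
        "monitoring_unit_cost",
        "blindness_direct_annual",
        "low_vision_direct_annual",
        "blindness_total_annual",
        "low_vision_total_annual",
    ):
        mean = getattr(c, name)
        add(f"costs.{name}", "gamma", mean, 0.1 * mean, 0.0, assumed=True)
    s = p.settings
    add("settings.baseline_bilateral", "beta", s.baseline_bilateral,
        0.1 * s.baseline_bilateral, 0.0, 1.0, assumed=True)
    add("settings.second_eye_annual_prob", "beta", s.second_eye_annual_prob,
        0.1 * s.second_eye_annual_prob, 0.0, 1.0, assumed=True)
    return out
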