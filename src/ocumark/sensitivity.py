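"""Deterministic (tornado) and probabilistic sensitivity analyses.

The one-way DSA moves each uncertain input to the limits of its 95%
confidence interval (or +/-10% where no SE is reported) and re-runs the
full comparison.  The PSA redraws every uncertain input from its
distribution family (beta for probabilities/incidences, gamma for costs
and rates, normal for utilities and efficacy means) and records the
incremental cost/QALY pair per replication.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cea import CEAResult, compute_icer, net_monetary_benefit, run_comparison
from .markov import LifeTable
from .parameters import (
    ParameterSet,
    UncertainParameter,
    apply_overrides,
    uncertain_parameters,
)

__all__ = [
    "DsaEntry",
    "PsaResult",
    "dsa_bounds",
    "one_way_dsa",
    "beta_from_moments",
    "gamma_from_moments",
    "run_psa",
]


@dataclass
class DsaEntry:
    parameter: str
    low_value: float
    high_value: float
    icer_low: float | None
    icer_high: float | None
    nmb_low: float
    nmb_high: float
    dominance_low: str
    dominance_high: str

    @property
    def icer_range(self) -> float:
        if self.icer_low is None or self.icer_high is None:
            return float("nan")
        return abs(self.icer_high - self.icer_low)

    @property
    def nmb_range(self) -> float:
        return abs(self.nmb_high - self.nmb_low)


def dsa_bounds(param: UncertainParameter, z: float = 1.959964) -> tuple[float, float]:
    """Low/high inputs for the one-way analysis.

    Reported SEs give the 95% CI (mean +/- 1.96 SE); imputed SEs fall
    back to a plain +/-10% variation, as do parameters carrying an
    explicit ``dsa_pct``.  Bounds are clipped to the parameter's domain.
    """
    if param.dsa_pct is not None:
        lo = param.mean * (1.0 - param.dsa_pct)
        hi = param.mean * (1.0 + param.dsa_pct)
    elif param.se_assumed or param.se == 0.0:
        lo, hi = param.mean * 0.9, param.mean * 1.1
        if param.se == 0.0 and not param.se_assumed:
            lo = hi = param.mean
    else:
        lo = param.mean - z * param.se
        hi = param.mean + z * param.se
    lo = min(max(lo, param.lo), param.hi)
    hi = min(max(hi, param.lo), param.hi)
    return (lo, hi) if lo <= hi else (hi, lo)


def one_way_dsa(
    params: ParameterSet,
    life_table: LifeTable,
    top: int | None = None,
) -> list[DsaEntry]:
    """Tornado analysis: re-run the comparison at each parameter's bounds.

    Entries come back sorted by descending net-monetary-benefit range
    (the ICER range is also reported; negative ICERs make it an
    unreliable ordering key on their own).
    """
    base = run_comparison(params, life_table)
    entries: list[DsaEntry] = []
    for up in uncertain_parameters(params):
        lo, hi = dsa_bounds(up)
        results = {}
        for tag, value in (("low", lo), ("high", hi)):
            if value == up.mean:
                results[tag] = base
            else:
                perturbed = apply_overrides(params, {up.path: value})
                results[tag] = run_comparison(perturbed, life_table)
        entries.append(
            DsaEntry(
                parameter=up.path,
                low_value=lo,
                high_value=hi,
                icer_low=results["low"].icer,
                icer_high=results["high"].icer,
                nmb_low=results["low"].nmb,
                nmb_high=results["high"].nmb,
                dominance_low=results["low"].dominance,
                dominance_high=results["high"].dominance,
            )
        )
    entries.sort(key=lambda e: e.nmb_range, reverse=True)
    if top is not None:
        entries = entries[:top]
    return entries


def dsa_to_dataframe(entries: Sequence[DsaEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": [e.parameter for e in entries],
            "low_value": [e.low_value for e in entries],
            "high_value": [e.high_value for e in entries],
            "icer_low": [e.icer_low for e in entries],
            "icer_high": [e.icer_high for e in entries],
            "icer_range": [e.icer_range for e in entries],
            "nmb_low": [e.nmb_low for e in entries],
            "nmb_high": [e.nmb_high for e in entries],
            "nmb_range": [e.nmb_range for e in entries],
            "dominance_low": [e.dominance_low for e in entries],
            "dominance_high": [e.dominance_high for e in entries],
        }
    )


# --------------------------------------------------------------------------
# distribution fitting (method of moments)
# --------------------------------------------------------------------------

def beta_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Beta(alpha, beta) shape parameters matching (mean, se)."""
    if not 0.0 < mean < 1.0:
        raise ValueError("beta mean must lie strictly in (0,1)")
    if se < 0:
        raise ValueError("se must be >= 0")
    if se == 0.0:
        return float("inf"), float("inf")  # degenerate point mass
    var = se * se
    if var >= mean * (1.0 - mean):
        raise ValueError("infeasible beta moments: se^2 >= mean(1-mean)")
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def gamma_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Gamma (shape, scale) matching (mean, se)."""
    if mean <= 0:
        raise ValueError("gamma mean must be > 0")
    if se < 0:
        raise ValueError("se must be >= 0")
    if se == 0.0:
        return float("inf"), 0.0  # degenerate point mass
    shape = (mean / se) ** 2
    scale = se * se / mean
    return shape, scale


def _draw(up: UncertainParameter, rng: np.random.Generator) -> float:
    if up.se == 0.0:
        return up.mean
    if up.family == "beta":
        a, b = beta_from_moments(up.mean, up.se)
        return float(rng.beta(a, b))
    if up.family == "gamma":
        shape, scale = gamma_from_moments(up.mean, up.se)
        return float(rng.gamma(shape, scale))
    if up.family == "normal":
        # truncate to the domain by resampling
        for _ in range(1000):
            x = float(rng.normal(up.mean, up.se))
            if up.lo <= x <= up.hi:
                return x
        raise RuntimeError(f"truncated-normal resampling failed for {up.path}")
    raise ValueError(f"unknown distribution family: {up.family!r}")


@dataclass
class PsaResult:
    samples: pd.DataFrame
    summary: dict
    ceac: pd.DataFrame
    seed: int
    wtp: float


DEFAULT_WTP_GRID = tuple(range(0, 105_000, 5_000))


def run_psa(
    params: ParameterSet,
    life_table: LifeTable,
    n_reps: int = 1000,
    seed: int = 0,
    wtp: float | None = None,
    wtp_grid: Sequence[float] = DEFAULT_WTP_GRID,
) -> PsaResult:
    """Probabilistic sensitivity analysis with independent parameter draws.

    One master seed spawns a substream per replication, so individual
    replications are reproducible regardless of evaluation order.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    wtp = params.settings.wtp if wtp is None else wtp
    ups = uncertain_parameters(params)
    streams = np.random.SeedSequence(seed).spawn(n_reps)
    rows = []
    for rep, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        values = {up.path: _draw(up, rng) for up in ups}
        drawn = apply_overrides(params, values)
        res = run_comparison(drawn, life_table)
        rows.append(
            {
                "replication": rep,
                "delta_qalys": res.delta_qalys,
                "delta_costs": res.delta_costs,
                "dominance": res.dominance,
                "nmb": net_monetary_benefit(res.delta_costs, res.delta_qalys, wtp),
            }
        )
    samples = pd.DataFrame(rows)
    dominant = (samples["delta_qalys"] >= 0) & (samples["delta_costs"] <= 0)
    cost_effective = ~dominant & (samples["nmb"] > 0)
    summary = {
        "n_reps": n_reps,
        "seed": seed,
        "wtp": wtp,
        "mean_delta_qalys": float(samples["delta_qalys"].mean()),
        "mean_delta_costs": float(samples["delta_costs"].mean()),
        "se_delta_qalys": float(samples["delta_qalys"].std(ddof=1) / np.sqrt(n_reps)),
        "se_delta_costs": float(samples["delta_costs"].std(ddof=1) / np.sqrt(n_reps)),
        "fraction_dominant": float(dominant.mean()),
        "fraction_cost_effective": float(cost_effective.mean()),
        "fraction_not_cost_effective": float((~dominant & ~cost_effective).mean()),
    }
    ceac_rows = []
    for w in wtp_grid:
        nmb_w = samples["delta_qalys"] * w - samples["delta_costs"]
        ceac_rows.append({"wtp": w, "p_cost_effective": float((nmb_w > 0).mean())})
    ceac = pd.DataFrame(ceac_rows)
    return PsaResult(samples=samples, summary=summary, ceac=ceac, seed=seed, wtp=wtp)
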