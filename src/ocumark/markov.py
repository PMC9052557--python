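"""Annual-cycle cohort simulation.

Each cycle: (1) age/sex mortality, optionally adjusted per VA state on
the hazard scale, removes mass from every living compartment; (2)
surviving on-treatment mass moves between VA states by the period's
transition matrix; (3) a discontinuation fraction (base case 0) moves to
off-treatment, where the VA state is frozen; (4) the bilateral-disease
fraction among the living accrues; (5) the cohort ages one year.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import N_STATES, ParameterSet, VAState
from .transitions import TransitionMatrix

__all__ = [
    "LifeTable",
    "MortalityAdjustment",
    "CohortTrace",
    "adjusted_death_probability",
    "cohort_death_probability",
    "update_bilateral_fraction",
    "run_cohort",
]

SEXES = ("female", "male")


@dataclass
class LifeTable:
    """Annual death probability q(age) per sex, ages ``min_age``..terminal.

    The terminal age has q = 1.  Fractional ages are linearly
    interpolated between the bracketing integer ages.
    """

    qx: dict[str, np.ndarray]
    min_age: int = 0

    def __post_init__(self) -> None:
        self.qx = {sex: np.asarray(q, dtype=float) for sex, q in self.qx.items()}

    @property
    def max_age(self) -> int:
        n = min(len(q) for q in self.qx.values())
        return self.min_age + n - 1

    def validate(self) -> None:
        for sex, q in self.qx.items():
            if np.any(q < 0) or np.any(q > 1):
                raise ValueError(f"{sex}: death probabilities must lie in [0,1]")
            if q[-1] != 1.0:
                raise ValueError(f"{sex}: terminal death probability must be 1")
            adult = q[max(0, 30 - self.min_age):]
            if np.any(np.diff(adult) < -1e-12):
                raise ValueError(f"{sex}: q must be weakly increasing beyond age 30")

    def q(self, age: float, sex: str) -> float:
        """Interpolated annual death probability at a (fractional) age."""
        q = self.qx[sex]
        if age < self.min_age or age > self.min_age + len(q) - 1:
            raise ValueError(f"age {age} outside life-table range")
        pos = age - self.min_age
        lo = int(np.floor(pos))
        hi = min(lo + 1, len(q) - 1)
        frac = pos - lo
        return float(q[lo] * (1 - frac) + q[hi] * frac)

    def to_csv(self) -> str:
        buf = io.StringIO()
        buf.write("age,sex,qx\n")
        for sex in sorted(self.qx):
            for i, q in enumerate(self.qx[sex]):
                buf.write(f"{self.min_age + i},{sex},{q:.10g}\n")
        return buf.getvalue()

    @classmethod
    def from_csv(cls, text: str) -> "LifeTable":
        df = pd.read_csv(io.StringIO(text))
        qx = {}
        min_age = int(df["age"].min())
        for sex, grp in df.groupby("sex"):
            grp = grp.sort_values("age")
            if int(grp["age"].min()) != min_age:
                raise ValueError("sexes must cover the same age range")
            if np.any(np.diff(grp["age"].to_numpy()) != 1):
                raise ValueError("ages must be consecutive integers")
            qx[str(sex)] = grp["qx"].to_numpy(dtype=float)
        lt = cls(qx=qx, min_age=min_age)
        lt.validate()
        return lt


@dataclass
class MortalityAdjustment:
    """Relative mortality risk per VA state (hazard-scale multipliers)."""

    rr: np.ndarray = field(default_factory=lambda: np.ones(N_STATES))

    def __post_init__(self) -> None:
        self.rr = np.asarray(self.rr, dtype=float)
        if self.rr.shape != (N_STATES,):
            raise ValueError("need one relative risk per VA state")
        if np.any(self.rr <= 0):
            raise ValueError("relative risks must be > 0")


def adjusted_death_probability(base_prob: float, rr: float) -> float:
    """Apply a relative risk on the hazard scale: 1 - (1-q)^rr."""
    if not 0.0 <= base_prob <= 1.0:
        raise ValueError("base_prob must lie in [0,1]")
    if rr <= 0:
        raise ValueError("rr must be > 0")
    return 1.0 - (1.0 - base_prob) ** rr


def cohort_death_probability(age: float, pct_female: float, life_table: LifeTable) -> float:
    """Female-share-weighted death probability at the cohort's mean age."""
    if not 0.0 <= pct_female <= 1.0:
        raise ValueError("pct_female must lie in [0,1]")
    qf = life_table.q(age, "female")
    qm = life_table.q(age, "male")
    return pct_female * qf + (1.0 - pct_female) * qm


def update_bilateral_fraction(b_t: float, annual_second_eye_prob: float) -> float:
    """One-step accrual of bilateral disease among surviving unilaterals."""
    if not 0.0 <= b_t <= 1.0 or not 0.0 <= annual_second_eye_prob <= 1.0:
        raise ValueError("inputs must lie in [0,1]")
    return b_t + (1.0 - b_t) * annual_second_eye_prob


@dataclass
class CohortTrace:
    """Per-cycle compartment occupancy for one strategy.

    Arrays are indexed ``[cycle, state]`` (cycle 0 = baseline);
    ``on`` + ``off`` + ``dead`` sums to 1 every cycle.
    """

    strategy: str
    on: np.ndarray
    off: np.ndarray
    dead: np.ndarray
    bilateral: np.ndarray
    age: np.ndarray

    @property
    def n_cycles(self) -> int:
        return len(self.dead) - 1

    @property
    def alive(self) -> np.ndarray:
        return self.on.sum(axis=1) + self.off.sum(axis=1)

    @property
    def occupancy(self) -> np.ndarray:
        """Living occupancy per VA state (on- plus off-treatment)."""
        return self.on + self.off

    def validate(self, atol: float = 1e-10) -> None:
        total = self.on.sum(axis=1) + self.off.sum(axis=1) + self.dead
        if np.max(np.abs(total - 1.0)) > atol:
            raise ValueError("compartments must sum to 1 every cycle")
        if np.any(self.on < -atol) or np.any(self.off < -atol):
            raise ValueError("occupancies must be >= 0")
        if np.any(np.diff(self.dead) < -atol):
            raise ValueError("dead fraction must be non-decreasing")

    def to_dataframe(self) -> pd.DataFrame:
        cols = {f"on_{s.label}": self.on[:, s] for s in VAState}
        cols.update({f"off_{s.label}": self.off[:, s] for s in VAState})
        cols["dead"] = self.dead
        cols["alive"] = self.alive
        cols["bilateral"] = self.bilateral
        cols["age"] = self.age
        df = pd.DataFrame(cols)
        df.insert(0, "cycle", np.arange(len(self.dead)))
        return df

    def to_csv(self) -> str:
        return self.to_dataframe().to_csv(index=False)


def run_cohort(
    strategy: str,
    params: ParameterSet,
    matrices: dict[str, TransitionMatrix],
    life_table: LifeTable,
    mort_adj: MortalityAdjustment | None = None,
) -> CohortTrace:
    """Simulate the cohort over ``settings.horizon`` annual cycles.

    ``matrices`` maps ``year1`` / ``year2plus`` to transition matrices.
    """
    s = params.settings
    if mort_adj is None:
        mort_adj = MortalityAdjustment(rr=np.asarray(s.mortality_rr))
    horizon = s.horizon
    if s.mean_age + horizon > life_table.max_age:
        raise ValueError("horizon exceeds the life-table age range")

    n = horizon + 1
    on = np.zeros((n, N_STATES))
    off = np.zeros((n, N_STATES))
    dead = np.zeros(n)
    bilateral = np.zeros(n)
    age = np.zeros(n)

    on[0] = np.asarray(params.baseline.occupancy, dtype=float)
    bilateral[0] = s.baseline_bilateral
    age[0] = s.mean_age

    for t in range(1, n):
        q_base = cohort_death_probability(age[t - 1], s.pct_female, life_table)
        q_state = np.array(
            [adjusted_death_probability(q_base, rr) for rr in mort_adj.rr]
        )
        surv_on = on[t - 1] * (1.0 - q_state)
        surv_off = off[t - 1] * (1.0 - q_state)
        dead[t] = dead[t - 1] + float(
            np.sum(on[t - 1] * q_state) + np.sum(off[t - 1] * q_state)
        )
        period = "year1" if t == 1 else "year2plus"
        moved = surv_on @ matrices[period].matrix
        leave = s.discontinuation_annual
        on[t] = moved * (1.0 - leave)
        off[t] = surv_off + moved * leave
        bilateral[t] = update_bilateral_fraction(
            bilateral[t - 1], s.second_eye_annual_prob
        )
        age[t] = age[t - 1] + s.cycle_years

    trace = CohortTrace(
        strategy=strategy, on=on, off=off, dead=dead, bilateral=bilateral, age=age
    )
    trace.validate()
    return trace
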