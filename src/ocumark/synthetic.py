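"""Synthetic stand-ins for inputs not available as machine-readable data.

Three generators keep the whole model testable offline:

* a Gompertz-Makeham life table emulating Italian (2018) all-cause
  mortality, as a stand-in for the official national tables;
* a baseline visual-acuity distribution over the six ETDRS bands
  (the trial distribution is published only as a figure);
* individual-level BCVA letter-change draws, the brute-force oracle for
  the parametric normal-CDF transition estimator.

WARNING: :data:`STANDIN_BASELINE_OCCUPANCY` and
:data:`ITALY_2018_LIKE` are documented approximations.  Exact
reproduction of the published tables requires the trial figure values
and the official life table, both loadable through the ordinary
parameter/``LifeTable.from_csv`` paths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .markov import LifeTable
from .parameters import BaselineDistribution, N_STATES, VAState
from .transitions import (
    DEFAULT_CUTOFFS,
    LetterCutoffs,
    TransitionMatrix,
)

__all__ = [
    "GompertzMakehamParams",
    "SimulatedCohort",
    "ITALY_2018_LIKE",
    "STANDIN_BASELINE_OCCUPANCY",
    "generate_life_table",
    "default_life_table",
    "default_baseline_distribution",
    "simulate_individual_changes",
    "empirical_band_probabilities",
    "empirical_transition_matrix",
]


@dataclass(frozen=True)
class GompertzMakehamParams:
    """Hazard h(a) = makeham + scale * shape**age, per sex."""

    makeham: float
    scale: float
    shape: float
    sex: str = ""

    def __post_init__(self) -> None:
        if self.makeham < 0 or self.scale <= 0 or self.shape <= 1:
            raise ValueError(
                "need makeham >= 0, scale > 0, shape > 1 for a valid hazard"
            )

    def hazard(self, age: np.ndarray | float) -> np.ndarray | float:
        return self.makeham + self.scale * self.shape ** np.asarray(age, dtype=float)


#: Sex-specific parameters tuned so that remaining life expectancy at age
#: 75.8 matches the ~12.9 y (women) / ~10.8 y (men) observed for Italy
#: in 2018.
ITALY_2018_LIKE = {
    "female": GompertzMakehamParams(
        makeham=2.0e-4, scale=1.134e-7, shape=1.170, sex="female"
    ),
    "male": GompertzMakehamParams(
        makeham=3.0e-4, scale=1.736e-7, shape=1.170, sex="male"
    ),
}


def generate_life_table(
    params: dict[str, GompertzMakehamParams] | None = None, max_age: int = 120
) -> LifeTable:
    """Integer-age life table q(a) = 1 - exp(-h(a)), terminal q = 1."""
    params = params or ITALY_2018_LIKE
    ages = np.arange(max_age + 1)
    qx = {}
    for sex, gm in params.items():
        q = 1.0 - np.exp(-np.asarray(gm.hazard(ages)))
        q[-1] = 1.0
        qx[sex] = q
    lt = LifeTable(qx=qx, min_age=0)
    lt.validate()
    return lt


def default_life_table() -> LifeTable:
    return generate_life_table(ITALY_2018_LIKE)


#: Stand-in baseline occupancy per VA band (best to worst): a
#: Normal(60.6, 13.2) letter score discretized at the band boundaries,
#: matching the letter range typical of nAMD trial entry criteria.
STANDIN_BASELINE_OCCUPANCY = (0.0296, 0.1970, 0.4238, 0.2857, 0.0600, 0.0039)


def default_baseline_distribution() -> BaselineDistribution:
    """Documented stand-in for the unpublished trial baseline distribution."""
    return BaselineDistribution(occupancy=list(STANDIN_BASELINE_OCCUPANCY))


# --------------------------------------------------------------------------
# individual-level oracle for the parametric transition estimator
# --------------------------------------------------------------------------

_BAND_UPPER = (100.0, 85.0, 70.0, 55.0, 40.0, 25.0)
_BAND_LOWER = (86.0, 71.0, 56.0, 41.0, 26.0, 0.0)


@dataclass
class SimulatedCohort:
    """Individual baseline states/letters plus one cycle of letter changes."""

    baseline_state: np.ndarray
    baseline_letters: np.ndarray
    changes: np.ndarray
    seed: int


def simulate_individual_changes(
    n: int,
    mean: float,
    sd: float,
    seed: int,
    baseline: BaselineDistribution | None = None,
) -> SimulatedCohort:
    """Draw ``n`` letter changes from Normal(mean, sd) for a simulated cohort.

    Baseline states are sampled from ``baseline`` (uniform across the six
    bands by default, so every matrix row is populated); a continuous
    letter score is drawn uniformly inside each individual's band.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if sd <= 0:
        raise ValueError("sd must be > 0")
    rng = np.random.default_rng(seed)
    if baseline is None:
        probs = np.full(N_STATES, 1.0 / N_STATES)
    else:
        probs = np.asarray(baseline.occupancy, dtype=float)
        probs = probs / probs.sum()
    states = rng.choice(N_STATES, size=n, p=probs)
    lo = np.asarray(_BAND_LOWER)[states]
    hi = np.asarray(_BAND_UPPER)[states]
    letters = rng.uniform(lo, hi)
    changes = rng.normal(mean, sd, size=n)
    return SimulatedCohort(
        baseline_state=states, baseline_letters=letters, changes=changes, seed=seed
    )


def _moves_from_changes(
    changes: np.ndarray, cutoffs: LetterCutoffs
) -> np.ndarray:
    """State-index shift per individual (-2 = gain two bands ... +2)."""
    c1, c2 = cutoffs.one_state, cutoffs.two_state
    moves = np.zeros(len(changes), dtype=int)
    moves[changes >= c2] = -2
    moves[(changes >= c1) & (changes < c2)] = -1
    moves[(changes <= -c1) & (changes > -c2)] = 1
    moves[changes <= -c2] = 2
    return moves


def empirical_band_probabilities(
    changes: np.ndarray, cutoffs: LetterCutoffs = DEFAULT_CUTOFFS
) -> np.ndarray:
    """Empirical frequencies of (gain2, gain1, stay, lose1, lose2)."""
    moves = _moves_from_changes(np.asarray(changes, dtype=float), cutoffs)
    return np.array([np.mean(moves == m) for m in (-2, -1, 0, 1, 2)])


def empirical_transition_matrix(
    cohort: SimulatedCohort, cutoffs: LetterCutoffs = DEFAULT_CUTOFFS
) -> TransitionMatrix:
    """Empirical state-to-state frequencies from simulated letter changes.

    Moves are capped at two bands and clipped at the boundary states,
    mirroring the parametric construction.  Unvisited start states keep
    an identity row.
    """
    moves = _moves_from_changes(cohort.changes, cutoffs)
    dest = np.clip(cohort.baseline_state + moves, 0, N_STATES - 1)
    counts = np.zeros((N_STATES, N_STATES))
    np.add.at(counts, (cohort.baseline_state, dest), 1.0)
    m = np.zeros_like(counts)
    for i in range(N_STATES):
        row_n = counts[i].sum()
        if row_n > 0:
            m[i] = counts[i] / row_n
        else:
            m[i, i] = 1.0
    return TransitionMatrix(matrix=m, strategy="empirical", period="")
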