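"""Annual transition matrices from BCVA-change summaries.

Letter changes over a cycle are modelled as Normal(mean, sd); the normal
CDF evaluated at the +/-7.5 and +/-22.5 letter cut-offs yields the
probabilities of moving up or down one or two visual-acuity bands (moves
beyond two bands are not allowed).  Band probabilities are laid onto a
6x6 row-stochastic matrix, with mass that would overshoot the best/worst
band accumulating at the boundary.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .parameters import N_STATES, ParameterSet, VAState

__all__ = [
    "LetterCutoffs",
    "BandProbabilities",
    "TransitionMatrix",
    "scale_partial_year_change",
    "band_probabilities",
    "build_transition_matrix",
    "annualize_incidence",
    "strategy_matrices",
]

WEEKS_PER_YEAR = 52.0


@dataclass(frozen=True)
class LetterCutoffs:
    """ETDRS-letter thresholds for one- and two-band moves."""

    one_state: float = 7.5
    two_state: float = 22.5

    def __post_init__(self) -> None:
        if not 0 < self.one_state < self.two_state:
            raise ValueError("cutoffs must satisfy 0 < one_state < two_state")


DEFAULT_CUTOFFS = LetterCutoffs()


@dataclass(frozen=True)
class BandProbabilities:
    """Probabilities of the five permitted moves over one cycle."""

    p_gain2: float
    p_gain1: float
    p_stay: float
    p_lose1: float
    p_lose2: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.p_gain2, self.p_gain1, self.p_stay, self.p_lose1, self.p_lose2]
        )

    def validate(self) -> None:
        arr = self.as_array()
        if np.any(arr < -1e-15) or np.any(arr > 1 + 1e-15):
            raise ValueError("band probabilities must lie in [0,1]")
        if abs(arr.sum() - 1.0) > 1e-12:
            raise ValueError("band probabilities must sum to 1")


@dataclass
class TransitionMatrix:
    """Row-stochastic 6x6 matrix over VA states for one strategy/period."""

    matrix: np.ndarray
    strategy: str = ""
    period: str = ""

    def validate(self, atol: float = 1e-12) -> None:
        m = self.matrix
        if m.shape != (N_STATES, N_STATES):
            raise ValueError("transition matrix must be 6x6")
        if np.any(m < -atol):
            raise ValueError("transition probabilities must be >= 0")
        if np.max(np.abs(m.sum(axis=1) - 1.0)) > atol:
            raise ValueError("transition matrix rows must sum to 1")
        for i in range(N_STATES):
            for j in range(N_STATES):
                if abs(i - j) > 2 and m[i, j] != 0.0:
                    raise ValueError("moves beyond two states are not allowed")

    def to_csv(self) -> str:
        labels = [s.label for s in VAState]
        buf = io.StringIO()
        buf.write("from\\to," + ",".join(labels) + "\n")
        for i, row in enumerate(self.matrix):
            buf.write(labels[i] + "," + ",".join(f"{x:.12g}" for x in row) + "\n")
        return buf.getvalue()


def scale_partial_year_change(
    mean_change: float, observed_weeks: float, target_weeks: float = WEEKS_PER_YEAR
) -> float:
    """Linearly extrapolate a mean letter change to ``target_weeks``.

    A change observed over a partial year is assumed to continue at the
    same weekly rate for the remainder of the year.
    """
    if observed_weeks <= 0 or target_weeks <= 0:
        raise ValueError("week counts must be positive")
    return mean_change * target_weeks / observed_weeks


def band_probabilities(
    mean: float, sd: float, cutoffs: LetterCutoffs = DEFAULT_CUTOFFS
) -> BandProbabilities:
    """Discretize Normal(mean, sd) letter change into the five move bands."""
    if sd <= 0:
        raise ValueError("sd must be > 0")
    c1, c2 = cutoffs.one_state, cutoffs.two_state
    cdf = norm(loc=mean, scale=sd).cdf
    bands = BandProbabilities(
        p_gain2=1.0 - cdf(c2),
        p_gain1=cdf(c2) - cdf(c1),
        p_stay=cdf(c1) - cdf(-c1),
        p_lose1=cdf(-c1) - cdf(-c2),
        p_lose2=cdf(-c2),
    )
    bands.validate()
    return bands


def build_transition_matrix(
    bands: BandProbabilities, strategy: str = "", period: str = ""
) -> TransitionMatrix:
    """Lay band probabilities onto the 6x6 state matrix.

    Gaining moves toward index 0 (best vision).  Mass that would land
    outside the state space accumulates in the boundary state.
    """
    bands.validate()
    probs = bands.as_array()
    moves = (-2, -1, 0, 1, 2)  # index shifts: gain 2 ... lose 2
    m = np.zeros((N_STATES, N_STATES))
    for i in range(N_STATES):
        for move, prob in zip(moves, probs):
            j = min(max(i + move, 0), N_STATES - 1)
            m[i, j] += prob
    tm = TransitionMatrix(matrix=m, strategy=strategy, period=period)
    tm.validate()
    return tm


def annualize_incidence(
    count: int, n_patients: int, observed_weeks: float = 96.0
) -> float:
    """Convert an event proportion over ``observed_weeks`` to a per-year one."""
    if n_patients <= 0:
        raise ValueError("n_patients must be > 0")
    if not 0 <= count <= n_patients:
        raise ValueError("count must lie in [0, n_patients]")
    if observed_weeks <= 0:
        raise ValueError("observed_weeks must be > 0")
    return (count / n_patients) * WEEKS_PER_YEAR / observed_weeks


def strategy_matrices(
    params: ParameterSet,
    strategy: str,
    cutoffs: LetterCutoffs = DEFAULT_CUTOFFS,
    scale_sd: bool = False,
) -> dict[str, TransitionMatrix]:
    """Year-1 and Year-2+ matrices for one strategy.

    The Year-2 mean (observed over 44 weeks) is extrapolated to a full
    52-week year; the SD is kept at its reported value unless
    ``scale_sd`` requests a sqrt-of-time adjustment.
    """
    out: dict[str, TransitionMatrix] = {}
    for period, eff in params.efficacy[strategy].items():
        mean = scale_partial_year_change(eff.mean, eff.observed_weeks)
        sd = eff.sd
        if scale_sd and eff.observed_weeks != WEEKS_PER_YEAR:
            sd = sd * (WEEKS_PER_YEAR / eff.observed_weeks) ** 0.5
        bands = band_probabilities(mean, sd, cutoffs)
        out[period] = build_transition_matrix(bands, strategy=strategy, period=period)
    return out
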