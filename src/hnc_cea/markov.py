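"""Discrete-time Markov cohort engine with discounted cost/QALY accrual.

The cohort model tracks the fraction of a treated cohort occupying each
health state across fixed-length cycles.  The default clinical structure
has six states built from radiotherapy toxicity — composite
xerostomia × dysphagia severities (LXLD, LXHD, HXLD, HXHD) — plus a
lost-to-follow-up (LTF) state and an absorbing Death state.  Patients
lost to follow-up are assumed to die at the same per-cycle rate as the
rest of the cohort; this is enforced as a validation rule on every
transition matrix.

Rewards: each alive state carries a utility weight (per year of
occupancy) and a cost per cycle.  By default rewards accrue from cycle 1
using end-of-cycle occupancy; a half-cycle correction (averaging
adjacent occupancy rows) can be enabled, and a start-of-cycle convention
is available for oracle comparisons.  Discounting is annual, converted
to the cycle length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigurationError,
    InvalidInputError,
    MatrixValidationError,
    ModelError,
)

DEATH = "Death"
ATOL = 1e-9


@dataclass(frozen=True)
class HealthState:
    name: str
    absorbing: bool = False
    lost_to_follow_up: bool = False


#: Composite toxicity reading of the six-state structure.
DEFAULT_STATE_NAMES: tuple[str, ...] = ("LXLD", "LXHD", "HXLD", "HXHD", "LTF", "Death")


def default_states() -> tuple[HealthState, ...]:
    return tuple(
        HealthState(
            name=n,
            absorbing=(n == DEATH),
            lost_to_follow_up=(n == "LTF"),
        )
        for n in DEFAULT_STATE_NAMES
    )


@dataclass
class ModelSpec:
    """Markov structure and run controls shared by all strategies."""

    states: Sequence[HealthState]
    cycle_length_years: float = 0.25
    n_cycles: int = 20
    discount_rate_annual: float = 0.03
    half_cycle_correction: bool = False
    initial_distribution: Sequence[float] | None = None
    #: Per-cycle death probability every alive state (incl. LTF) must share;
    #: if None it is inferred from the non-LTF alive rows at validation time.
    cohort_death_prob: float | None = None

    def __post_init__(self) -> None:
        self.states = tuple(self.states)
        deaths = [s for s in self.states if s.name == DEATH]
        if len(deaths) != 1 or not deaths[0].absorbing:
            raise ConfigurationError("exactly one absorbing state named 'Death' is required")
        if sum(s.lost_to_follow_up for s in self.states) > 1:
            raise ConfigurationError("at most one lost-to-follow-up state is allowed")
        if len({s.name for s in self.states}) != len(self.states):
            raise ConfigurationError("state names must be unique")
        if self.cycle_length_years <= 0:
            raise InvalidInputError("cycle_length_years must be positive")
        if self.n_cycles < 1:
            raise InvalidInputError("n_cycles must be >= 1")
        if self.discount_rate_annual < 0:
            raise InvalidInputError("discount_rate_annual must be >= 0")
        if self.initial_distribution is None:
            init = np.zeros(len(self.states))
            init[0] = 1.0
        else:
            init = np.asarray(self.initial_distribution, dtype=float)
        if init.shape != (len(self.states),) or (init < 0).any():
            raise InvalidInputError("initial_distribution must be a non-negative vector over states")
        if abs(init.sum() - 1.0) > ATOL:
            raise InvalidInputError(
                f"initial_distribution must sum to 1, got {init.sum()!r}"
            )
        self.initial_distribution = init

    @property
    def state_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.states)

    @property
    def horizon_years(self) -> float:
        return self.n_cycles * self.cycle_length_years

    def index(self, name: str) -> int:
        try:
            return self.state_names.index(name)
        except ValueError:
            raise InvalidInputError(f"unknown state {name!r}") from None

    @property
    def death_index(self) -> int:
        return self.index(DEATH)

    @property
    def ltf_index(self) -> int | None:
        for i, s in enumerate(self.states):
            if s.lost_to_follow_up:
                return i
        return None


@dataclass
class TransitionMatrix:
    """Row-stochastic per-cycle transition matrix for one strategy."""

    strategy: str
    entries: np.ndarray

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        if self.entries.ndim != 2 or self.entries.shape[0] != self.entries.shape[1]:
            raise InvalidInputError("transition matrix must be square")


def validate_matrix(
    m: TransitionMatrix,
    spec: ModelSpec,
    cohort_death_prob: float | None = None,
    atol: float = ATOL,
) -> TransitionMatrix:
    """Check row-stochasticity, the absorbing Death row, and the LTF rule.

    The lost-to-follow-up state must transition to Death with exactly the
    cohort per-cycle death probability (given explicitly, configured on
    the spec, or inferred from the other alive rows, which must then
    agree among themselves).
    """
    P = m.entries
    n = len(spec.states)
    if P.shape != (n, n):
        raise MatrixValidationError(
            f"matrix shape {P.shape} does not match {n} states"
        )
    if (P < 0).any():
        i, j = map(int, np.argwhere(P < 0)[0])
        raise MatrixValidationError(
            f"negative entry at ({spec.state_names[i]!r} -> {spec.state_names[j]!r})"
        )
    sums = P.sum(axis=1)
    bad = np.where(np.abs(sums - 1.0) > atol)[0]
    if bad.size:
        i = int(bad[0])
        raise MatrixValidationError(
            f"row {spec.state_names[i]!r} sums to {sums[i]!r}, not 1"
        )
    d = spec.death_index
    death_row = np.zeros(n)
    death_row[d] = 1.0
    if not np.allclose(P[d], death_row, atol=atol, rtol=0):
        raise MatrixValidationError("Death row must be the identity on Death (absorbing)")

    ltf = spec.ltf_index
    if ltf is not None:
        expected = cohort_death_prob
        if expected is None:
            expected = spec.cohort_death_prob
        if expected is None:
            others = [
                P[i, d]
                for i in range(n)
                if i not in (d, ltf)
            ]
            if not others:
                expected = P[ltf, d]
            else:
                if max(others) - min(others) > atol:
                    raise ConfigurationError(
                        "cohort death rate is ambiguous: alive rows have unequal "
                        "death probabilities and no cohort_death_prob was configured"
                    )
                expected = others[0]
        if abs(P[ltf, d] - expected) > atol:
            raise MatrixValidationError(
                f"LTF death probability {P[ltf, d]!r} differs from the cohort "
                f"death rate {expected!r}"
            )
    return m


@dataclass
class CohortTrace:
    """State occupancy by cycle; row 0 is the initial distribution."""

    occupancy: np.ndarray
    state_names: tuple[str, ...]

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=list(self.state_names))
        df.insert(0, "cycle", np.arange(len(df)))
        return df


def run_cohort(spec: ModelSpec, m: TransitionMatrix) -> CohortTrace:
    """Propagate the cohort: occupancy(t+1) = occupancy(t) @ P."""
    validate_matrix(m, spec)
    n = len(spec.states)
    occ = np.empty((spec.n_cycles + 1, n))
    occ[0] = spec.initial_distribution
    for t in range(spec.n_cycles):
        occ[t + 1] = occ[t] @ m.entries
    return CohortTrace(occupancy=occ, state_names=spec.state_names)


def expected_time_in_states(m: TransitionMatrix, spec: ModelSpec) -> dict[str, float]:
    """Expected cycles spent in each transient state before absorption.

    Uses the fundamental matrix N = inv(I - Q) of the absorbing chain,
    weighted by the initial distribution; the count includes cycle 0, so
    it equals the infinite-horizon sum of start-of-cycle occupancies.
    """
    transient = [i for i, s in enumerate(spec.states) if not s.absorbing]
    Q = m.entries[np.ix_(transient, transient)]
    eye = np.eye(len(transient))
    try:
        N = np.linalg.inv(eye - Q)
    except np.linalg.LinAlgError:
        raise ModelError("no absorbing state is reachable (I - Q singular)") from None
    init = np.asarray(spec.initial_distribution)[transient]
    times = init @ N
    if (times < -1e-8).any() or not np.isfinite(times).all():
        raise ModelError("absorption times are not finite/non-negative; chain may not absorb")
    return {spec.state_names[i]: float(times[k]) for k, i in enumerate(transient)}


@dataclass
class StatePayoffs:
    """Per-state utility weights (per year alive) and costs (per cycle).

    States absent from a map contribute zero.  Death, if present, must
    carry exactly zero utility and cost.
    """

    utility_per_year: Mapping[str, float] = field(default_factory=dict)
    cost_per_cycle: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.utility_per_year.get(DEATH, 0.0) != 0.0 or self.cost_per_cycle.get(DEATH, 0.0) != 0.0:
            raise InvalidInputError("Death payoffs must be exactly 0")
        for state, c in self.cost_per_cycle.items():
            if c < 0:
                raise InvalidInputError(f"cost for state {state!r} must be >= 0")

    def vectors(self, spec: ModelSpec) -> tuple[np.ndarray, np.ndarray]:
        for key in (*self.utility_per_year, *self.cost_per_cycle):
            if key not in spec.state_names:
                raise InvalidInputError(f"payoff refers to unknown state {key!r}")
        u = np.array([self.utility_per_year.get(s, 0.0) for s in spec.state_names])
        c = np.array([self.cost_per_cycle.get(s, 0.0) for s in spec.state_names])
        return u, c


def expected_outcomes(
    trace: CohortTrace,
    payoffs: StatePayoffs,
    spec: ModelSpec,
    convention: str | None = None,
) -> tuple[float, float]:
    """Discounted total (cost, QALY) over the horizon.

    For each cycle t = 1..n the cycle reward is the occupancy-weighted
    payoff, with QALYs scaled by the cycle length, discounted by
    (1 + r)^(-t * cycle_length).  ``convention`` selects the occupancy
    row used for cycle t: ``"end"`` (row t, the default), ``"start"``
    (row t-1) or ``"half"`` (the average); when None, the spec's
    half-cycle flag chooses between ``"half"`` and ``"end"``.  Cycle-0
    payoffs are never accrued on their own.
    """
    if convention is None:
        convention = "half" if spec.half_cycle_correction else "end"
    if convention not in ("end", "start", "half"):
        raise InvalidInputError(f"unknown accumulation convention {convention!r}")
    occ = trace.occupancy
    if occ.shape != (spec.n_cycles + 1, len(spec.states)):
        raise InvalidInputError("trace shape does not match the model spec")
    if trace.state_names != spec.state_names:
        raise InvalidInputError("trace states do not match the model spec")
    u, c = payoffs.vectors(spec)
    per_cycle_discount = (1.0 + spec.discount_rate_annual) ** (-spec.cycle_length_years)

    total_cost = 0.0
    total_qaly = 0.0
    for t in range(1, spec.n_cycles + 1):
        if convention == "end":
            row = occ[t]
        elif convention == "start":
            row = occ[t - 1]
        else:
            row = 0.5 * (occ[t - 1] + occ[t])
        v = per_cycle_discount**t
        total_cost += float(row @ c) * v
        total_qaly += float(row @ u) * spec.cycle_length_years * v
    return total_cost, total_qaly
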