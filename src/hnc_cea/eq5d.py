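"""EQ-5D-3L utility scoring with pluggable additive TTO value sets.

A health profile is a 5-digit code over the dimensions mobility,
self-care, usual activities, pain/discomfort and anxiety/depression, each
at level 1 (no problems), 2 (some problems) or 3 (extreme problems).  A
time-trade-off value set scores a profile additively:

    U = full_health − c·1{any level > 1} − Σ d(dim, level) − n3·1{any level = 3}

where ``c`` is a constant decrement applied once for any departure from
full health, ``d`` are per-dimension decrements for levels 2 and 3, and
``n3`` is applied once if any dimension is at the extreme level.  Scores
below zero (states worse than dead) are permitted.

Value sets are data, loaded from CSV; the package ships a fully synthetic
set for testing and demonstration because the country-specific TTO
coefficients used in the study are not public in machine-readable form.
"""

from __future__ import annotations

import itertools
import math
import statistics
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import ConfigurationError, InvalidInputError

DIMENSIONS: tuple[str, ...] = (
    "mobility",
    "self_care",
    "usual_activities",
    "pain_discomfort",
    "anxiety_depression",
)
LEVELS: tuple[int, ...] = (1, 2, 3)


@dataclass(frozen=True)
class EQ5DResponse:
    """One respondent's 5-digit EQ-5D-3L profile."""

    mobility: int
    self_care: int
    usual_activities: int
    pain_discomfort: int
    anxiety_depression: int

    def __post_init__(self) -> None:
        for dim in DIMENSIONS:
            lvl = getattr(self, dim)
            if lvl not in LEVELS:
                raise InvalidInputError(f"{dim} level must be in {LEVELS}, got {lvl!r}")

    @classmethod
    def from_profile(cls, profile: str) -> "EQ5DResponse":
        """Build from a 5-character digit string such as ``"21231"``."""
        if len(profile) != 5 or not profile.isdigit():
            raise InvalidInputError(f"profile must be 5 digits in 1-3, got {profile!r}")
        return cls(*(int(ch) for ch in profile))

    @property
    def profile(self) -> str:
        return "".join(str(getattr(self, d)) for d in DIMENSIONS)

    def levels(self) -> tuple[int, ...]:
        return tuple(getattr(self, d) for d in DIMENSIONS)


@dataclass(frozen=True)
class ValueSet:
    """Additive TTO value set: constant, per-dimension and N3 decrements.

    ``dimension_decrements`` maps ``(dimension, level)`` for levels 2 and 3
    to non-negative decrements.  Entries may be sparse; scoring a profile
    that needs a missing entry raises :class:`ConfigurationError`.
    """

    full_health_value: float = 1.0
    constant_decrement_any_problem: float = 0.0
    dimension_decrements: Mapping[tuple[str, int], float] = field(default_factory=dict)
    n3_decrement: float = 0.0

    def __post_init__(self) -> None:
        if self.constant_decrement_any_problem < 0 or self.n3_decrement < 0:
            raise InvalidInputError("value-set decrements must be >= 0")
        for (dim, lvl), v in self.dimension_decrements.items():
            if dim not in DIMENSIONS or lvl not in (2, 3):
                raise ConfigurationError(f"bad decrement key {(dim, lvl)!r}")
            if v < 0:
                raise InvalidInputError(f"decrement for {(dim, lvl)!r} must be >= 0")
        for dim in DIMENSIONS:
            d2 = self.dimension_decrements.get((dim, 2))
            d3 = self.dimension_decrements.get((dim, 3))
            if d2 is not None and d3 is not None and d3 < d2:
                raise ConfigurationError(
                    f"level-3 decrement below level-2 decrement for {dim!r}"
                )


@dataclass(frozen=True)
class UtilityEstimate:
    """Mean/SD utility over a sample of scored profiles."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise InvalidInputError("n must be >= 1")
        if self.sd < 0:
            raise InvalidInputError("sd must be >= 0")


def score_profile(response: EQ5DResponse, vs: ValueSet) -> float:
    """Score one profile with an additive value set.

    Full health (11111) always scores ``full_health_value``.
    """
    levels = response.levels()
    utility = vs.full_health_value
    if any(lvl > 1 for lvl in levels):
        utility -= vs.constant_decrement_any_problem
    for dim, lvl in zip(DIMENSIONS, levels):
        if lvl == 1:
            continue
        try:
            utility -= vs.dimension_decrements[(dim, lvl)]
        except KeyError:
            raise ConfigurationError(
                f"value set has no decrement for ({dim!r}, level {lvl})"
            ) from None
    if any(lvl == 3 for lvl in levels):
        utility -= vs.n3_decrement
    return utility


def state_utility(responses: Iterable[EQ5DResponse], vs: ValueSet) -> UtilityEstimate:
    """Mean and SD of scored utilities (sample SD; 0 for a single response)."""
    scores = [score_profile(r, vs) for r in responses]
    if not scores:
        raise InvalidInputError("state_utility requires at least one response")
    mean = sum(scores) / len(scores)
    sd = statistics.stdev(scores) if len(scores) > 1 else 0.0
    return UtilityEstimate(mean=mean, sd=sd, n=len(scores))


def expected_utility(
    level_probs: Mapping[str, Sequence[float]], vs: ValueSet, atol: float = 1e-9
) -> float:
    """Exact expected utility under independent per-dimension level draws.

    ``level_probs[dim]`` is the probability vector over levels 1-3.  The
    expectation is computed by exhaustive enumeration of all 3^5 = 243
    profiles (the constant and N3 terms make the score non-separable
    across dimensions, so no shortcut is taken).
    """
    probs = []
    for dim in DIMENSIONS:
        p = list(level_probs[dim])
        if len(p) != 3 or any(x < 0 for x in p) or abs(sum(p) - 1.0) > atol:
            raise ConfigurationError(f"bad level probability vector for {dim!r}: {p}")
        probs.append(p)
    total = 0.0
    for combo in itertools.product(LEVELS, repeat=5):
        w = math.prod(probs[i][lvl - 1] for i, lvl in enumerate(combo))
        if w == 0.0:
            continue
        total += w * score_profile(EQ5DResponse(*combo), vs)
    return total


# ---------------------------------------------------------------------------
# value-set and response I/O


def load_value_set(path) -> ValueSet:
    """Load a value set from CSV rows ``term,dimension,level,decrement``.

    ``term`` is ``constant``, ``n3``, ``full_health`` or ``dimension``;
    ``dimension``/``level`` apply only to dimension rows.
    """
    df = pd.read_csv(path)
    full = 1.0
    constant = 0.0
    n3 = 0.0
    decs: dict[tuple[str, int], float] = {}
    for row in df.itertuples(index=False):
        term = str(row.term)
        if term == "constant":
            constant = float(row.decrement)
        elif term == "n3":
            n3 = float(row.decrement)
        elif term == "full_health":
            full = float(row.decrement)
        elif term == "dimension":
            decs[(str(row.dimension), int(row.level))] = float(row.decrement)
        else:
            raise ConfigurationError(f"unknown value-set term {term!r}")
    return ValueSet(
        full_health_value=full,
        constant_decrement_any_problem=constant,
        dimension_decrements=decs,
        n3_decrement=n3,
    )


def default_value_set() -> ValueSet:
    """The package's shipped synthetic TTO value set (for tests and demos)."""
    with resources.as_file(
        resources.files("hnc_cea.data").joinpath("synthetic_tto_value_set.csv")
    ) as p:
        return load_value_set(p)


def read_responses(path) -> pd.DataFrame:
    """Read responses CSV ``patient_id,arm,state_label,profile``; validates profiles."""
    df = pd.read_csv(path, dtype={"patient_id": str, "arm": str, "state_label": str, "profile": str})
    required = {"patient_id", "arm", "state_label", "profile"}
    if not required.issubset(df.columns):
        raise InvalidInputError(f"responses file missing columns {sorted(required - set(df.columns))}")
    df["response"] = df["profile"].map(EQ5DResponse.from_profile)
    return df


def utilities_by_state(df: pd.DataFrame, vs: ValueSet) -> pd.DataFrame:
    """Per (arm, state_label) utility estimates from a responses frame."""
    rows = []
    for (arm, state), grp in df.groupby(["arm", "state_label"], sort=True):
        est = state_utility(list(grp["response"]), vs)
        rows.append({"arm": arm, "state_label": state, "mean": est.mean, "sd": est.sd, "n": est.n})
    return pd.DataFrame(rows)
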