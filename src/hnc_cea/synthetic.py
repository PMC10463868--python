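"""Synthetic study-shaped data with known ground truth.

The study collected costs and EQ-5D-3L responses from 97 head-and-neck
cancer patients treated with IMRT or 3D-CRT; the micro-data are not
deposited.  This module generates inputs of exactly that shape — per-
patient cost records whose category means default to the published cost
table, absenteeism records whose human-capital value matches the
productivity-loss means, EQ-5D responses with configurable per-dimension
level probabilities, and valid transition matrices honouring the
lost-to-follow-up mortality rule — so every pipeline stage can be tested
end to end without any download.  Every generator is a pure function of
its configuration and seed.

The per-arm split of the 97 respondents, the per-state EQ-5D level
probabilities and the cost dispersion are not reported in the study;
the defaults here are placeholders chosen once (49/48 split, CV 0.4
gamma cost noise) and documented as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from . import markov
from .costing import CATEGORIES, DIRECT_MEDICAL, DIRECT_NON_MEDICAL, AbsenteeismRecord, CostItem
from .eq5d import DIMENSIONS, EQ5DResponse
from .exceptions import ConfigurationError, InvalidInputError
from .markov import HealthState, ModelSpec, StatePayoffs, TransitionMatrix
from .model import CostEffectivenessModel, Strategy
from .sensitivity import ParamSpec

ARMS: tuple[str, str] = ("3D-CRT", "IMRT")

#: Published per-patient cost means (USD) by arm and category.
TABLE1_MEANS: dict[str, dict[str, float]] = {
    "IMRT": {
        "visits": 44.17,
        "laboratory": 138.99,
        "diagnosis": 184.75,
        "radiotherapy": 12995.65,
        "transport": 46.22,
        "lodging": 57.14,
        "productivity_loss": 294.41,
    },
    "3D-CRT": {
        "visits": 17.57,
        "laboratory": 83.12,
        "diagnosis": 175.17,
        "radiotherapy": 9497.05,
        "transport": 24.89,
        "lodging": 55.83,
        "productivity_loss": 296.57,
    },
}

#: Placeholder per-dimension level probabilities by arm and toxicity state.
DEFAULT_EQ5D_PROBS: dict[str, dict[str, dict[str, tuple[float, float, float]]]] = {
    "3D-CRT": {
        "LXLD": {d: (0.70, 0.25, 0.05) for d in DIMENSIONS},
        "HXLD": {d: (0.40, 0.40, 0.20) for d in DIMENSIONS},
    },
    "IMRT": {
        "LXLD": {d: (0.60, 0.30, 0.10) for d in DIMENSIONS},
        "HXLD": {d: (0.35, 0.45, 0.20) for d in DIMENSIONS},
    },
}

# Daily wages (USD) used to decompose productivity loss into absenteeism
# records; shares split the target mean across the three components.
_WAGE_PATIENT = 24.0
_WAGE_COMPANION = 20.0
_RATE_NURSING = 30.0
_SHARES = (0.60, 0.25, 0.15)


@dataclass
class SyntheticStudyConfig:
    """Configuration for the synthetic study generators."""

    n_patients: int = 97
    #: fraction of patients assigned to the comparator (IMRT) arm
    arm_split: float = 49 / 97
    cost_means: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {a: dict(m) for a, m in TABLE1_MEANS.items()}
    )
    cost_cv: float = 0.4
    eq5d_level_probs: Mapping[str, Mapping[str, Mapping[str, Sequence[float]]]] = field(
        default_factory=lambda: {
            a: {s: dict(d) for s, d in states.items()} for a, states in DEFAULT_EQ5D_PROBS.items()
        }
    )
    death_prob_per_cycle: float = 0.02
    seed: int = 20210822

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise InvalidInputError("n_patients must be >= 1")
        if not 0.0 <= self.arm_split <= 1.0:
            raise ConfigurationError("arm_split must lie in [0, 1]")
        if self.cost_cv < 0:
            raise ConfigurationError("cost_cv must be >= 0")
        if not 0.0 <= self.death_prob_per_cycle < 1.0:
            raise ConfigurationError("death_prob_per_cycle must lie in [0, 1)")
        n_imrt = round(self.n_patients * self.arm_split)
        if 0 < self.arm_split < 1 and self.n_patients < 2:
            raise ConfigurationError("need n_patients >= 2 when both arms are requested")
        self._n_by_arm = {"IMRT": n_imrt, "3D-CRT": self.n_patients - n_imrt}
        for arm, states in self.eq5d_level_probs.items():
            for state, dims in states.items():
                for dim, p in dims.items():
                    p = list(p)
                    if len(p) != 3 or any(x < 0 for x in p) or abs(sum(p) - 1.0) > 1e-9:
                        raise ConfigurationError(
                            f"eq5d level probabilities for ({arm}, {state}, {dim}) must be a "
                            f"3-vector summing to 1, got {p}"
                        )

    @property
    def n_by_arm(self) -> dict[str, int]:
        return dict(self._n_by_arm)

    def patient_ids(self, arm: str) -> list[str]:
        prefix = "I" if arm == "IMRT" else "C"
        return [f"{prefix}{k:03d}" for k in range(1, self._n_by_arm[arm] + 1)]


def _gamma_draw(rng: np.random.Generator, mean: float, cv: float, size: int) -> np.ndarray:
    """Gamma draws with the given mean and coefficient of variation (cv=0 → constant)."""
    if mean < 0:
        raise ConfigurationError(f"cost mean must be >= 0, got {mean!r}")
    if mean == 0.0 or cv == 0.0:
        return np.full(size, mean)
    shape = 1.0 / (cv * cv)
    scale = mean * cv * cv
    return rng.gamma(shape, scale, size=size)


def gen_cost_records(
    cfg: SyntheticStudyConfig,
) -> tuple[list[CostItem], list[AbsenteeismRecord]]:
    """Per-patient cost items and absenteeism records for both arms.

    Direct categories are gamma-distributed around the configured means
    with the configured CV; productivity loss is decomposed into patient
    absenteeism, companion absenteeism and home nursing at fixed daily
    wages so that the human-capital value has the configured mean.
    Amounts are emitted in USD.
    """
    rng = np.random.default_rng(cfg.seed)
    items: list[CostItem] = []
    absentee: list[AbsenteeismRecord] = []
    for arm in ARMS:
        ids = cfg.patient_ids(arm)
        if not ids:
            continue
        means = cfg.cost_means[arm]
        unknown = set(means) - set(CATEGORIES)
        if unknown:
            raise ConfigurationError(f"unknown cost categories {sorted(unknown)}")
        for cat in DIRECT_MEDICAL + DIRECT_NON_MEDICAL:
            draws = _gamma_draw(rng, float(means.get(cat, 0.0)), cfg.cost_cv, len(ids))
            items.extend(
                CostItem(pid, cat, float(a), "USD") for pid, a in zip(ids, draws)
            )
        target = float(means.get("productivity_loss", 0.0))
        day_means = (
            _SHARES[0] * target / _WAGE_PATIENT,
            _SHARES[1] * target / _WAGE_COMPANION,
            _SHARES[2] * target / _RATE_NURSING,
        )
        pdays = _gamma_draw(rng, day_means[0], cfg.cost_cv, len(ids))
        cdays = _gamma_draw(rng, day_means[1], cfg.cost_cv, len(ids))
        ndays = _gamma_draw(rng, day_means[2], cfg.cost_cv, len(ids))
        absentee.extend(
            AbsenteeismRecord(
                patient_id=pid,
                patient_days_absent=float(pd_),
                patient_daily_wage=_WAGE_PATIENT,
                companion_days_absent=float(cd),
                companion_daily_wage=_WAGE_COMPANION,
                home_nursing_days=float(nd),
                nursing_daily_rate=_RATE_NURSING,
            )
            for pid, pd_, cd, nd in zip(ids, pdays, cdays, ndays)
        )
    return items, absentee


@dataclass(frozen=True)
class LabelledResponse:
    """An EQ-5D response tagged with its arm and Markov-state label."""

    patient_id: str
    arm: str
    state_label: str
    response: EQ5DResponse


def gen_eq5d_responses(cfg: SyntheticStudyConfig) -> list[LabelledResponse]:
    """EQ-5D-3L responses sampled dimension-independently per (arm, state).

    Patients within an arm are assigned round-robin to that arm's
    configured state labels, so state counts are as balanced as possible.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    out: list[LabelledResponse] = []
    for arm in ARMS:
        ids = cfg.patient_ids(arm)
        states = list(cfg.eq5d_level_probs.get(arm, {}))
        if not ids or not states:
            continue
        for k, pid in enumerate(ids):
            state = states[k % len(states)]
            dims = cfg.eq5d_level_probs[arm][state]
            levels = [int(rng.choice((1, 2, 3), p=np.asarray(dims[d], dtype=float))) for d in DIMENSIONS]
            out.append(LabelledResponse(pid, arm, state, EQ5DResponse(*levels)))
    return out


def gen_transition_matrices(
    n_alive_states: int = 4,
    death_prob: float = 0.02,
    ltf_prob: float = 0.05,
    mixing: float = 0.2,
    seed: int = 20210822,
    strategies: Sequence[str] = ARMS,
    state_names: Sequence[str] | None = None,
) -> tuple[ModelSpec, dict[str, TransitionMatrix]]:
    """Random valid matrices over ``n_alive_states`` toxicity states + LTF + Death.

    Every alive row (including LTF) sends exactly ``death_prob`` to
    Death; non-LTF alive rows send ``ltf_prob`` to LTF and split the
    remaining mass between staying put (weight ``1 - mixing``) and a
    random Dirichlet mix over the other toxicity states (weight
    ``mixing``).  The result passes matrix validation by construction.
    """
    if not 0.0 <= death_prob < 1.0 or not 0.0 <= ltf_prob < 1.0:
        raise ConfigurationError("death_prob and ltf_prob must lie in [0, 1)")
    if death_prob + ltf_prob >= 1.0:
        raise ConfigurationError("death_prob + ltf_prob must be < 1")
    if not 0.0 <= mixing <= 1.0:
        raise ConfigurationError("mixing must lie in [0, 1]")
    if n_alive_states < 1:
        raise ConfigurationError("need at least one toxicity state")
    if state_names is None:
        if n_alive_states == 4:
            state_names = ("LXLD", "LXHD", "HXLD", "HXHD")
        else:
            state_names = tuple(f"S{k + 1}" for k in range(n_alive_states))
    if len(state_names) != n_alive_states:
        raise ConfigurationError("state_names length must equal n_alive_states")

    states = tuple(
        [HealthState(n) for n in state_names]
        + [HealthState("LTF", lost_to_follow_up=True), HealthState("Death", absorbing=True)]
    )
    init = np.zeros(len(states))
    init[:n_alive_states] = 1.0 / n_alive_states
    spec = ModelSpec(
        states=states,
        initial_distribution=init,
        cohort_death_prob=death_prob,
    )
    rng = np.random.default_rng(seed)
    n = len(states)
    ltf_i, death_i = n - 2, n - 1
    matrices: dict[str, TransitionMatrix] = {}
    for strat in strategies:
        P = np.zeros((n, n))
        for i in range(n_alive_states):
            P[i, death_i] = death_prob
            P[i, ltf_i] = ltf_prob
            rem = 1.0 - death_prob - ltf_prob
            P[i, i] = (1.0 - mixing) * rem
            others = [j for j in range(n_alive_states) if j != i]
            if others and mixing > 0:
                w = rng.dirichlet(np.ones(len(others)))
                for j, wj in zip(others, w):
                    P[i, j] = mixing * rem * wj
            else:
                P[i, i] = rem
        P[ltf_i, death_i] = death_prob
        P[ltf_i, ltf_i] = 1.0 - death_prob
        P[death_i, death_i] = 1.0
        matrices[strat] = markov.validate_matrix(TransitionMatrix(strat, P), spec)
    return spec, matrices


# ---------------------------------------------------------------------------
# calibrated single-state fixture


@dataclass
class CalibratedFixture:
    """A two-strategy model calibrated to the published base-case cells."""

    model: CostEffectivenessModel
    psa_params: list[ParamSpec]
    dsa_params: list[ParamSpec]


#: Per-cycle payoffs chosen so that 5 undiscounted one-year cycles yield the
#: published (cost, QALY) cells exactly: 5 × 1841.952 = 9209.76 and
#: 5 × 0.726 = 3.63 for 3D-CRT; 5 × 2512.58 = 12562.90 and 5 × 0.634 = 3.17
#: for IMRT.
_FIXTURE = {
    "3D-CRT": {"utility": 0.726, "cost": 1841.952},
    "IMRT": {"utility": 0.634, "cost": 2512.58},
}


def gen_calibrated_fixture() -> CalibratedFixture:
    """Deterministic two-arm model reproducing the published base case.

    A single always-alive state over five undiscounted one-year cycles;
    per-cycle payoffs are the published totals divided by five.  PSA
    parameters put modest beta noise on the utilities and gamma noise on
    the per-cycle costs, centred on the base values; DSA parameters give
    ±10% utility ranges.
    """
    states = (HealthState("Alive"), HealthState("Death", absorbing=True))
    spec = ModelSpec(
        states=states,
        cycle_length_years=1.0,
        n_cycles=5,
        discount_rate_annual=0.0,
        half_cycle_correction=False,
        initial_distribution=(1.0, 0.0),
    )
    strategies = []
    for name, pay in _FIXTURE.items():
        P = np.array([[1.0, 0.0], [0.0, 1.0]])
        strategies.append(
            Strategy(
                name=name,
                transition=TransitionMatrix(name, P),
                payoffs=StatePayoffs(
                    utility_per_year={"Alive": pay["utility"]},
                    cost_per_cycle={"Alive": pay["cost"]},
                ),
            )
        )
    model = CostEffectivenessModel(spec, strategies)

    psa_params = []
    dsa_params = []
    for name, pay in _FIXTURE.items():
        u, c = pay["utility"], pay["cost"]
        psa_params.append(
            ParamSpec(
                name=f"utility {name}", target=f"utility:{name}:Alive", base=u,
                distribution="beta", mean=u, sd=0.04,
            )
        )
        psa_params.append(
            ParamSpec(
                name=f"cycle cost {name}", target=f"cost:{name}:Alive", base=c,
                distribution="gamma", mean=c, sd=0.08 * c,
            )
        )
        dsa_params.append(
            ParamSpec(
                name=f"utility {name}", target=f"utility:{name}:Alive", base=u,
                low=0.9 * u, high=min(1.0, 1.1 * u),
            )
        )
        dsa_params.append(
            ParamSpec(
                name=f"cycle cost {name}", target=f"cost:{name}:Alive", base=c,
                low=0.9 * c, high=1.1 * c,
            )
        )
    return CalibratedFixture(model=model, psa_params=psa_params, dsa_params=dsa_params)


def gen_demo_model(seed: int = 20210822) -> tuple[CostEffectivenessModel, list[ParamSpec]]:
    """Six-state two-arm demo model with DSA ranges for a tornado diagram.

    Utility ranges are deliberately widest for the reference arm's LXLD
    and HXLD states, mirroring the qualitative finding that those two
    utilities drive the result.
    """
    spec, matrices = gen_transition_matrices(seed=seed)
    utilities = {"LXLD": 0.85, "LXHD": 0.65, "HXLD": 0.70, "HXHD": 0.50, "LTF": 0.60}
    costs = {
        "3D-CRT": {s: c for s, c in zip(("LXLD", "LXHD", "HXLD", "HXHD", "LTF"), (400.0, 700.0, 600.0, 900.0, 300.0))},
        "IMRT": {s: c for s, c in zip(("LXLD", "LXHD", "HXLD", "HXHD", "LTF"), (550.0, 850.0, 750.0, 1050.0, 300.0))},
    }
    upfront = {"3D-CRT": 7000.0, "IMRT": 10500.0}
    strategies = [
        Strategy(
            name=arm,
            transition=matrices[arm],
            payoffs=StatePayoffs(utility_per_year=dict(utilities), cost_per_cycle=dict(costs[arm])),
            upfront_cost=upfront[arm],
        )
        for arm in ARMS
    ]
    model = CostEffectivenessModel(spec, strategies)

    params = []
    for state, width in (("LXLD", 0.30), ("HXLD", 0.25), ("LXHD", 0.10), ("HXHD", 0.10)):
        u = utilities[state]
        params.append(
            ParamSpec(
                name=f"QALY weight {state} (3D-CRT)",
                target=f"utility:3D-CRT:{state}",
                base=u, low=u - width / 2, high=min(1.0, u + width / 2),
            )
        )
    for arm in ARMS:
        c = upfront[arm]
        params.append(
            ParamSpec(
                name=f"upfront cost ({arm})", target=f"upfront:{arm}",
                base=c, low=0.95 * c, high=1.05 * c,
            )
        )
    return model, params
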