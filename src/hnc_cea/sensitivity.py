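"""Deterministic and probabilistic sensitivity analysis.

One-way (tornado) analysis re-evaluates an incremental outcome at a
parameter's low and high bounds with everything else at base.
Probabilistic sensitivity analysis (PSA) draws all uncertain parameters
jointly — beta for utilities and single probabilities, gamma for costs,
Dirichlet for whole transition rows, each moment-matched from a mean and
SD — pushes every draw through the Markov engine for every strategy, and
classifies the incremental (ΔQALY, Δcost) pair on the cost-effectiveness
plane.  Acceptability curves report, at each willingness-to-pay value,
the fraction of draws in which each strategy has the highest net
monetary benefit (ties split equally).

Parameter targets are colon-separated paths into the model:

    ``utility:<strategy>:<state>``        state utility weight
    ``cost:<strategy>:<state>``           state cost per cycle
    ``upfront:<strategy>``                cycle-0 cost
    ``transition:<strategy>:<from>:<to>`` one transition probability
    ``row:<strategy>:<from>``             a full transition row (PSA only)

Perturbing a single transition probability rescales the remaining
non-Death entries of its row proportionally and leaves the Death
probability fixed, so the row stays stochastic and the lost-to-follow-up
mortality rule is preserved.

Quadrant convention (ΔQALY on x, Δcost on y, comparator minus
reference): I = (+, +), II = (+, −), III = (−, −), IV = (−, +); a zero
delta is assigned to the adjacent lower-numbered quadrant and flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import markov, ranking
from .exceptions import ConfigurationError, InvalidInputError, ModelError
from .model import CostEffectivenessModel
from .ranking import StrategyResult

DISTRIBUTIONS = ("fixed", "beta", "gamma", "dirichlet_row")
OUTCOMES = ("icer", "nmb", "delta_cost", "delta_qaly")

#: Default PSA seed when a run config does not supply one.
DEFAULT_SEED = 20210822


@dataclass
class ParamSpec:
    """One uncertain parameter: target path, base value, DSA range, PSA distribution."""

    name: str
    target: str
    base: float
    low: float | None = None
    high: float | None = None
    distribution: str = "fixed"
    mean: float | None = None
    sd: float | None = None
    concentration: float | None = None

    def __post_init__(self) -> None:
        if self.distribution not in DISTRIBUTIONS:
            raise ConfigurationError(
                f"unknown distribution {self.distribution!r}; expected one of {DISTRIBUTIONS}"
            )
        if self.low is None:
            self.low = self.base
        if self.high is None:
            self.high = self.base
        if not (self.low <= self.base <= self.high):
            raise ConfigurationError(
                f"parameter {self.name!r}: need low <= base <= high, got "
                f"({self.low}, {self.base}, {self.high})"
            )
        if self.mean is None:
            self.mean = self.base


# ---------------------------------------------------------------------------
# target paths


def _parse_target(target: str) -> tuple[str, ...]:
    parts = tuple(target.split(":"))
    kinds = {"utility": 3, "cost": 3, "upfront": 2, "transition": 4, "row": 3}
    if not parts or parts[0] not in kinds or len(parts) != kinds[parts[0]]:
        raise ConfigurationError(f"unresolvable parameter target {target!r}")
    return parts


def set_transition_prob(
    entries: np.ndarray, spec: markov.ModelSpec, row_state: str, col_state: str, value: float
) -> None:
    """Set one transition probability in place, renormalizing its row.

    Non-Death entries other than the target share the remaining mass in
    proportion to their current values; the Death entry is untouched
    (unless it is itself the target, in which case all other entries
    rescale).  Raises when the requested value leaves no feasible row.
    """
    if not (0.0 <= value <= 1.0):
        raise InvalidInputError(f"transition probability must be in [0, 1], got {value!r}")
    i = spec.index(row_state)
    j = spec.index(col_state)
    d = spec.death_index
    row = entries[i].copy()
    if j == d:
        others = [k for k in range(len(row)) if k != d]
        free = 1.0 - value
    else:
        others = [k for k in range(len(row)) if k not in (j, d)]
        free = 1.0 - value - row[d]
    if free < -markov.ATOL:
        raise InvalidInputError(
            f"setting {row_state!r}->{col_state!r} to {value} exceeds the row's free mass"
        )
    free = max(free, 0.0)
    current = sum(row[k] for k in others)
    if current <= markov.ATOL:
        if free > markov.ATOL:
            raise InvalidInputError(
                f"row {row_state!r} has no entries to absorb the remaining mass"
            )
        scale = 0.0
    else:
        scale = free / current
    for k in others:
        row[k] *= scale
    row[j] = value
    entries[i] = row


def apply_param(model: CostEffectivenessModel, target: str, value) -> None:
    """Apply one parameter value to a model in place (use on a copy)."""
    parts = _parse_target(target)
    kind = parts[0]
    try:
        strat = model.strategies[parts[1]]
    except KeyError:
        raise ConfigurationError(f"target {target!r}: unknown strategy {parts[1]!r}") from None
    if kind == "utility":
        model.spec.index(parts[2])
        strat.payoffs.utility_per_year = {**strat.payoffs.utility_per_year, parts[2]: float(value)}
    elif kind == "cost":
        model.spec.index(parts[2])
        strat.payoffs.cost_per_cycle = {**strat.payoffs.cost_per_cycle, parts[2]: float(value)}
    elif kind == "upfront":
        strat.upfront_cost = float(value)
    elif kind == "transition":
        set_transition_prob(strat.transition.entries, model.spec, parts[2], parts[3], float(value))
    elif kind == "row":
        i = model.spec.index(parts[2])
        row = np.asarray(value, dtype=float)
        if row.shape != (len(model.spec.states),):
            raise ConfigurationError(f"target {target!r}: row has wrong length")
        strat.transition.entries[i] = row


# ---------------------------------------------------------------------------
# incremental outcomes


def _resolve_pair(
    base_results: Mapping[str, StrategyResult],
    reference: str | None,
    comparator: str | None,
) -> tuple[str, str]:
    names = list(base_results)
    if reference is None:
        reference = min(base_results.values(), key=lambda r: r.cost).name
    if reference not in base_results:
        raise InvalidInputError(f"unknown reference strategy {reference!r}")
    if comparator is None:
        others = [n for n in names if n != reference]
        if len(others) != 1:
            raise InvalidInputError(
                "comparator must be named explicitly when more than two strategies are present"
            )
        comparator = others[0]
    if comparator not in base_results or comparator == reference:
        raise InvalidInputError(f"bad comparator {comparator!r}")
    return reference, comparator


def _incremental_outcome(
    results: Mapping[str, StrategyResult],
    outcome: str,
    wtp: float | None,
    reference: str,
    comparator: str,
) -> float:
    ref, comp = results[reference], results[comparator]
    if outcome == "delta_cost":
        return comp.cost - ref.cost
    if outcome == "delta_qaly":
        return comp.qaly - ref.qaly
    if outcome == "icer":
        value = ranking.icer(ref, comp)
        if value is None:
            raise ModelError("ICER undefined: zero QALY difference at this evaluation")
        return value
    if outcome == "nmb":
        if wtp is None:
            raise InvalidInputError("the nmb outcome requires a willingness-to-pay value")
        return ranking.net_monetary_benefit(comp, wtp) - ranking.net_monetary_benefit(ref, wtp)
    raise InvalidInputError(f"unknown outcome {outcome!r}; expected one of {OUTCOMES}")


# ---------------------------------------------------------------------------
# one-way / tornado


@dataclass(frozen=True)
class TornadoBar:
    name: str
    outcome_at_low: float
    outcome_at_high: float

    @property
    def swing(self) -> float:
        return abs(self.outcome_at_high - self.outcome_at_low)


def one_way(
    model: CostEffectivenessModel,
    p: ParamSpec,
    outcome: str = "icer",
    wtp: float | None = None,
    reference: str | None = None,
    comparator: str | None = None,
) -> TornadoBar:
    """Evaluate an incremental outcome at a parameter's low and high bounds.

    The base model is never mutated; each bound is applied to a fresh
    copy.  Whole-row targets are rejected (perturb a scalar entry instead
    and let the row renormalize).
    """
    if _parse_target(p.target)[0] == "row":
        raise ConfigurationError(
            f"parameter {p.name!r}: whole-row targets are not valid for one-way analysis"
        )
    reference, comparator = _resolve_pair(model.evaluate(), reference, comparator)
    values = []
    for bound in (p.low, p.high):
        perturbed = model.copy()
        apply_param(perturbed, p.target, bound)
        values.append(
            _incremental_outcome(perturbed.evaluate(), outcome, wtp, reference, comparator)
        )
    return TornadoBar(name=p.name, outcome_at_low=values[0], outcome_at_high=values[1])


def tornado(bars: Iterable[TornadoBar]) -> list[TornadoBar]:
    """Sort bars by descending swing; ties keep input order (stable sort)."""
    bars = list(bars)
    if not bars:
        raise InvalidInputError("tornado requires at least one bar")
    return sorted(bars, key=lambda b: -b.swing)


# ---------------------------------------------------------------------------
# distributions (method of moments)


def beta_moments(mean: float, sd: float) -> tuple[float, float]:
    """Beta(α, β) matching a mean in (0,1) and a feasible SD."""
    if not 0.0 < mean < 1.0:
        raise ConfigurationError(f"beta mean must lie in (0, 1), got {mean!r}")
    if sd <= 0:
        raise ConfigurationError(f"beta sd must be positive, got {sd!r}")
    var = sd * sd
    if var >= mean * (1.0 - mean):
        raise ConfigurationError(
            f"beta sd {sd} too large for mean {mean} (needs sd^2 < mean(1-mean))"
        )
    alpha = mean * (mean * (1.0 - mean) / var - 1.0)
    beta = alpha * (1.0 - mean) / mean
    return alpha, beta


def gamma_moments(mean: float, sd: float) -> tuple[float, float]:
    """Gamma(shape, scale) matching a positive mean and SD."""
    if mean <= 0 or sd <= 0:
        raise ConfigurationError(f"gamma needs mean > 0 and sd > 0, got ({mean!r}, {sd!r})")
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return shape, scale


def draw_parameters(
    model: CostEffectivenessModel,
    params: Sequence[ParamSpec],
    rng: np.random.Generator,
) -> CostEffectivenessModel:
    """One joint parameter draw applied to a copy of the model.

    Parameters are drawn in declaration order from the single supplied
    generator, so the draw stream is reproducible.  Fixed parameters keep
    their base values.  The returned model is *not* revalidated here;
    :func:`run_psa` rejects draws whose matrices fail validation.
    """
    sampled = model.copy()
    for p in params:
        if p.distribution == "fixed":
            continue
        if p.distribution == "beta":
            a, b = beta_moments(p.mean, p.sd if p.sd is not None else 0.0)
            value = rng.beta(a, b)
        elif p.distribution == "gamma":
            shape, scale = gamma_moments(p.mean, p.sd if p.sd is not None else 0.0)
            value = rng.gamma(shape, scale)
        else:  # dirichlet_row
            parts = _parse_target(p.target)
            if parts[0] != "row":
                raise ConfigurationError(
                    f"parameter {p.name!r}: dirichlet_row requires a row:<strategy>:<state> target"
                )
            if p.concentration is None or p.concentration <= 0:
                raise ConfigurationError(
                    f"parameter {p.name!r}: dirichlet_row needs a positive concentration"
                )
            i = sampled.spec.index(parts[2])
            mean_row = sampled.strategies[parts[1]].transition.entries[i]
            alpha = np.maximum(np.asarray(mean_row) * p.concentration, 1e-12)
            value = rng.dirichlet(alpha)
        apply_param(sampled, p.target, value)
    return sampled


# ---------------------------------------------------------------------------
# PSA


def classify_quadrant(delta_qaly: float, delta_cost: float) -> tuple[str, bool]:
    """CE-plane quadrant for (ΔQALY, Δcost), with a boundary flag for zero deltas."""
    if delta_qaly == 0.0 and delta_cost == 0.0:
        return "I", True
    if delta_qaly == 0.0:
        return ("I", True) if delta_cost > 0 else ("II", True)
    if delta_cost == 0.0:
        return ("I", True) if delta_qaly > 0 else ("III", True)
    if delta_qaly > 0:
        return ("I", False) if delta_cost > 0 else ("II", False)
    return ("III", False) if delta_cost < 0 else ("IV", False)


@dataclass
class PSAResult:
    """Monte-Carlo PSA draws with CE-plane and acceptability summaries."""

    reference: str
    comparator: str
    costs: pd.DataFrame
    qalys: pd.DataFrame
    deltas: pd.DataFrame
    base_results: dict[str, StrategyResult]
    n_rejected: int = 0
    seed: int | None = None

    @property
    def n_draws(self) -> int:
        return len(self.deltas)

    @property
    def strategies(self) -> list[str]:
        return list(self.costs.columns)

    def quadrant_shares(self) -> dict[str, float]:
        """Fraction of draws in each CE-plane quadrant (sums to 1)."""
        counts = self.deltas["quadrant"].value_counts()
        return {q: float(counts.get(q, 0)) / self.n_draws for q in ("I", "II", "III", "IV")}

    def default_wtp_grid(self, n_points: int = 101) -> np.ndarray:
        top = 3.0 * max(r.cost for r in self.base_results.values())
        return np.linspace(0.0, top, n_points)

    def ceac(self, wtp_grid: Sequence[float] | None = None) -> pd.DataFrame:
        grid = self.default_wtp_grid() if wtp_grid is None else np.asarray(wtp_grid, dtype=float)
        return ceac(self.costs, self.qalys, grid)

    def samples_frame(self) -> pd.DataFrame:
        """Long-format draw table (deltas attached to comparator rows)."""
        rows = []
        for idx in range(self.n_draws):
            for s in self.strategies:
                row: dict[str, object] = {
                    "draw": idx,
                    "strategy": s,
                    "cost": self.costs.iloc[idx][s],
                    "qaly": self.qalys.iloc[idx][s],
                }
                if s == self.comparator:
                    row.update(
                        delta_cost=self.deltas.iloc[idx]["delta_cost"],
                        delta_qaly=self.deltas.iloc[idx]["delta_qaly"],
                        quadrant=self.deltas.iloc[idx]["quadrant"],
                    )
                rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        shares = self.quadrant_shares()
        lines = [
            f"PSA: {self.n_draws} draws ({self.n_rejected} rejected), "
            f"{self.comparator} vs {self.reference}",
            "  quadrant shares (ΔQALY, Δcost): "
            + ", ".join(f"{q}={shares[q]:.3f}" for q in ("I", "II", "III", "IV")),
            f"  mean Δcost {self.deltas['delta_cost'].mean():.2f}, "
            f"mean ΔQALY {self.deltas['delta_qaly'].mean():.4f}",
        ]
        return "\n".join(lines)


def run_psa(
    model: CostEffectivenessModel,
    params: Sequence[ParamSpec],
    n_draws: int,
    seed: int = DEFAULT_SEED,
    reference: str | None = None,
    comparator: str | None = None,
) -> PSAResult:
    """Monte-Carlo propagation of parameter uncertainty through the model.

    Each draw samples every parameter (declaration order, draws as the
    outer loop from one seeded generator), re-runs the engine for every
    strategy and records comparator-minus-reference deltas.  Draws whose
    matrices fail validation are rejected and redrawn, up to 100×n_draws
    attempts.
    """
    if n_draws < 1:
        raise InvalidInputError("n_draws must be >= 1")
    base_results = model.evaluate()
    reference, comparator = _resolve_pair(base_results, reference, comparator)
    rng = np.random.default_rng(seed)

    cost_rows, qaly_rows, delta_rows = [], [], []
    rejected = 0
    attempts = 0
    while len(delta_rows) < n_draws:
        attempts += 1
        if attempts > 100 * n_draws:
            raise ModelError(
                f"PSA rejected too many draws ({rejected} of {attempts}); "
                "check the parameter distributions against the matrix constraints"
            )
        sampled = draw_parameters(model, params, rng)
        try:
            for s in sampled.strategies.values():
                markov.validate_matrix(s.transition, sampled.spec)
        except (markov.MatrixValidationError, ConfigurationError):
            rejected += 1
            continue
        results = sampled.evaluate()
        cost_rows.append({n: results[n].cost for n in results})
        qaly_rows.append({n: results[n].qaly for n in results})
        d_cost = results[comparator].cost - results[reference].cost
        d_qaly = results[comparator].qaly - results[reference].qaly
        quadrant, boundary = classify_quadrant(d_qaly, d_cost)
        delta_rows.append(
            {"delta_cost": d_cost, "delta_qaly": d_qaly, "quadrant": quadrant, "boundary": boundary}
        )

    return PSAResult(
        reference=reference,
        comparator=comparator,
        costs=pd.DataFrame(cost_rows),
        qalys=pd.DataFrame(qaly_rows),
        deltas=pd.DataFrame(delta_rows),
        base_results=base_results,
        n_rejected=rejected,
        seed=seed,
    )


def ceac(costs: pd.DataFrame, qalys: pd.DataFrame, wtp_grid: Sequence[float]) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves from PSA draws.

    At each willingness-to-pay value, each strategy's probability is the
    fraction of draws in which it attains the strictly highest net
    monetary benefit; exact ties split their weight equally, so the
    probabilities sum to 1 at every grid point.
    """
    grid = np.asarray(wtp_grid, dtype=float)
    if grid.size == 0:
        raise InvalidInputError("wtp_grid must contain at least one value")
    if (grid < 0).any():
        raise InvalidInputError("willingness-to-pay values must be >= 0")
    if costs.empty or qalys.empty:
        raise InvalidInputError("ceac requires at least one PSA draw")
    C = costs.to_numpy(dtype=float)
    Q = qalys.to_numpy(dtype=float)
    n_draws = C.shape[0]
    rows = []
    for wtp in grid:
        nmb = wtp * Q - C
        best = nmb.max(axis=1, keepdims=True)
        winners = nmb == best
        weights = winners / winners.sum(axis=1, keepdims=True)
        probs = weights.mean(axis=0)
        for s, p in zip(costs.columns, probs):
            rows.append({"wtp": float(wtp), "strategy": s, "probability": float(p)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# parameter-file I/O


def read_params(path) -> list[ParamSpec]:
    """Read a parameter CSV: ``name,target,base,low,high,distribution,mean,sd,concentration``."""
    df = pd.read_csv(path)
    required = {"name", "target", "base"}
    if not required.issubset(df.columns):
        raise ConfigurationError(f"parameter file missing columns {sorted(required - set(df.columns))}")

    def opt(row, key):
        if key not in df.columns:
            return None
        v = getattr(row, key)
        return None if pd.isna(v) else float(v)

    out = []
    for row in df.itertuples(index=False):
        dist = getattr(row, "distribution", "fixed")
        out.append(
            ParamSpec(
                name=str(row.name),
                target=str(row.target),
                base=float(row.base),
                low=opt(row, "low"),
                high=opt(row, "high"),
                distribution="fixed" if pd.isna(dist) else str(dist),
                mean=opt(row, "mean"),
                sd=opt(row, "sd"),
                concentration=opt(row, "concentration"),
            )
        )
    return out


def params_frame(params: Sequence[ParamSpec]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "name": p.name,
                "target": p.target,
                "base": p.base,
                "low": p.low,
                "high": p.high,
                "distribution": p.distribution,
                "mean": p.mean,
                "sd": p.sd,
                "concentration": p.concentration,
            }
            for p in params
        ]
    )
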