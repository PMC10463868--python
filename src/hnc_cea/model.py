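"""Model/Results facade over the Markov engine and the CEA ranking.

:class:`CostEffectivenessModel` bundles one shared Markov structure
(:class:`~hnc_cea.markov.ModelSpec`) with fully independent per-strategy
inputs — a transition matrix, state payoffs, and an optional upfront
(cycle-0) cost.  ``fit()`` runs the cohort for every strategy and returns
a :class:`CEAResults` carrying per-strategy discounted totals, the
dominance ranking, cohort traces and a printable summary.  Sensitivity
analyses (tornado, probabilistic) hang off the model, like ``simulate``
on a statsmodels model.

Example
-------
>>> from hnc_cea.synthetic import gen_calibrated_fixture
>>> res = gen_calibrated_fixture().model.fit()
>>> print(res.summary())        # doctest: +SKIP
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import markov, ranking
from .exceptions import ConfigurationError, InvalidInputError
from .markov import CohortTrace, ModelSpec, StatePayoffs, TransitionMatrix
from .ranking import RankingRow, StrategyResult


@dataclass
class Strategy:
    """One treatment strategy: its transition dynamics and payoffs."""

    name: str
    transition: TransitionMatrix
    payoffs: StatePayoffs
    upfront_cost: float = 0.0

    def __post_init__(self) -> None:
        if self.upfront_cost < 0:
            raise InvalidInputError("upfront_cost must be >= 0")


class CostEffectivenessModel:
    """A multi-strategy Markov cohort cost-effectiveness model.

    Parameters
    ----------
    spec
        Shared state structure and run controls.
    strategies
        Strategies to compare; each is validated against the spec at
        construction.  Strategies are fully independent model instances —
        no parameters are shared unless the caller shares objects.
    """

    def __init__(self, spec: ModelSpec, strategies: Sequence[Strategy]):
        if not strategies:
            raise InvalidInputError("at least one strategy is required")
        names = [s.name for s in strategies]
        if len(set(names)) != len(names):
            raise InvalidInputError("strategy names must be distinct")
        self.spec = spec
        self.strategies: dict[str, Strategy] = {s.name: s for s in strategies}
        for s in strategies:
            markov.validate_matrix(s.transition, spec)
            s.payoffs.vectors(spec)  # raises on unknown state names

    # -- construction -------------------------------------------------

    @classmethod
    def from_config(cls, source) -> "CostEffectivenessModel":
        """Build from a YAML/JSON file path or an equivalent mapping.

        Expected keys: ``states`` (list of ``{name, absorbing,
        lost_to_follow_up}``), ``cycle_length_years``, ``n_cycles``,
        ``discount_rate``, ``half_cycle``, ``initial_distribution``,
        optional ``cohort_death_prob``, and ``strategies`` mapping each
        name to ``transition_matrix`` (row-major), ``state_costs``,
        ``state_utilities`` and optional ``upfront_cost``.
        """
        if isinstance(source, (str, Path)):
            with open(source) as fh:
                cfg = yaml.safe_load(fh)
        else:
            cfg = dict(source)
        try:
            states = tuple(
                markov.HealthState(
                    name=s["name"],
                    absorbing=bool(s.get("absorbing", False)),
                    lost_to_follow_up=bool(s.get("lost_to_follow_up", False)),
                )
                for s in cfg["states"]
            )
            spec = ModelSpec(
                states=states,
                cycle_length_years=float(cfg.get("cycle_length_years", 0.25)),
                n_cycles=int(cfg.get("n_cycles", 20)),
                discount_rate_annual=float(cfg.get("discount_rate", 0.03)),
                half_cycle_correction=bool(cfg.get("half_cycle", False)),
                initial_distribution=cfg.get("initial_distribution"),
                cohort_death_prob=cfg.get("cohort_death_prob"),
            )
            strategies = []
            for name, s in cfg["strategies"].items():
                strategies.append(
                    Strategy(
                        name=str(name),
                        transition=TransitionMatrix(str(name), np.asarray(s["transition_matrix"], dtype=float)),
                        payoffs=StatePayoffs(
                            utility_per_year=dict(s.get("state_utilities", {})),
                            cost_per_cycle=dict(s.get("state_costs", {})),
                        ),
                        upfront_cost=float(s.get("upfront_cost", 0.0)),
                    )
                )
        except (KeyError, TypeError) as exc:
            raise ConfigurationError(f"malformed model config: {exc!r}") from exc
        return cls(spec, strategies)

    def to_config(self) -> dict:
        """Round-trippable plain-dict form of the model (for YAML output)."""
        return {
            "states": [
                {"name": s.name, "absorbing": s.absorbing, "lost_to_follow_up": s.lost_to_follow_up}
                for s in self.spec.states
            ],
            "cycle_length_years": self.spec.cycle_length_years,
            "n_cycles": self.spec.n_cycles,
            "discount_rate": self.spec.discount_rate_annual,
            "half_cycle": self.spec.half_cycle_correction,
            "initial_distribution": [float(x) for x in self.spec.initial_distribution],
            "cohort_death_prob": self.spec.cohort_death_prob,
            "strategies": {
                s.name: {
                    "transition_matrix": s.transition.entries.tolist(),
                    "state_utilities": dict(s.payoffs.utility_per_year),
                    "state_costs": dict(s.payoffs.cost_per_cycle),
                    "upfront_cost": s.upfront_cost,
                }
                for s in self.strategies.values()
            },
        }

    def copy(self) -> "CostEffectivenessModel":
        """Independent deep copy (used by the sensitivity analyses)."""
        return copy.deepcopy(self)

    # -- evaluation ----------------------------------------------------

    def trace(self, name: str) -> CohortTrace:
        try:
            s = self.strategies[name]
        except KeyError:
            raise InvalidInputError(f"unknown strategy {name!r}") from None
        return markov.run_cohort(self.spec, s.transition)

    def evaluate(self) -> dict[str, StrategyResult]:
        """Discounted (cost, QALY) per strategy, upfront costs included."""
        out: dict[str, StrategyResult] = {}
        for s in self.strategies.values():
            trace = markov.run_cohort(self.spec, s.transition)
            cost, qaly = markov.expected_outcomes(trace, s.payoffs, self.spec)
            out[s.name] = StrategyResult(name=s.name, cost=cost + s.upfront_cost, qaly=qaly)
        return out

    def fit(self) -> "CEAResults":
        """Run all strategies and rank them; returns the results object."""
        results = self.evaluate()
        rows = ranking.rank_strategies(results.values())
        traces = {name: self.trace(name) for name in self.strategies}
        return CEAResults(model=self, strategy_results=results, ranking=rows, traces=traces)

    # -- sensitivity (delegates; see hnc_cea.sensitivity) --------------

    def tornado(self, params, outcome: str = "icer", wtp: float | None = None,
                reference: str | None = None, comparator: str | None = None) -> pd.DataFrame:
        from . import sensitivity

        bars = [
            sensitivity.one_way(self, p, outcome=outcome, wtp=wtp,
                                reference=reference, comparator=comparator)
            for p in params
        ]
        ordered = sensitivity.tornado(bars)
        return pd.DataFrame(
            [
                {"param": b.name, "outcome_low": b.outcome_at_low,
                 "outcome_high": b.outcome_at_high, "swing": b.swing}
                for b in ordered
            ]
        )

    def psa(self, params, n_draws: int, seed: int,
            reference: str | None = None, comparator: str | None = None):
        from . import sensitivity

        return sensitivity.run_psa(self, params, n_draws=n_draws, seed=seed,
                                   reference=reference, comparator=comparator)


@dataclass
class CEAResults:
    """Base-case results: per-strategy totals, ranking and traces."""

    model: CostEffectivenessModel
    strategy_results: dict[str, StrategyResult]
    ranking: list[RankingRow]
    traces: dict[str, CohortTrace] = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        """Cost-effectiveness ranking table (ascending cost)."""
        return ranking.ranking_frame(self.ranking)

    def ce_plane(self) -> pd.DataFrame:
        """Scatter data for a cost-effectiveness plane (one point per strategy)."""
        return pd.DataFrame(
            [{"strategy": r.name, "qaly": r.qaly, "cost": r.cost} for r in self.strategy_results.values()]
        )

    def summary(self) -> str:
        """Printable ranking table plus run controls."""
        spec = self.model.spec
        head = (
            "Cost-effectiveness analysis\n"
            f"  strategies: {', '.join(self.strategy_results)}\n"
            f"  states: {', '.join(spec.state_names)}\n"
            f"  horizon: {spec.n_cycles} cycles x {spec.cycle_length_years} y "
            f"= {spec.horizon_years:g} y; discount {spec.discount_rate_annual:.1%}/y; "
            f"half-cycle correction {'on' if spec.half_cycle_correction else 'off'}\n"
        )
        return head + self.table().to_string(index=False, na_rep="")
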