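"""Incremental cost-effectiveness ranking with strict and extended dominance.

Strategies are sorted by ascending cost; a strategy is *dominated* when
another costs no more and yields no fewer QALYs (strictly better in at
least one coordinate), and *extendedly dominated* when a convex blend of
two other strategies does the same — detected, as is standard, by
non-increasing ICERs along the cost-sorted frontier.  Survivors form the
efficient frontier and receive ICERs against the previous frontier
member; dominated rows keep their incremental cost/effect versus the
reference (lowest-cost) strategy but no ICER, since a negative ratio is
ambiguous between "dominant" and "dominated" and the categorical status
column carries that verdict instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .exceptions import InvalidInputError

REFERENCE = "reference"
NON_DOMINATED = "non-dominated"
DOMINATED = "dominated"
EXTENDEDLY_DOMINATED = "extendedly-dominated"


@dataclass(frozen=True)
class StrategyResult:
    """Total discounted (cost, QALY) for one strategy."""

    name: str
    cost: float
    qaly: float

    def __post_init__(self) -> None:
        if self.cost < 0:
            raise InvalidInputError(f"cost must be >= 0, got {self.cost!r}")
        if not (math.isfinite(self.cost) and math.isfinite(self.qaly)):
            raise InvalidInputError("cost and qaly must be finite")


@dataclass
class RankingRow:
    name: str
    cost: float
    qaly: float
    incremental_cost: Optional[float] = None
    incremental_effect: Optional[float] = None
    icer: Optional[float] = None
    status: str = NON_DOMINATED


def icer(a: StrategyResult, b: StrategyResult) -> Optional[float]:
    """(cost_b - cost_a) / (qaly_b - qaly_a); None when the QALY difference is 0."""
    d_effect = b.qaly - a.qaly
    if d_effect == 0.0:
        return None
    return (b.cost - a.cost) / d_effect


def net_monetary_benefit(r: StrategyResult, wtp: float) -> float:
    """NMB = WTP * QALY - cost at a willingness-to-pay threshold."""
    if wtp < 0:
        raise InvalidInputError(f"willingness-to-pay must be >= 0, got {wtp!r}")
    return wtp * r.qaly - r.cost


def _dominates(a: StrategyResult, b: StrategyResult) -> bool:
    """True when ``a`` weakly improves on ``b`` with at least one strict coordinate."""
    return (a.cost <= b.cost and a.qaly >= b.qaly) and (a.cost < b.cost or a.qaly > b.qaly)


def rank_strategies(results: Iterable[StrategyResult]) -> list[RankingRow]:
    """Cost-effectiveness ranking table (ascending cost).

    Returns one row per strategy with status reference / non-dominated /
    dominated / extendedly-dominated.  Frontier rows carry the ICER
    against the previous frontier member; all non-reference rows carry
    incremental cost/effect (dominated rows versus the reference).
    """
    results = list(results)
    if not results:
        raise InvalidInputError("rank_strategies requires at least one strategy")
    names = [r.name for r in results]
    if len(set(names)) != len(names):
        raise InvalidInputError("strategy names must be distinct")

    # ascending cost; equal costs ordered by descending QALY
    order = sorted(results, key=lambda r: (r.cost, -r.qaly))

    status = {r.name: NON_DOMINATED for r in order}
    for r in order:
        if any(_dominates(o, r) for o in order if o.name != r.name):
            status[r.name] = DOMINATED

    # extended dominance: drop frontier candidates whose ICER vs the previous
    # survivor exceeds the ICER to the next survivor; iterate to convergence
    changed = True
    while changed:
        changed = False
        frontier = [r for r in order if status[r.name] not in (DOMINATED, EXTENDEDLY_DOMINATED)]
        for k in range(1, len(frontier) - 1):
            prev_, cur, nxt = frontier[k - 1], frontier[k], frontier[k + 1]
            icer_in = icer(prev_, cur)
            icer_out = icer(cur, nxt)
            if icer_in is not None and icer_out is not None and icer_in > icer_out:
                status[cur.name] = EXTENDEDLY_DOMINATED
                changed = True
                break

    # the lowest-cost strategy (highest QALY among ties) can never be dominated
    reference = order[0]
    status[reference.name] = REFERENCE
    rows: list[RankingRow] = []
    prev_frontier: Optional[StrategyResult] = None
    for r in order:
        row = RankingRow(name=r.name, cost=r.cost, qaly=r.qaly, status=status[r.name])
        if status[r.name] == REFERENCE:
            prev_frontier = r
        elif status[r.name] in (DOMINATED, EXTENDEDLY_DOMINATED):
            row.incremental_cost = r.cost - reference.cost
            row.incremental_effect = r.qaly - reference.qaly
        else:
            assert prev_frontier is not None
            row.incremental_cost = r.cost - prev_frontier.cost
            row.incremental_effect = r.qaly - prev_frontier.qaly
            row.icer = icer(prev_frontier, r)
            prev_frontier = r
        rows.append(row)
    return rows


def ranking_frame(rows: Sequence[RankingRow]) -> pd.DataFrame:
    """Ranking as a cost-effectiveness table (costs/QALYs/ICER to 2 decimals)."""
    def r2(x: Optional[float]) -> float:
        return float("nan") if x is None else round(x, 2)

    return pd.DataFrame(
        [
            {
                "strategy": r.name,
                "effectiveness": r2(r.qaly),
                "incremental_effectiveness": r2(r.incremental_effect),
                "cost": r2(r.cost),
                "incremental_cost": r2(r.incremental_cost),
                "icer": r2(r.icer),
                "dominance": r.status,
            }
            for r in rows
        ]
    )
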