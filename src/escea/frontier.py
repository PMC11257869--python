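"""Incremental cost-effectiveness ratios, dominance classification and the
efficiency frontier.

The stepwise comparison follows the conventional league-table procedure:
strategies are sorted by ascending cost and compared each to its previous
alternative.  A strategy that is costlier yet no more effective than its
predecessor is (strictly) dominated; a strategy whose sequential ICER
exceeds that of the next alternative is extended dominated.  Dominated and
extended-dominated strategies are removed and the comparison repeated until
the sequential ICERs along the surviving strategies are strictly
increasing — the efficiency frontier (equivalently, the upper-left convex
hull of the cost/QALY scatter).  Every comparison pass is retained so the
full stepwise table can be exported.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

from .economics import CEResult

__all__ = ["icer", "nmb", "frontier", "FrontierEntry", "FrontierResult"]

logger = logging.getLogger(__name__)

FRONTIER = "frontier"
DOMINATED = "dominated"
EXTENDED_DOMINATED = "extended_dominated"


def icer(a: CEResult, b: CEResult) -> float:
    """Incremental cost-effectiveness ratio of a versus b, USD/QALY.

    Sign is preserved (a costlier but less effective comparison yields a
    negative ratio, reported verbatim but never interpreted as
    cost-effective).  Equal effectiveness has no meaningful ratio and is a
    dominance case, so it raises.
    """
    dq = a.total_qalys - b.total_qalys
    dc = a.total_cost - b.total_cost
    if dq == 0.0:
        raise ValueError(
            f"equal QALYs for {a.strategy!r} and {b.strategy!r}: "
            "resolve by cost dominance, not a ratio"
        )
    return dc / dq


def nmb(r: CEResult, wtp: float) -> float:
    """Net monetary benefit wtp * QALYs - cost."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be non-negative")
    return wtp * r.total_qalys - r.total_cost


@dataclass
class FrontierEntry:
    strategy: str
    cost: float
    qalys: float
    status: str = FRONTIER
    removed_in_pass: int | None = None
    sequential_icer: float | None = None  # vs previous frontier strategy
    icer_vs_reference: float | None = None  # vs the cheapest strategy


@dataclass
class FrontierResult:
    """Dominance-classified strategies in ascending-cost order plus the
    per-pass stepwise tables."""

    entries: list[FrontierEntry]
    passes: list[list[dict]] = field(default_factory=list)
    reference: str = ""

    @property
    def frontier_strategies(self) -> list[str]:
        return [e.strategy for e in self.entries if e.status == FRONTIER]

    def entry(self, strategy: str) -> FrontierEntry:
        for e in self.entries:
            if e.strategy == strategy:
                return e
        raise KeyError(strategy)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "strategy": e.strategy,
                    "cost": e.cost,
                    "qalys": e.qalys,
                    "status": e.status,
                    "removed_in_pass": e.removed_in_pass,
                    "sequential_icer": e.sequential_icer,
                    "icer_vs_reference": e.icer_vs_reference,
                }
                for e in self.entries
            ]
        )

    def passes_frame(self):
        import pandas as pd

        rows = []
        for i, tab in enumerate(self.passes, start=1):
            for row in tab:
                rows.append({"pass": i, **row})
        return pd.DataFrame(rows)


def _stepwise_pass(rows: list[FrontierEntry]) -> list[dict]:
    """One pass of the stepwise comparison over ascending-cost rows.

    Marks strict dominance (non-positive incremental QALYs at higher cost vs
    the previous row) and extended dominance (sequential ICER above the next
    row's).  Returns the table of the pass; marks are set on the entries.
    """
    table: list[dict] = []
    inc_q: list[float | None] = [None]
    seq_icer: list[float | None] = [None]
    for i in range(1, len(rows)):
        prev, cur = rows[i - 1], rows[i]
        dc = cur.cost - prev.cost
        dq = cur.qalys - prev.qalys
        inc_q.append(dq)
        seq_icer.append(dc / dq if dq != 0.0 else math.inf)
    flags = [""] * len(rows)
    for i in range(1, len(rows)):
        # after ascending-cost sorting dc >= 0, so non-positive incremental
        # QALYs means dominance (duplicates resolve against the earlier name)
        if inc_q[i] <= 0:
            flags[i] = "D"
    for i in range(1, len(rows) - 1):
        if flags[i]:
            continue
        nxt = i + 1
        if flags[nxt]:
            continue  # next row has no valid ICER (dominated)
        if inc_q[i] > 0 and inc_q[nxt] > 0 and seq_icer[i] > seq_icer[nxt]:
            flags[i] = "ED"
    for i, row in enumerate(rows):
        table.append(
            {
                "strategy": row.strategy,
                "cost": row.cost,
                "qalys": row.qalys,
                "incremental_cost": None if i == 0 else rows[i].cost - rows[i - 1].cost,
                "incremental_qalys": inc_q[i],
                "sequential_icer": seq_icer[i],
                "flag": flags[i],
            }
        )
    for row, flag in zip(rows, flags):
        row.status = {"D": DOMINATED, "ED": EXTENDED_DOMINATED, "": FRONTIER}[flag]
    return table


def frontier(results: Sequence[CEResult]) -> FrontierResult:
    """Stepwise dominance classification of two or more strategies.

    Iterates comparison passes, removing dominated and extended-dominated
    strategies each round, until sequential ICERs strictly increase along
    the survivors.  The cheapest strategy is always on the frontier and is
    the reference for the pairwise ICER column.
    """
    if len(results) < 2:
        raise ValueError("need at least 2 strategies")
    names = [r.strategy for r in results]
    if len(set(names)) != len(names):
        raise ValueError("strategy names must be unique")
    entries = [
        FrontierEntry(strategy=r.strategy, cost=r.total_cost, qalys=r.total_qalys)
        for r in results
    ]
    # ascending cost; equal-cost ties put the more effective first, then by
    # name (logged) so duplicates resolve deterministically
    entries.sort(key=lambda e: (e.cost, -e.qalys, e.strategy))
    for a, b in zip(entries, entries[1:]):
        if a.cost == b.cost and a.qalys == b.qalys:
            logger.warning(
                "identical (cost, QALY) for %s and %s; tie broken by name",
                a.strategy, b.strategy,
            )

    reference = entries[0]
    for e in entries[1:]:
        if e.qalys != reference.qalys:
            e.icer_vs_reference = (e.cost - reference.cost) / (e.qalys - reference.qalys)

    passes: list[list[dict]] = []
    active = list(entries)
    for pass_no in range(1, len(entries) + 1):
        table = _stepwise_pass(active)
        passes.append(table)
        removed = [e for e in active if e.status != FRONTIER]
        if not removed:
            break
        for e in removed:
            e.removed_in_pass = pass_no
        active = [e for e in active if e.status == FRONTIER]
    # final sequential ICERs along the frontier
    for prev, cur in zip(active, active[1:]):
        cur.sequential_icer = (cur.cost - prev.cost) / (cur.qalys - prev.qalys)
    return FrontierResult(entries=entries, passes=passes, reference=reference.strategy)
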