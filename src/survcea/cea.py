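"""Decision analysis: dominance frontier, ICERs, and net monetary benefit.

Simple dominance only: a strategy is ruled out iff another strategy costs
no more and delivers no fewer QALYs, with at least one strict inequality.
Extended dominance is deliberately not applied; the willingness-to-pay
decision therefore maximises net monetary benefit over all non-dominated
strategies, which is the consistent rule when extended dominance is
skipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import ValidationError


@dataclass(frozen=True)
class StrategyOutcome:
    """Per-strategy expected cost (JPY) and effects (years)."""

    name: str
    cost: float
    qalys: float
    lys: float | None = None

    def __post_init__(self) -> None:
        if self.cost < 0:
            raise ValidationError(f"{self.name}: cost must be >= 0")
        if self.lys is not None and self.qalys > self.lys + 1e-9:
            raise ValidationError(f"{self.name}: QALYs cannot exceed LYs")


@dataclass(frozen=True)
class FrontierEntry:
    name: str
    cost: float
    qalys: float
    status: str  # "on_frontier" | "dominated"
    icer: float | None  # vs previous frontier entry; None for the cheapest


@dataclass(frozen=True)
class FrontierTable:
    """Outcomes sorted by cost with dominance status and pairwise ICERs."""

    entries: tuple[FrontierEntry, ...]

    def frontier(self) -> tuple[FrontierEntry, ...]:
        return tuple(e for e in self.entries if e.status == "on_frontier")

    def dominated_names(self) -> set[str]:
        return {e.name for e in self.entries if e.status == "dominated"}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "strategy": e.name,
                    "cost_jpy": e.cost,
                    "qalys": e.qalys,
                    "status": e.status,
                    "icer_jpy_per_qaly": e.icer,
                }
                for e in self.entries
            ]
        )


def icer(a: StrategyOutcome, b: StrategyOutcome) -> float | None:
    """Incremental cost per QALY of ``b`` over ``a``; None when QALYs tie."""
    dq = b.qalys - a.qalys
    if dq == 0.0:
        return None
    return (b.cost - a.cost) / dq


def simple_dominance(outcomes: Sequence[StrategyOutcome]) -> FrontierTable:
    """Classify strategies by simple dominance and ladder ICERs up the frontier."""
    if not outcomes:
        raise ValidationError("need at least one strategy outcome")
    names = [o.name for o in outcomes]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate strategy names")
    dominated: set[str] = set()
    for o in outcomes:
        for other in outcomes:
            if other.name == o.name:
                continue
            if (
                other.cost <= o.cost
                and other.qalys >= o.qalys
                and (other.cost < o.cost or other.qalys > o.qalys)
            ):
                dominated.add(o.name)
                break
    ordered = sorted(outcomes, key=lambda o: (o.cost, o.qalys, o.name))
    entries: list[FrontierEntry] = []
    prev_frontier: StrategyOutcome | None = None
    for o in ordered:
        if o.name in dominated:
            entries.append(FrontierEntry(o.name, o.cost, o.qalys, "dominated", None))
            continue
        value = icer(prev_frontier, o) if prev_frontier is not None else None
        entries.append(FrontierEntry(o.name, o.cost, o.qalys, "on_frontier", value))
        prev_frontier = o
    return FrontierTable(tuple(entries))


def net_monetary_benefit(outcome: StrategyOutcome, wtp: float) -> float:
    """``wtp * QALYs - cost`` (JPY)."""
    if wtp < 0:
        raise ValidationError("willingness-to-pay must be >= 0")
    return wtp * outcome.qalys - outcome.cost


def optimal_at_wtp(outcomes: Sequence[StrategyOutcome], wtp: float) -> str:
    """Strategy with the highest net monetary benefit at this threshold.

    Ties break toward lower cost, then lexicographic name — deterministic.
    """
    if not outcomes:
        raise ValidationError("need at least one strategy outcome")
    return min(
        outcomes,
        key=lambda o: (-net_monetary_benefit(o, wtp), o.cost, o.name),
    ).name
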