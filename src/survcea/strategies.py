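"""Surveillance schedules as data.

A strategy is a named mapping from months since the surveillance clock was
last reset (surgery, or re-resection of a recurrence) to the set of
examinations performed at that visit.  Schedules are pure configuration:
the six bundled guideline programmes live in ``data/strategies/*.yaml`` and
engine correctness never depends on any particular transcription.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .errors import ValidationError

EXAM_NAMES = ("clinical_evaluation", "laboratory", "cect", "colonoscopy")

#: Order in which the six bundled programmes are conventionally reported.
BUNDLED_STRATEGY_NAMES = ("asco", "ascrs", "nccn", "esmo", "jsccr", "strategy6")


@dataclass(frozen=True)
class Examination:
    """One examination type: a cost (JPY) and, where applicable, a
    sensitivity for detecting distant (liver/lung) recurrence.

    Colonoscopy carries a cost but no distant-recurrence sensitivity: it
    contributes to visit cost, not to detection.
    """

    name: str
    cost: float
    sensitivity: float | None = None

    def __post_init__(self) -> None:
        if self.name not in EXAM_NAMES:
            raise ValidationError(f"unknown examination {self.name!r}")
        if self.cost < 0:
            raise ValidationError(f"{self.name}: cost must be >= 0")
        if self.sensitivity is not None and not (0.0 <= self.sensitivity <= 1.0):
            raise ValidationError(f"{self.name}: sensitivity outside [0, 1]")


@dataclass(frozen=True)
class SurveillanceStrategy:
    """Named schedule: month-since-clock-reset -> examinations due."""

    name: str
    visits: Mapping[int, frozenset[str]]
    duration: int = 60

    def __post_init__(self) -> None:
        if self.duration < 1:
            raise ValidationError("duration must be >= 1 month")
        for month, exams in self.visits.items():
            if not (1 <= int(month) <= self.duration):
                raise ValidationError(
                    f"{self.name}: visit month {month} outside [1, {self.duration}]"
                )
            for exam in exams:
                if exam not in EXAM_NAMES:
                    raise ValidationError(f"{self.name}: unknown examination {exam!r}")

    def months_with_visits(self) -> list[int]:
        return sorted(int(m) for m in self.visits)


def tests_due(strategy: SurveillanceStrategy, months_since_reset: int) -> frozenset[str]:
    """Examinations scheduled at this clock value; empty beyond ``duration``."""
    if months_since_reset < 0:
        raise ValidationError("months_since_reset must be >= 0")
    if months_since_reset > strategy.duration:
        return frozenset()
    return frozenset(strategy.visits.get(int(months_since_reset), frozenset()))


def visit_cost(exams: Iterable[Examination]) -> float:
    """Total cost (JPY) of one visit's examinations."""
    return float(sum(e.cost for e in exams))


def load_strategy(config_text: str | Mapping) -> SurveillanceStrategy:
    """Parse and validate one strategy from YAML text (or a parsed mapping).

    Expected keys: ``name``, ``duration_months`` (default 60) and
    ``visits`` mapping month -> list of examination names.  Duplicate month
    entries (e.g. the same month given as int and string) are merged with a
    warning.
    """
    raw = yaml.safe_load(config_text) if isinstance(config_text, str) else dict(config_text)
    if not isinstance(raw, Mapping) or "name" not in raw:
        raise ValidationError("strategy config must be a mapping with a 'name'")
    duration = int(raw.get("duration_months", 60))
    visits: dict[int, frozenset[str]] = {}
    for month, exams in (raw.get("visits") or {}).items():
        try:
            m = int(month)
        except (TypeError, ValueError):
            raise ValidationError(f"visit month {month!r} is not an integer") from None
        exams = frozenset(exams or [])
        if m in visits:
            warnings.warn(
                f"strategy {raw['name']!r}: duplicate entries for month {m}; merging",
                stacklevel=2,
            )
            exams |= visits[m]
        visits[m] = exams
    return SurveillanceStrategy(name=str(raw["name"]), visits=visits, duration=duration)


def load_strategy_file(path: str | Path) -> SurveillanceStrategy:
    return load_strategy(Path(path).read_text())


def load_strategies_dir(path: str | Path) -> dict[str, SurveillanceStrategy]:
    """Load every ``*.yaml`` strategy in a directory, keyed by name."""
    out: dict[str, SurveillanceStrategy] = {}
    files = sorted(Path(path).glob("*.yaml"))
    if not files:
        raise ValidationError(f"no strategy files (*.yaml) found in {path}")
    for f in files:
        s = load_strategy_file(f)
        if s.name in out:
            raise ValidationError(f"duplicate strategy name {s.name!r}")
        out[s.name] = s
    return out


def bundled_strategies() -> dict[str, SurveillanceStrategy]:
    """The six guideline programmes shipped with the package."""
    root = resources.files("survcea").joinpath("data/strategies")
    out: dict[str, SurveillanceStrategy] = {}
    for name in BUNDLED_STRATEGY_NAMES:
        out[name] = load_strategy(root.joinpath(f"{name}.yaml").read_text())
    return out
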