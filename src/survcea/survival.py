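"""Piecewise-exponential survival machinery behind the transition probabilities.

Transition inputs to the simulation are Kaplan-Meier survival summaries
reported at a handful of anchor times (12, 36 and 60 months after the
relevant clock start).  A hazard that is constant within each inter-anchor
segment is the weakest assumption that reproduces every anchor exactly, and
it yields the monthly per-cycle transition probabilities of the engine in
closed form:

    lambda_k = -ln(S_k / S_{k-1}) / (t_k - t_{k-1})

with the implicit anchor ``(0, 1)`` preceding all points.  Beyond the last
anchor the hazard follows a tail policy: ``"zero"`` (no further events, used
for recurrence endpoints once surveillance has ended) or ``"continue_last"``
(the last segment's hazard persists, used for mortality under chemotherapy).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .errors import ValidationError

TAIL_POLICIES = ("zero", "continue_last")


@dataclass(frozen=True)
class SurvivalAnchors:
    """Ordered ``(time in months, survival probability)`` summary points.

    Times are strictly increasing and positive; survival is non-increasing
    and in ``[0, 1]``.  A survival value of exactly zero is representable
    (a Kaplan-Meier estimate can reach zero) but is rejected downstream by
    :func:`fit_piecewise_exponential`, where it would imply an infinite
    hazard.
    """

    points: tuple[tuple[float, float], ...]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.points:
            raise ValidationError("anchor set must contain at least one point")
        prev_t, prev_s = 0.0, 1.0
        for t, s in self.points:
            if not (t > prev_t):
                raise ValidationError(
                    f"{self.label or 'anchors'}: times must be strictly increasing "
                    f"and positive (got {t} after {prev_t})"
                )
            if not (0.0 <= s <= 1.0):
                raise ValidationError(
                    f"{self.label or 'anchors'}: survival {s} outside [0, 1]"
                )
            if s > prev_s + 1e-12:
                raise ValidationError(
                    f"{self.label or 'anchors'}: survival must be non-increasing "
                    f"(got {s} after {prev_s})"
                )
            prev_t, prev_s = t, s

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.points], dtype=float)

    @property
    def survival(self) -> np.ndarray:
        return np.array([s for _, s in self.points], dtype=float)


@dataclass(frozen=True)
class PiecewiseHazard:
    """Per-month hazard, constant on segments ending at ``breakpoints``.

    ``rates[k]`` applies on ``(breakpoints[k-1], breakpoints[k]]`` (with an
    implicit left edge at 0).  The implied survival function is continuous
    and equals 1 at t = 0.
    """

    breakpoints: tuple[float, ...]
    rates: tuple[float, ...]
    tail_policy: str = "zero"

    def __post_init__(self) -> None:
        if len(self.breakpoints) != len(self.rates):
            raise ValidationError("need exactly one rate per segment")
        if any(r < 0 for r in self.rates):
            raise ValidationError("hazard rates must be non-negative")
        if any(b2 <= b1 for b1, b2 in zip(self.breakpoints, self.breakpoints[1:])):
            raise ValidationError("breakpoints must be strictly increasing")
        if self.breakpoints and self.breakpoints[0] <= 0:
            raise ValidationError("breakpoints must be positive")
        if self.tail_policy not in TAIL_POLICIES:
            raise ValidationError(f"unknown tail policy {self.tail_policy!r}")

    def cumulative_hazard(self, t) -> np.ndarray:
        """Integrated hazard at time(s) ``t`` (months)."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValidationError("time must be non-negative")
        edges = np.concatenate(([0.0], np.asarray(self.breakpoints, dtype=float)))
        rates = np.asarray(self.rates, dtype=float)
        out = np.zeros_like(t, dtype=float)
        for k, rate in enumerate(rates):
            lo, hi = edges[k], edges[k + 1]
            out += rate * np.clip(t - lo, 0.0, hi - lo)
        if self.tail_policy == "continue_last" and rates.size:
            out += rates[-1] * np.clip(t - edges[-1], 0.0, None)
        return out


def fit_piecewise_exponential(
    anchors: SurvivalAnchors, tail_policy: str = "zero"
) -> PiecewiseHazard:
    """Fit segment hazards that reproduce every anchor exactly.

    Raises :class:`ValidationError` for a zero survival anchor (infinite
    hazard) or non-monotone anchors (rejected at anchor construction).
    """
    times = anchors.times
    surv = anchors.survival
    if np.any(surv <= 0.0):
        raise ValidationError(
            f"{anchors.label or 'anchors'}: zero survival anchor implies an "
            "infinite hazard and cannot be fitted"
        )
    prev_t, prev_s = 0.0, 1.0
    rates = []
    for t, s in zip(times, surv):
        rates.append(-math.log(s / prev_s) / (t - prev_t))
        prev_t, prev_s = t, s
    return PiecewiseHazard(tuple(times), tuple(rates), tail_policy)


def survival_at(pw: PiecewiseHazard, t):
    """Survival probability at time(s) ``t`` months; S(0) = 1."""
    out = np.exp(-pw.cumulative_hazard(t))
    return float(out) if np.ndim(t) == 0 else out


def per_cycle_prob(pw: PiecewiseHazard, cycle_index: int) -> float:
    """Event probability during month ``cycle_index`` (1-based), conditional
    on being event-free at its start."""
    if cycle_index < 1:
        raise ValidationError("cycle_index must be >= 1")
    s0 = survival_at(pw, float(cycle_index - 1))
    s1 = survival_at(pw, float(cycle_index))
    if s0 <= 0.0:
        return 1.0
    return 1.0 - s1 / s0


def per_cycle_probs(pw: PiecewiseHazard, horizon: int) -> np.ndarray:
    """Vector of per-cycle probabilities, index ``t`` = month ``t``; index 0 is 0."""
    s = np.exp(-pw.cumulative_hazard(np.arange(horizon + 1, dtype=float)))
    out = np.zeros(horizon + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(s[:-1] > 0.0, s[1:] / s[:-1], 0.0)
    out[1:] = 1.0 - ratio
    return out


def cumulative_to_per_cycle(cum: float, n_cycles: int) -> float:
    """Per-cycle probability ``p`` with ``1 - (1-p)**n_cycles == cum``."""
    if not (0.0 <= cum < 1.0):
        raise ValidationError("cumulative probability must be in [0, 1)")
    if n_cycles < 1:
        raise ValidationError("n_cycles must be >= 1")
    return 1.0 - (1.0 - cum) ** (1.0 / n_cycles)


def _fit_km(event_times, event_flags) -> KaplanMeierFitter:
    times = np.asarray(event_times, dtype=float)
    flags = np.asarray(event_flags, dtype=bool)
    if times.size == 0:
        raise ValidationError("empty input to Kaplan-Meier estimator")
    if times.shape != flags.shape:
        raise ValidationError("event_times and event_flags must align")
    if np.any(times < 0):
        raise ValidationError("event times must be non-negative")
    return KaplanMeierFitter().fit(times, event_observed=flags)


def km_survival(event_times, event_flags, eval_times) -> np.ndarray:
    """Product-limit survival estimate at each evaluation time (0 maps to 1)."""
    kmf = _fit_km(event_times, event_flags)
    vals = kmf.survival_function_at_times(np.asarray(eval_times, dtype=float))
    return np.asarray(vals, dtype=float)


def km_estimate(
    event_times, event_flags, eval_times: Sequence[float], label: str = ""
) -> SurvivalAnchors:
    """Kaplan-Meier summary at positive evaluation times, as anchor points."""
    eval_times = [float(t) for t in eval_times]
    if any(t <= 0 for t in eval_times):
        raise ValidationError("anchor evaluation times must be positive")
    vals = km_survival(event_times, event_flags, eval_times)
    return SurvivalAnchors(tuple(zip(eval_times, vals)), label=label)


def greenwood_se(event_times, event_flags, eval_times) -> np.ndarray:
    """Greenwood standard error of the KM estimate at each evaluation time."""
    kmf = _fit_km(event_times, event_flags)
    table = kmf.event_table
    d = table["observed"].to_numpy(dtype=float)
    n = table["at_risk"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n > d, d / (n * (n - d)), 0.0)
    cum = pd.Series(np.cumsum(terms), index=table.index)
    eval_times = np.asarray(eval_times, dtype=float)
    s = km_survival(event_times, event_flags, eval_times)
    idx = np.searchsorted(cum.index.to_numpy(dtype=float), eval_times, side="right") - 1
    cum_at = np.where(idx >= 0, cum.to_numpy()[np.clip(idx, 0, None)], 0.0)
    return s * np.sqrt(cum_at)


def sample_event_times(
    pw: PiecewiseHazard, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw event times by inverting the cumulative hazard.

    Under a ``"zero"`` tail a draw may never experience the event; such
    entries are returned as ``np.inf``.
    """
    if n < 0:
        raise ValidationError("n must be non-negative")
    edges = np.concatenate(([0.0], np.asarray(pw.breakpoints, dtype=float)))
    rates = np.asarray(pw.rates, dtype=float)
    cum = np.concatenate(([0.0], np.cumsum(rates * np.diff(edges))))
    e = rng.exponential(size=n)
    t = np.full(n, np.inf)
    for k, rate in enumerate(rates):
        mask = (e > cum[k]) & (e <= cum[k + 1])
        if rate > 0:
            t[mask] = edges[k] + (e[mask] - cum[k]) / rate
    beyond = e > cum[-1]
    if pw.tail_policy == "continue_last" and rates.size and rates[-1] > 0:
        t[beyond] = edges[-1] + (e[beyond] - cum[-1]) / rates[-1]
    return t
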