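"""Probabilistic sensitivity analysis and cost-effectiveness acceptability curves.

Each outer draw resamples every uncertain parameter from its assigned
family — beta for probabilities (fitted from raw event counts where the
source data provide them, otherwise moment-matched to the base value with
the printed low/high bounds read as a central 95% interval) and gamma for
costs (mean at the base value, bounds of +/-25% read the same way).  The
model is re-run per draw for every strategy with common random numbers,
and the acceptability curve reports, per willingness-to-pay value, the
fraction of draws in which each strategy maximises net monetary benefit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _engine
from .cea import StrategyOutcome, optimal_at_wtp
from .detection import SensitivitySet
from .errors import ValidationError
from .microsim import N_PURPOSES, SimSettings, build_engine_inputs
from .params import CostSet, FixedRates, ParamSet, UtilitySet
from .strategies import SurveillanceStrategy
from .survival import SurvivalAnchors

_Z95 = 3.919927969080108  # width of a central 95% normal interval, in SDs


@dataclass(frozen=True)
class ParamDistribution:
    """One uncertain parameter: base value, bounds, and sampling family."""

    name: str
    base: float
    low: float | None = None
    high: float | None = None
    family: str = "fixed"
    events: float | None = None  # raw beta counts, when the source prints them
    total: float | None = None

    def __post_init__(self) -> None:
        if self.family not in ("beta", "gamma", "fixed"):
            raise ValidationError(f"{self.name}: unknown family {self.family!r}")
        if self.low is not None and self.high is not None:
            if not (self.low <= self.base <= self.high):
                raise ValidationError(
                    f"{self.name}: base {self.base} outside [{self.low}, {self.high}]"
                )


class Sampler:
    """Callable drawing one value per invocation from a fitted distribution."""

    def __init__(self, name: str, kind: str, a: float = 0.0, b: float = 0.0):
        self.name = name
        self.kind = kind
        self.a = a
        self.b = b

    def __call__(self, rng: np.random.Generator) -> float:
        if self.kind == "fixed":
            return self.a
        if self.kind == "beta":
            return float(rng.beta(self.a, self.b))
        return float(rng.gamma(self.a, self.b))  # shape, scale


def fit_distribution(dist: ParamDistribution, range_is_95ci: bool = True) -> Sampler:
    """Turn a parameter's (base, low, high, family) spec into a sampler.

    Beta uses raw counts when available, else moment matching; gamma is
    moment-matched to mean = base.  Raises on infeasible moments, naming
    the parameter.
    """
    if dist.family == "fixed":
        return Sampler(dist.name, "fixed", dist.base)
    if dist.family == "beta" and dist.events is not None and dist.total is not None:
        if not (0 < dist.events < dist.total):
            raise ValidationError(f"{dist.name}: infeasible beta counts")
        return Sampler(dist.name, "beta", dist.events, dist.total - dist.events)
    if dist.low is None or dist.high is None or dist.high <= dist.low:
        raise ValidationError(f"{dist.name}: need low < high bounds to moment-match")
    sd = (dist.high - dist.low) / (_Z95 if range_is_95ci else 2.0)
    m = dist.base
    if dist.family == "beta":
        if not (0.0 < m < 1.0):
            raise ValidationError(f"{dist.name}: beta mean must be inside (0, 1)")
        nu = m * (1.0 - m) / sd**2 - 1.0
        if nu <= 0:
            raise ValidationError(
                f"{dist.name}: bounds too wide for a beta with mean {m}"
            )
        return Sampler(dist.name, "beta", m * nu, (1.0 - m) * nu)
    # gamma
    if m <= 0:
        raise ValidationError(f"{dist.name}: gamma mean must be positive")
    shape = (m / sd) ** 2
    return Sampler(dist.name, "gamma", shape, sd**2 / m)


def _dist_from_entry(name: str, entry: Mapping, collapse: bool) -> ParamDistribution:
    family = "fixed" if collapse else entry.get("family", "fixed")
    if family == "complement":
        family = "fixed"  # handled jointly with its partner
    return ParamDistribution(
        name=name,
        base=float(entry["value"]),
        low=float(entry["low"]) if "low" in entry else None,
        high=float(entry["high"]) if "high" in entry else None,
        family=family,
        events=float(entry["events"]) if "events" in entry else None,
        total=float(entry["total"]) if "total" in entry else None,
    )


def _sample_anchor_block(
    name: str, block: Mapping, rng, range_is_95ci: bool, collapse: bool,
    max_tries: int = 1000,
) -> SurvivalAnchors:
    entries = block["anchors"]
    samplers = [
        fit_distribution(
            _dist_from_entry(f"{name}@{a['month']}", a, collapse), range_is_95ci
        )
        for a in entries
    ]
    months = [float(a["month"]) for a in entries]
    for _ in range(max_tries):
        vals = [s(rng) for s in samplers]
        if all(v2 <= v1 for v1, v2 in zip(vals, vals[1:])) and vals[0] <= 1.0:
            return SurvivalAnchors(tuple(zip(months, vals)), label=block.get("label", name))
    raise ValidationError(
        f"{name}: could not draw monotone survival anchors in {max_tries} tries"
    )


def sample_param_set(
    params: ParamSet,
    rng: np.random.Generator,
    range_is_95ci: bool = True,
    collapse: bool = False,
) -> ParamSet:
    """Draw one coherent parameter set for a PSA iteration.

    Survival anchors are resampled jointly with monotonicity enforced by
    rejection; the hepatectomy/pneumonectomy split keeps summing to one;
    ``theta`` (a calibrated structural constant) is carried unchanged.
    With ``collapse=True`` every family is treated as fixed and the base
    parameter set is returned value-for-value.
    """
    raw = params.raw
    if raw is None:
        raise ValidationError("ParamSet carries no distribution table (raw is None)")

    def draw(section: str, key: str) -> float:
        entry = raw[section][key]
        sampler = fit_distribution(_dist_from_entry(key, entry, collapse), range_is_95ci)
        return sampler(rng)

    anchors = {
        blk: _sample_anchor_block(blk, raw["survival"][blk], rng, range_is_95ci, collapse)
        for blk in ("rfs_primary", "rfs_post_resection", "os_chemo")
    }
    prop_hep = draw("rates", "prop_hepatectomy")
    if collapse:  # keep the printed base value bit-exact
        prop_pneu = float(raw["rates"]["prop_pneumonectomy"]["value"])
    else:
        prop_pneu = 1.0 - prop_hep
    rates = FixedRates(
        resection_rate_at_first_recurrence=draw(
            "rates", "resection_rate_at_first_recurrence"
        ),
        prop_hepatectomy=prop_hep,
        prop_pneumonectomy=prop_pneu,
        conversion_cum_5yr=draw("rates", "conversion_cum_5yr"),
    )
    costs = CostSet(**{k: draw("costs", k) for k in raw["costs"]})
    utilities = UtilitySet(
        no_evidence_of_disease=min(1.0, draw("utilities", "no_evidence_of_disease")),
        after_resection=min(1.0, draw("utilities", "after_resection")),
        under_chemotherapy=min(1.0, draw("utilities", "under_chemotherapy")),
    )
    sens = SensitivitySet(
        clinical_evaluation=min(1.0, draw("sensitivities", "clinical_evaluation")),
        laboratory=min(1.0, draw("sensitivities", "laboratory")),
        cect=min(1.0, draw("sensitivities", "cect")),
    )
    return params.replace(
        rfs_primary=anchors["rfs_primary"],
        rfs_post_resection=anchors["rfs_post_resection"],
        os_chemo=anchors["os_chemo"],
        rates=rates,
        costs=costs,
        utilities=utilities,
        sensitivities=sens,
    )


@dataclass(frozen=True)
class PSASettings:
    n_outer: int = 500
    n_inner: int = 10_000
    wtp_grid: tuple[float, ...] = tuple(np.arange(0, 10_000_001, 250_000.0))
    seed: int = 0
    range_is_95ci: bool = True
    collapse: bool = False
    horizon_cycles: int = 180
    surveillance_stop: int = 60
    discount_rate_annual: float = 0.02
    discount_lys: bool = True

    def __post_init__(self) -> None:
        if self.n_outer < 1 or self.n_inner < 1:
            raise ValidationError("n_outer and n_inner must be >= 1")


@dataclass(frozen=True)
class CEACCurve:
    """Probability each strategy is optimal, per willingness-to-pay value."""

    probabilities: pd.DataFrame  # index: WTP (JPY/QALY); columns: strategies
    n_outer: int
    seed: int

    def probability(self, strategy: str, wtp: float) -> float:
        return float(self.probabilities.loc[wtp, strategy])

    def modal_strategy(self, wtp: float) -> str:
        row = self.probabilities.loc[wtp]
        return str(row.sort_index().idxmax())  # lexicographic tie-break


@dataclass(frozen=True)
class PSAResult:
    ceac: CEACCurve
    outcomes: pd.DataFrame  # one row per (draw, strategy)


def run_psa(
    params: ParamSet,
    strategies: Mapping[str, SurveillanceStrategy],
    settings: PSASettings,
) -> PSAResult:
    """Outer parameter draws, inner microsimulation with common random numbers.

    One inner uniform draw array is generated per run and shared by every
    strategy and every outer draw (common random numbers): strategy
    contrasts are not confounded by Monte-Carlo noise, and collapsing all
    distributions to point masses reproduces the base-case decision
    exactly.
    """
    if not strategies:
        raise ValidationError("need at least one strategy")
    names = sorted(strategies)
    wtps = list(settings.wtp_grid)
    counts = pd.DataFrame(0.0, index=wtps, columns=names)
    rows = []
    ss = np.random.SeedSequence(settings.seed)
    sim_settings = SimSettings(
        n_trials=settings.n_inner,
        horizon_cycles=settings.horizon_cycles,
        surveillance_stop=settings.surveillance_stop,
        discount_rate_annual=settings.discount_rate_annual,
        discount_lys=settings.discount_lys,
        seed=0,
    )
    inner_ss, outer_ss = ss.spawn(2)
    draws = np.random.default_rng(inner_ss).random(
        (settings.n_inner, settings.horizon_cycles, N_PURPOSES)
    )
    for d, child in enumerate(outer_ss.spawn(settings.n_outer)):
        rng_param = np.random.default_rng(child)
        ps = sample_param_set(
            params, rng_param,
            range_is_95ci=settings.range_is_95ci, collapse=settings.collapse,
        )
        outcomes = []
        for name in names:
            inputs = build_engine_inputs(ps, strategies[name], sim_settings)
            cost, qaly, ly, _, _, _ = _engine.run_engine(inputs, draws)
            outcomes.append(
                StrategyOutcome(
                    name=name,
                    cost=float(cost.mean()),
                    qalys=float(qaly.mean()),
                    lys=float(ly.mean()),
                )
            )
            rows.append(
                {
                    "draw": d,
                    "strategy": name,
                    "cost_jpy": outcomes[-1].cost,
                    "qalys": outcomes[-1].qalys,
                    "lys": outcomes[-1].lys,
                }
            )
        for wtp in wtps:
            counts.loc[wtp, optimal_at_wtp(outcomes, wtp)] += 1.0
    probs = counts / settings.n_outer
    ceac = CEACCurve(probabilities=probs, n_outer=settings.n_outer, seed=settings.seed)
    return PSAResult(ceac=ceac, outcomes=pd.DataFrame(rows))
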