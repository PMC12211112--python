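"""Parameter file handling.

The model is fully specified by one YAML file: survival anchors for the
three time-to-event endpoints, fixed treatment rates, unit costs (JPY),
state utilities, examination sensitivities, simulation settings, and the
calibrated latent-progression rate ``theta``.  Every uncertain entry also
carries a range and a sampling family (beta or gamma) consumed by the
probabilistic sensitivity analysis.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

from .detection import SensitivitySet
from .errors import ValidationError
from .survival import SurvivalAnchors

SURVIVAL_BLOCKS = ("rfs_primary", "rfs_post_resection", "os_chemo")


@dataclass(frozen=True)
class FixedRates:
    """Treatment probabilities held fixed over time in the model."""

    resection_rate_at_first_recurrence: float = 0.38
    prop_hepatectomy: float = 0.70
    prop_pneumonectomy: float = 0.30
    conversion_cum_5yr: float = 0.192

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{f.name}={v} outside [0, 1]")
        if abs(self.prop_hepatectomy + self.prop_pneumonectomy - 1.0) > 1e-9:
            raise ValidationError("hepatectomy and pneumonectomy shares must sum to 1")


@dataclass(frozen=True)
class UtilitySet:
    """Quality-of-life weights per health state."""

    no_evidence_of_disease: float = 0.74
    after_resection: float = 0.74
    under_chemotherapy: float = 0.25
    death: float = 0.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"utility {f.name}={v} outside [0, 1]")


@dataclass(frozen=True)
class CostSet:
    """Unit costs in JPY."""

    clinical_evaluation: float = 0.0
    laboratory: float = 11_750.0
    cect: float = 38_190.0
    colonoscopy: float = 15_500.0
    hepatectomy: float = 1_950_000.0
    pneumonectomy: float = 1_477_000.0
    chemotherapy_per_month: float = 485_000.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ValidationError(f"cost {f.name} must be >= 0")

    def exam_cost(self, name: str) -> float:
        return float(getattr(self, name))


@dataclass(frozen=True)
class ParamSet:
    """Complete model parameterisation (base-case values plus PSA metadata).

    ``raw`` retains the parsed parameter file so the PSA can recover each
    entry's range and sampling family.
    """

    rfs_primary: SurvivalAnchors
    rfs_post_resection: SurvivalAnchors
    os_chemo: SurvivalAnchors
    tail_policies: Mapping[str, str]
    rates: FixedRates
    costs: CostSet
    utilities: UtilitySet
    sensitivities: SensitivitySet
    theta: float
    conversion_window_months: int = 60
    raw: Mapping | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta <= 1.0):
            raise ValidationError("theta must be in [0, 1]")

    def replace(self, **changes) -> "ParamSet":
        return dataclasses.replace(self, **changes)


def _anchors_from_block(name: str, block: Mapping) -> tuple[SurvivalAnchors, str]:
    try:
        pts = tuple(
            (float(a["month"]), float(a["value"])) for a in block["anchors"]
        )
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"survival block {name!r} malformed: {exc}") from exc
    anchors = SurvivalAnchors(pts, label=block.get("label", name))
    tail = block.get("tail_policy", "zero")
    return anchors, tail


def params_from_dict(raw: Mapping) -> ParamSet:
    """Build and validate a :class:`ParamSet` from a parsed parameter file."""
    try:
        surv = raw["survival"]
        rates_raw = raw["rates"]
        costs_raw = raw["costs"]
        util_raw = raw["utilities"]
        sens_raw = raw["sensitivities"]
    except KeyError as exc:
        raise ValidationError(f"parameter file missing section {exc}") from exc

    anchors: dict[str, SurvivalAnchors] = {}
    tails: dict[str, str] = {}
    for name in SURVIVAL_BLOCKS:
        if name not in surv:
            raise ValidationError(f"parameter file missing survival block {name!r}")
        anchors[name], tails[name] = _anchors_from_block(name, surv[name])

    def value(section: Mapping, key: str) -> float:
        try:
            return float(section[key]["value"])
        except (KeyError, TypeError) as exc:
            raise ValidationError(f"parameter {key!r} malformed or missing") from exc

    rates = FixedRates(
        resection_rate_at_first_recurrence=value(
            rates_raw, "resection_rate_at_first_recurrence"
        ),
        prop_hepatectomy=value(rates_raw, "prop_hepatectomy"),
        prop_pneumonectomy=value(rates_raw, "prop_pneumonectomy"),
        conversion_cum_5yr=value(rates_raw, "conversion_cum_5yr"),
    )
    costs = CostSet(**{k: value(costs_raw, k) for k in costs_raw})
    utilities = UtilitySet(
        no_evidence_of_disease=value(util_raw, "no_evidence_of_disease"),
        after_resection=value(util_raw, "after_resection"),
        under_chemotherapy=value(util_raw, "under_chemotherapy"),
    )
    sens = SensitivitySet(
        clinical_evaluation=value(sens_raw, "clinical_evaluation"),
        laboratory=value(sens_raw, "laboratory"),
        cect=value(sens_raw, "cect"),
    )
    theta = float(raw.get("calibration", {}).get("theta", 0.0))
    return ParamSet(
        rfs_primary=anchors["rfs_primary"],
        rfs_post_resection=anchors["rfs_post_resection"],
        os_chemo=anchors["os_chemo"],
        tail_policies=tails,
        rates=rates,
        costs=costs,
        utilities=utilities,
        sensitivities=sens,
        theta=theta,
        raw=raw,
    )


def load_params(path: str | Path | None = None) -> ParamSet:
    """Load a parameter file; ``None`` loads the bundled base-case file."""
    if path is None:
        text = resources.files("survcea").joinpath("data/params.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, Mapping):
        raise ValidationError("parameter file must parse to a mapping")
    return params_from_dict(raw)


def simulation_defaults(params: ParamSet) -> dict:
    """Simulation settings block from the parameter file (with defaults)."""
    sim = dict((params.raw or {}).get("simulation", {}))
    sim.setdefault("n_trials", 500_000)
    sim.setdefault("horizon_cycles", 180)
    sim.setdefault("surveillance_stop_cycles", 60)
    sim.setdefault("discount_rate_annual", 0.02)
    sim.setdefault("discount_life_years", True)
    sim.setdefault("jpy_per_usd", 150)
    sim.setdefault("wtp_low", 5_000_000)
    sim.setdefault("wtp_high", 6_000_000)
    return sim
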