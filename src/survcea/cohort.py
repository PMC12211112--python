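"""Synthetic patient-level cohorts for end-to-end testing of the pipeline.

The generator emulates the statistical structure of a single-centre cohort
of 119 patients resected with curative intent for colorectal cancer with
liver and/or lung metastases: recurrence times follow the fitted
piecewise-exponential recurrence hazard, resectability of a detected
recurrence is Bernoulli, chemotherapy survival follows the
overall-survival hazard, conversion-surgery times are exponential at the
rate matching the 19.2% five-year cumulative probability, and censoring is
administrative (uniform accrual over a 120-month window with a fixed
cutoff, giving a median follow-up near five years).  Demographics are
carried as inert labels only; no covariate enters the model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .params import ParamSet
from .survival import (
    SurvivalAnchors,
    fit_piecewise_exponential,
    km_estimate,
    sample_event_times,
)

DEFAULT_ACCRUAL_MONTHS = 120.0
ANCHOR_MONTHS = (12.0, 36.0, 60.0)


def generate_cohort(
    n: int,
    params: ParamSet,
    seed: int = 0,
    accrual_months: float = DEFAULT_ACCRUAL_MONTHS,
    censoring: bool = True,
) -> pd.DataFrame:
    """Draw ``n`` synthetic patients; reproducible given the seed.

    Columns: ``recurrence_time`` (months, inf if none),
    ``recurrence_resectable``, ``post_resection_recurrence_time``,
    ``death_time_under_chemo``, ``conversion_time``, ``censoring_time``,
    plus inert demographic labels (``age``, ``sex``, ``primary_site``).
    With ``censoring=False`` the censoring time is set beyond the horizon.
    """
    if n < 0:
        raise ValidationError("n must be >= 0")
    rng = np.random.default_rng(seed)
    pw_rec = fit_piecewise_exponential(
        params.rfs_primary, params.tail_policies.get("rfs_primary", "zero")
    )
    pw_rec2 = fit_piecewise_exponential(
        params.rfs_post_resection, params.tail_policies.get("rfs_post_resection", "zero")
    )
    pw_os = fit_piecewise_exponential(
        params.os_chemo, params.tail_policies.get("os_chemo", "continue_last")
    )
    recurrence = sample_event_times(pw_rec, n, rng)
    resectable = rng.random(n) < params.rates.resection_rate_at_first_recurrence
    post_rec = sample_event_times(pw_rec2, n, rng)
    death_chemo = sample_event_times(pw_os, n, rng)
    conv_rate = -math.log(1.0 - params.rates.conversion_cum_5yr) / float(
        params.conversion_window_months
    )
    conversion = rng.exponential(1.0 / conv_rate, size=n) if conv_rate > 0 else np.full(n, np.inf)
    if censoring:
        cens = rng.uniform(0.0, accrual_months, size=n)
    else:
        cens = np.full(n, 10_000.0)
    age = np.clip(rng.normal(60.8, 11.8, size=n), 18.0, 95.0).round(1)
    sex = np.where(rng.random(n) < 0.58, "male", "female")
    site = np.where(rng.random(n) < 0.613, "colon", "rectum")
    return pd.DataFrame(
        {
            "recurrence_time": recurrence,
            "recurrence_resectable": resectable,
            "post_resection_recurrence_time": post_rec,
            "death_time_under_chemo": death_chemo,
            "conversion_time": conversion,
            "censoring_time": cens,
            "age": age,
            "sex": sex,
            "primary_site": site,
        }
    )


@dataclass(frozen=True)
class DerivedSurvival:
    """KM-derived anchor blocks in the parameter-file schema; a block is
    ``None`` when its endpoint has no events in the cohort."""

    rfs_primary: SurvivalAnchors | None
    rfs_post_resection: SurvivalAnchors | None
    os_chemo: SurvivalAnchors | None

    def as_param_fragment(self) -> dict:
        out: dict = {"survival": {}}
        tails = {"rfs_primary": "zero", "rfs_post_resection": "zero",
                 "os_chemo": "continue_last"}
        for name in ("rfs_primary", "rfs_post_resection", "os_chemo"):
            anchors = getattr(self, name)
            if anchors is None:
                out["survival"][name] = None
                continue
            out["survival"][name] = {
                "label": anchors.label,
                "tail_policy": tails[name],
                "anchors": [
                    {"month": float(t), "value": float(s)} for t, s in anchors.points
                ],
            }
        return out


def _km_block(durations, events, label) -> SurvivalAnchors | None:
    if len(durations) == 0 or not np.any(events):
        return None
    return km_estimate(durations, events, ANCHOR_MONTHS, label=label)


def derive_params(cohort: pd.DataFrame) -> DerivedSurvival:
    """Kaplan-Meier anchor estimates (12/36/60 months) per endpoint.

    Mirrors how the model's transition inputs are derived from patient
    records: recurrence-free survival from curative resection over the
    whole cohort; recurrence-free survival after re-resection among
    resected recurrences; overall survival from chemotherapy start among
    unresectable recurrences.
    """
    if cohort.empty:
        raise ValidationError("cohort is empty")
    rec = cohort["recurrence_time"].to_numpy(dtype=float)
    cens = cohort["censoring_time"].to_numpy(dtype=float)
    observed = rec <= cens
    rfs_primary = _km_block(
        np.minimum(rec, cens), observed, "RFS after curative resection (derived)"
    )
    resected = observed & cohort["recurrence_resectable"].to_numpy(dtype=bool)
    remaining = cens - rec
    post = cohort["post_resection_recurrence_time"].to_numpy(dtype=float)
    rfs_post = _km_block(
        np.minimum(post[resected], remaining[resected]),
        post[resected] <= remaining[resected],
        "RFS after resection of recurrence (derived)",
    )
    chemo = observed & ~cohort["recurrence_resectable"].to_numpy(dtype=bool)
    death = cohort["death_time_under_chemo"].to_numpy(dtype=float)
    os_chemo = _km_block(
        np.minimum(death[chemo], remaining[chemo]),
        death[chemo] <= remaining[chemo],
        "OS after induction of chemotherapy (derived)",
    )
    return DerivedSurvival(rfs_primary, rfs_post, os_chemo)
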