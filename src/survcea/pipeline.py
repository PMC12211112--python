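"""Reproducible end-to-end runs: base case, frontier, optional PSA, manifest.

Outputs are plain CSV (tables) and JSON (manifest).  Given identical
configuration and seed, the CSV outputs are byte-identical across runs;
the manifest records the tool version, input hashes, seeds and settings
needed to reproduce every number.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from . import __version__
from .cea import StrategyOutcome, simple_dominance
from .errors import ValidationError
from .microsim import SimSettings, simulate_cohort
from .params import ParamSet, load_params, simulation_defaults
from .psa import PSASettings, run_psa
from .strategies import bundled_strategies, load_strategies_dir


def format_currency(jpy: float, jpy_per_usd: float = 150.0) -> dict:
    """Report a JPY amount alongside USD at the fixed conversion rate."""
    if not np.isfinite(jpy):
        raise ValidationError("currency value must be finite")
    return {"jpy": float(jpy), "usd": round(jpy / jpy_per_usd)}


def _sha256(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()


def _resolve_inputs(config: Mapping):
    params_path = config.get("params")
    params = load_params(params_path)
    strategies_dir = config.get("strategies_dir")
    if strategies_dir:
        strategies = load_strategies_dir(strategies_dir)
        strat_texts = {
            f.stem: f.read_text() for f in sorted(Path(strategies_dir).glob("*.yaml"))
        }
    else:
        strategies = bundled_strategies()
        root = resources.files("survcea").joinpath("data/strategies")
        strat_texts = {name: root.joinpath(f"{name}.yaml").read_text() for name in strategies}
    if params_path:
        params_text = Path(params_path).read_text()
    else:
        params_text = resources.files("survcea").joinpath("data/params.yaml").read_text()
    return params, params_text, strategies, strat_texts


def run_base_case(
    params: ParamSet,
    strategies: Mapping,
    n_trials: int,
    seed: int,
    jpy_per_usd: float = 150.0,
    **settings_kwargs,
):
    """Simulate every strategy and return a tidy results table."""
    import pandas as pd

    rows = []
    for name in sorted(strategies):
        settings = SimSettings(n_trials=n_trials, seed=seed, **settings_kwargs)
        r = simulate_cohort(params, strategies[name], settings)
        rows.append(
            {
                "strategy": name,
                "cost_jpy": r.mean_cost,
                "cost_usd": round(r.mean_cost / jpy_per_usd),
                "se_cost_jpy": r.se_cost,
                "lys": r.mean_lys,
                "se_lys": r.se_lys,
                "qalys": r.mean_qalys,
                "se_qalys": r.se_qalys,
                "resectability": r.resectability,
                "se_resectability": r.se_resectability,
                "n_first_recurrence": r.n_first_recurrence,
                "n_trials": r.n_trials,
                "seed": r.seed,
                "theta": r.theta,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: Mapping | str | Path, out_dir: str | Path) -> dict:
    """Execute base case + frontier (+ optional PSA) under one master seed.

    ``config`` keys (all optional): ``params`` (path; default bundled),
    ``strategies_dir`` (path; default bundled), ``n_trials``, ``seed``,
    ``wtp``, ``psa`` ({enabled, n_outer, n_inner, wtp_grid: [start, stop,
    step]}).  Returns the manifest dict; writes ``results.csv``,
    ``frontier.csv``, optionally ``ceac.csv``, and ``manifest.json``.
    """
    if not isinstance(config, Mapping):
        config = yaml.safe_load(Path(config).read_text()) or {}
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params, params_text, strategies, strat_texts = _resolve_inputs(config)
    sim = simulation_defaults(params)
    n_trials = int(config.get("n_trials", sim["n_trials"]))
    seed = int(config.get("seed", 0))
    wtp = float(config.get("wtp", sim["wtp_low"]))
    jpy_per_usd = float(sim["jpy_per_usd"])

    results = run_base_case(params, strategies, n_trials, seed, jpy_per_usd)
    results.to_csv(out_dir / "results.csv", index=False)

    outcomes = [
        StrategyOutcome(row.strategy, row.cost_jpy, row.qalys, row.lys)
        for row in results.itertuples()
    ]
    frontier = simple_dominance(outcomes).to_dataframe()
    frontier["cost_usd"] = (frontier["cost_jpy"] / jpy_per_usd).round().astype(int)
    frontier.to_csv(out_dir / "frontier.csv", index=False)

    psa_cfg = dict(config.get("psa") or {})
    ceac_written = False
    if psa_cfg.get("enabled"):
        grid_cfg = psa_cfg.get("wtp_grid", [0, 10_000_000, 250_000])
        grid = tuple(np.arange(grid_cfg[0], grid_cfg[1] + 1, grid_cfg[2], dtype=float))
        psa_settings = PSASettings(
            n_outer=int(psa_cfg.get("n_outer", 500)),
            n_inner=int(psa_cfg.get("n_inner", 10_000)),
            wtp_grid=grid,
            seed=seed,
        )
        psa_result = run_psa(params, strategies, psa_settings)
        psa_result.ceac.probabilities.rename_axis("wtp_jpy_per_qaly").to_csv(
            out_dir / "ceac.csv"
        )
        ceac_written = True

    manifest = {
        "tool": "survcea",
        "version": __version__,
        "seed": seed,
        "n_trials": n_trials,
        "wtp": wtp,
        "theta": params.theta,
        "params_sha256": _sha256(params_text),
        "strategy_sha256": {name: _sha256(t) for name, t in sorted(strat_texts.items())},
        "psa": {"enabled": bool(psa_cfg.get("enabled")), **{k: v for k, v in psa_cfg.items() if k != "enabled"}},
        "outputs": ["results.csv", "frontier.csv"] + (["ceac.csv"] if ceac_written else []),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
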