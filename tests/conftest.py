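import numpy as np
import pytest

import survcea as sc

# Base-case outcomes published by the original economic evaluation
# (cost in JPY, QALYs, LYs), used as fixed reference inputs for the
# decision-analysis layer.
REFERENCE_OUTCOMES = {
    "asco": (8_054_136, 2.666, 4.788),
    "ascrs": (8_098_162, 2.696, 4.834),
    "nccn": (8_153_181, 2.680, 4.806),
    "esmo": (8_163_627, 2.684, 4.812),
    "jsccr": (8_525_679, 2.844, 5.07),
    "strategy6": (8_772_512, 2.845, 5.079),
}


@pytest.fixture(scope="session")
def params():
    return sc.load_params()


@pytest.fixture(scope="session")
def strategies():
    return sc.bundled_strategies()


@pytest.fixture(scope="session")
def jsccr(strategies):
    return strategies["jsccr"]


@pytest.fixture(scope="session")
def reference_outcomes():
    return [
        sc.StrategyOutcome(name, cost, qalys, lys)
        for name, (cost, qalys, lys) in REFERENCE_OUTCOMES.items()
    ]


@pytest.fixture(scope="session")
def sparse_dense():
    """Nested stand-in schedules: dense is a strict superset of sparse."""
    sparse = sc.load_strategy(
        "name: sparse\nvisits:\n  12: [cect]\n  24: [cect]\n  36: [cect]\n"
    )
    dense = sc.load_strategy(
        "name: dense\nvisits:\n"
        "  6: [cect]\n  12: [cect]\n  18: [cect]\n  24: [cect]\n"
        "  30: [cect]\n  36: [cect]\n"
    )
    return sparse, dense


@pytest.fixture(scope="session")
def no_visit_strategy():
    return sc.load_strategy("name: none\nvisits: {}\n")


@pytest.fixture(scope="session")
def zero_hazard_params(params):
    """All event hazards zero: everyone survives recurrence-free."""
    flat = sc.SurvivalAnchors(((12.0, 1.0), (36.0, 1.0), (60.0, 1.0)), "flat")
    return params.replace(
        rfs_primary=flat, rfs_post_resection=flat, os_chemo=flat,
        rates=sc.FixedRates(conversion_cum_5yr=0.0),
    )


def monthly_annuity(n_cycles: int, annual_rate: float) -> float:
    """Discounted years from surviving n_cycles monthly cycles (oracle)."""
    t = np.arange(1, n_cycles + 1)
    return float(np.sum((1.0 + annual_rate) ** (-t / 12.0)) / 12.0)
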