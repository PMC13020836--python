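import logging

import pytest

from oamarkov.parameters import (CostSet, ManufacturingInputs, ModelConfig,
                                 MortalityInputs, ParameterSet,
                                 RawTransitionTable, TkrrRiskTable,
                                 UtilitySet, paper_baseline)

logging.getLogger("oamarkov").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def _baseline_cache():
    cache = {}

    def get(perspective, arm):
        key = (perspective, arm)
        if key not in cache:
            cache[key] = paper_baseline(perspective, arm)
        return cache[key]

    return get


@pytest.fixture
def baseline(_baseline_cache):
    """Fresh deep copy of the published base case for one perspective/arm."""
    return lambda perspective="hospital", arm="SoC": \
        _baseline_cache(perspective, arm).copy()


def make_toy_params(state_cost=2569.73, horizon=1, discount_cost=0.0,
                    self_loop=True, utility=0.82) -> ParameterSet:
    """Minimal single-state model: cohort sits in KL II, nobody dies.

    With a pure self-loop the closed-form outcomes are a discounted
    annuity of the KL II state cost and utility.
    """
    rows = {"KL_II": {"KL_II": 1.0} if self_loop else {"KL_II": 0.5, "TKR": 0.5},
            "TKRR": {"TKRR": 1.0}, "Death": {"Death": 1.0}}
    mfg = ManufacturingInputs(0, 0, 0, 0, 0, units_per_year=1)
    util = {s: utility for s in
            ("Healthy", "KL_I", "KL_II", "KL_III", "KL_IV", "TKR", "TKRR")}
    return ParameterSet(
        transitions=RawTransitionTable(rows=rows),
        mortality=MortalityInputs(
            background={a: 0.0 for a in range(45, 100)},
            drug_excess=0.0, operation_excess=0.0),
        tkrr_risk=TkrrRiskTable(by_year={1: 0.0}),
        costs=CostSet(perspective="hospital",
                      annual_state_cost={s: (state_cost if s == "KL_II" else 0.0)
                                         for s in util},
                      tkr_operation=0.0, tkrr_operation=0.0, death=0.0,
                      treatment_unit=0.0),
        utilities=UtilitySet(state_utility=util, tkr_operation_cycle=utility,
                             tkrr_operation_cycle=utility),
        manufacturing=mfg,
        config=ModelConfig(horizon=horizon, discount_cost=discount_cost,
                           discount_effect=0.0),
        bounds={},
    )


@pytest.fixture
def toy_params():
    return make_toy_params
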