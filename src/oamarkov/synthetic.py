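"""Synthetic inputs and an individual-level microsimulation oracle.

Everything the cohort analysis consumes can be generated here without
external files: a Gompertz life table standing in for the national
age-indexed death probabilities, random progressive-only disease models,
and a year-indexed revision-risk table.  The microsimulation simulates
individual patients with explicit memory (years since knee replacement,
treatment history) and accrues exactly the same costs, utilities and
discounting as the cohort engine; since the cohort model is the expectation
of the individual process, the two must agree within sampling error — the
main correctness oracle for the matrix machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import engine
from .parameters import (CostSet, ManufacturingInputs, ModelConfig,
                         MortalityInputs, ParameterSet, RawTransitionTable,
                         TkrrRiskTable, UtilitySet, printed_unit_cost)
from .states import DISEASE_CHAIN, STATE_NAMES, TREATED_ARMS


@dataclass
class SyntheticMortalitySpec:
    """Gompertz annual death probability q(age) = min(1, A·exp(B·age)).

    Defaults approximate a western-European life table over ages 45-110
    (q ≈ 0.0011 at 45, ≈ 0.066 at 85).
    """

    level: float = 1.13e-5   # A, baseline hazard scale
    slope: float = 0.102     # B, per year of age
    age_min: int = 45
    age_max: int = 110
    drug_excess: float = 0.0012
    operation_excess: float = 0.002


@dataclass
class MicrosimResult:
    n: int
    seed: int
    mean_cost: float
    se_cost: float
    mean_qalys: float
    se_qalys: float
    tkr_per_1000: float
    se_tkr_per_1000: float
    tkrr_per_1000: float
    se_tkrr_per_1000: float


def synth_mortality(spec: SyntheticMortalitySpec) -> MortalityInputs:
    """Materialise the Gompertz table as engine-ready mortality inputs."""
    if spec.level <= 0:
        raise ValueError("Gompertz level A must be positive")
    if spec.slope < 0:
        raise ValueError("Gompertz slope B must be non-negative")
    table = {age: min(1.0, spec.level * math.exp(spec.slope * age))
             for age in range(spec.age_min, spec.age_max + 1)}
    return MortalityInputs(background=table, drug_excess=spec.drug_excess,
                           operation_excess=spec.operation_excess)


def synth_model(seed: int, n_disease_states: int = 5) -> ParameterSet:
    """A random but structurally valid progressive disease model.

    The pre-surgical chain is a contiguous slice of
    Healthy < KL I < KL II < KL III < KL IV containing KL II (the model
    entry state), with raw transition mass only on self, the one-step
    decline and surgery.  Costs rise and utilities fall with severity so
    that a more effective treatment is unambiguously beneficial.
    Deterministic given the seed.
    """
    if n_disease_states < 2:
        raise ValueError("need at least 2 disease states")
    n_disease_states = min(n_disease_states, len(DISEASE_CHAIN))
    start = min(2, len(DISEASE_CHAIN) - n_disease_states)
    chain = DISEASE_CHAIN[start:start + n_disease_states]

    rng = np.random.default_rng(seed)
    rows: dict[str, dict[str, float]] = {}
    for i, s in enumerate(chain):
        row = {s: float(rng.uniform(0.6, 0.9))}
        if i + 1 < len(chain):
            row[chain[i + 1]] = float(rng.uniform(0.05, 0.2))
            row["TKR"] = float(rng.uniform(0.005, 0.05))
        else:
            row["TKR"] = float(rng.uniform(0.05, 0.3))
        rows[s] = row
    rows["TKRR"] = {"TKRR": 1.0}
    rows["Death"] = {"Death": 1.0}

    mort = synth_mortality(SyntheticMortalitySpec(
        level=float(rng.uniform(5e-6, 5e-5)),
        slope=float(rng.uniform(0.08, 0.11)),
    ))

    n_years = int(rng.integers(5, 11))
    risks = np.sort(rng.uniform(0.002, 0.02, size=n_years))[::-1]
    tkrr = TkrrRiskTable(by_year={y + 1: float(x) for y, x in enumerate(risks)})

    state_cost = {s: float(c) for s, c in zip(
        DISEASE_CHAIN, np.sort(rng.uniform(100.0, 8000.0, len(DISEASE_CHAIN))))}
    state_cost["TKR"] = 0.0
    state_cost["TKRR"] = float(rng.uniform(500.0, 3000.0))
    mfg = ManufacturingInputs(
        facility=float(rng.uniform(5e4, 3e5)),
        staffing=float(rng.uniform(1e5, 6e5)),
        equipment_depreciation=float(rng.uniform(2e4, 2e5)),
        consumables=float(rng.uniform(5e4, 3e5)),
        quality_control=float(rng.uniform(5e4, 2e5)),
        units_per_year=float(rng.integers(200, 2000)),
    )
    costs = CostSet(
        perspective="hospital",
        annual_state_cost=state_cost,
        tkr_operation=float(rng.uniform(8000.0, 25000.0)),
        tkrr_operation=float(rng.uniform(15000.0, 35000.0)),
        death=float(rng.uniform(500.0, 2000.0)),
        treatment_unit=mfg.total_annual_cost / mfg.units_per_year,
    )

    util = {s: float(u) for s, u in zip(
        DISEASE_CHAIN, np.sort(rng.uniform(0.4, 1.0, len(DISEASE_CHAIN)))[::-1])}
    util["Healthy"] = 1.0
    util["TKR"] = float(rng.uniform(0.6, 0.9))
    util["TKRR"] = float(rng.uniform(0.5, util["TKR"]))
    utilities = UtilitySet(
        state_utility=util,
        tkr_operation_cycle=max(0.0, util["TKR"] - 0.03),
        tkrr_operation_cycle=max(0.0, util["TKRR"] - 0.02),
    )

    config = ModelConfig(effectiveness=float(rng.uniform(0.4, 0.9)))
    return ParameterSet(
        transitions=RawTransitionTable(rows=rows),
        mortality=mort,
        tkrr_risk=tkrr,
        costs=costs,
        utilities=utilities,
        manufacturing=mfg,
        config=config,
        bounds={},
    )


def write_fixture_csvs(mortality: MortalityInputs, tkrr: TkrrRiskTable,
                       directory) -> tuple[str, str]:
    """Emit (age,q) and (year,X) CSVs in the dialect the loader reads."""
    import os

    mpath = os.path.join(str(directory), "mortality.csv")
    tpath = os.path.join(str(directory), "tkrr_risk.csv")
    with open(mpath, "w") as fh:
        fh.write("age,q\n")
        for age in sorted(mortality.background):
            fh.write(f"{age},{mortality.background[age]!r}\n")
    with open(tpath, "w") as fh:
        fh.write("year,x\n")
        for year in sorted(tkrr.by_year):
            fh.write(f"{year},{tkrr.by_year[year]!r}\n")
    return mpath, tpath


def microsim(arm: str, params: ParameterSet, n: int, seed: int) -> MicrosimResult:
    """Simulate n independent patients; accrue like the cohort engine.

    Patient memory (tunnel year, ever-treated status) lives in the same
    expanded state space the cohort engine uses, so the per-cycle
    transition rows are shared verbatim; only the propagation differs
    (sampled trajectories instead of expected occupancy).  One seeded
    generator drives all draws, so results are exactly reproducible given
    (seed, n).
    """
    if n < 1:
        raise ValueError("need at least one patient")
    if arm != params.config.arm:
        params = params.copy()
        params.config.arm = arm
    cfg = params.config
    space = engine.build_state_space(params)
    horizon = cfg.horizon
    mats = [engine.build_cycle_matrix(space, k, params) for k in range(horizon)]
    cumrows = [np.cumsum(m, axis=1) for m in mats]

    trace_stub = engine.CohortTrace(
        space=space, occupancy=np.zeros((1, space.n)),
        agg_occupancy=None, agg_inflow=None, administrations=None,
        ages=None, params=params)
    c_state = engine._state_cost_vector(trace_stub, params)
    u_state = engine._utility_vector(trace_stub, params)
    agg_id = np.array([STATE_NAMES.index(st.name) for st in space.states])
    TKR_A, TKRR_A, DEATH_A = (STATE_NAMES.index(s) for s in ("TKR", "TKRR", "Death"))

    treat_mask = np.zeros(space.n, dtype=bool)
    unit = 0.0
    if cfg.arm in TREATED_ARMS:
        for i, st in enumerate(space.states):
            if (st.name == "KL_II" and not st.lingering
                    and (cfg.redo_treatment or not st.treated)):
                treat_mask[i] = True
        unit = (printed_unit_cost(cfg.arm) if cfg.use_printed_unit_costs
                else params.costs.treatment_unit)

    k_idx = np.arange(horizon + 1)
    dfc = (1.0 + cfg.discount_cost) ** (-k_idx)
    dfe = (1.0 + cfg.discount_effect) ** (-k_idx)

    rng = np.random.default_rng(seed)
    state = np.full(n, space.index[engine.ExpandedState("KL_II")], dtype=np.int64)
    cost = np.zeros(n)
    qaly = np.zeros(n)
    had_tkr = np.zeros(n, dtype=bool)
    had_tkrr = np.zeros(n, dtype=bool)

    for k in range(horizon):
        cost += dfc[k] * c_state[state]
        qaly += dfe[k] * u_state[state]
        if unit:
            cost[treat_mask[state]] += dfc[k] * unit
        new_state = state.copy()
        cr = cumrows[k]
        for i in np.unique(state):
            members = np.nonzero(state == i)[0]
            draws = rng.random(members.size)
            new_state[members] = np.searchsorted(cr[i], draws, side="right")
        entered = agg_id[new_state] != agg_id[state]
        ev = entered & (agg_id[new_state] == TKR_A)
        cost[ev] += dfc[k + 1] * params.costs.tkr_operation
        had_tkr |= ev
        ev = entered & (agg_id[new_state] == TKRR_A)
        cost[ev] += dfc[k + 1] * params.costs.tkrr_operation
        had_tkrr |= ev
        ev = entered & (agg_id[new_state] == DEATH_A)
        cost[ev] += dfc[k + 1] * params.costs.death
        state = new_state

    def mean_se(x):
        m = float(np.mean(x))
        se = float(np.std(x, ddof=1) / math.sqrt(n)) if n > 1 else 0.0
        return m, se

    mc, sec = mean_se(cost)
    mq, seq = mean_se(qaly)
    mt, set_ = mean_se(1000.0 * had_tkr)
    mr, ser = mean_se(1000.0 * had_tkrr)
    return MicrosimResult(n=n, seed=seed, mean_cost=mc, se_cost=sec,
                          mean_qalys=mq, se_qalys=seq,
                          tkr_per_1000=mt, se_tkr_per_1000=set_,
                          tkrr_per_1000=mr, se_tkrr_per_1000=ser)
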