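"""Markov cohort engine: per-cycle matrix assembly and 40-year simulation.

The cohort starts entirely in KL II at age 45 and is propagated through
one transition matrix per one-year cycle.  Matrix assembly implements, in
order: the multi-step-decline collapse rule, the treatment-success entry
(treated arms only), mortality layering (age-specific background death plus
OA-drug and first-cycle operation excesses), and a proportional
renormalisation so each row sums to exactly one — the published raw rows do
not (the Healthy row sums to 1.0563, the KL II row to 0.9663, and the
age-varying death entry changes the sum every cycle).

Time-dependent revision risk after knee replacement is made Markovian with
tunnel states (one TKR copy per year since surgery); the "treat once only"
scenario with an ever-treated stratum duplicate of the pre-surgical states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .economics import ArmOutcomes
from .parameters import MortalityInputs, ParameterSet, printed_unit_cost
from .states import DISEASE_CHAIN, STATE_NAMES, TREATED_ARMS

ROW_TOL = 1e-12
OCCUPANCY_TOL = 1e-9


@dataclass(frozen=True)
class ExpandedState:
    """One row/column of the expanded transition matrix.

    ``name`` is the aggregate health state; ``tunnel_year`` counts years
    since TKR surgery (the terminal copy, ``tunnel_year == n+1``, absorbs
    all later years under the table's extrapolation rule); ``treated`` marks
    the ever-treated stratum used when re-treatment is disallowed;
    ``post_op`` distinguishes the TKRR years after the operation year, so
    the operation-cycle mortality and utility apply to the entry year only;
    ``lingering`` marks the KL II copy holding patients whose treatment
    already failed this episode — they are not re-treated until they leave
    KL II and enter again (per-entry treatment frequency only).
    """

    name: str
    tunnel_year: int | None = None
    treated: bool = False
    post_op: bool = False
    lingering: bool = False


@dataclass
class ExpandedStateSpace:
    states: list[ExpandedState]
    index: dict[ExpandedState, int]
    once_only: bool

    @property
    def n(self) -> int:
        return len(self.states)

    def aggregate_of(self, i: int) -> str:
        return self.states[i].name


def build_state_space(params: ParameterSet) -> ExpandedStateSpace:
    cfg = params.config
    once_only = cfg.arm in TREATED_ARMS and not cfg.redo_treatment
    states: list[ExpandedState] = [ExpandedState(s) for s in DISEASE_CHAIN]
    if once_only:
        states += [ExpandedState(s, treated=True) for s in DISEASE_CHAIN]
    elif cfg.arm in TREATED_ARMS and cfg.treatment_frequency == "per_entry":
        # failed-treatment holding copy: occupied between a failed entry
        # treatment and the next exit from KL II
        states.append(ExpandedState("KL_II", lingering=True))
    n_tunnel = params.tkrr_risk.n_years
    states += [ExpandedState("TKR", tunnel_year=y) for y in range(1, n_tunnel + 2)]
    states += [ExpandedState("TKRR"),                # operation (entry) year
               ExpandedState("TKRR", post_op=True),  # all later years
               ExpandedState("Death")]
    return ExpandedStateSpace(
        states=states,
        index={s: i for i, s in enumerate(states)},
        once_only=once_only,
    )


def _tkrr_entry(space: ExpandedStateSpace) -> int:
    return space.index[ExpandedState("TKRR")]


def _tkrr_post(space: ExpandedStateSpace) -> int:
    return space.index[ExpandedState("TKRR", post_op=True)]


# ---------------------------------------------------------------------------
# row assembly
# ---------------------------------------------------------------------------

def collapse_decline(raw_row: dict[str, float], source: str) -> dict[str, float]:
    """Fold multi-step severity declines onto the one-step destination.

    Patients decline at most one KL grade per cycle: any raw probability of
    dropping two or more grades along Healthy < KL I < ... < KL IV is added
    to the adjacent (one-step) decline and zeroed at its original
    destination.  Surgery (TKR) and death entries are untouched — they are
    reachable from any pre-surgical state.
    """
    if source not in DISEASE_CHAIN:
        return dict(raw_row)
    out = dict(raw_row)
    src_i = DISEASE_CHAIN.index(source)
    if src_i + 1 >= len(DISEASE_CHAIN):
        return out
    one_step = DISEASE_CHAIN[src_i + 1]
    for dst in list(out):
        if dst in DISEASE_CHAIN and DISEASE_CHAIN.index(dst) > src_i + 1:
            out[one_step] = out.get(one_step, 0.0) + out[dst]
            out[dst] = 0.0
    return out


def mortality_for(state: str, age: int, first_cycle_in_state: bool,
                  mortality: MortalityInputs) -> float:
    """Per-cycle death probability layered on top of the life table.

    Healthy / KL I: background only.  KL II-IV: background plus the
    OA-drug excess.  TKR / TKRR: the operation excess in the first cycle
    after surgery, background only afterwards.  Clamped to [0, 1].
    """
    table = mortality.background
    lo = min(table)
    if age < lo:
        raise ValueError(f"age {age} below the mortality table start ({lo})")
    q = table.get(age, table[max(table)])
    if state in ("KL_II", "KL_III", "KL_IV"):
        q += mortality.drug_excess
    elif state in ("TKR", "TKRR") and first_cycle_in_state:
        q += mortality.operation_excess
    return min(max(q, 0.0), 1.0)


def assemble_row(state: ExpandedState, age: int, params: ParameterSet,
                 space: ExpandedStateSpace) -> np.ndarray:
    """One row-stochastic row of the cycle matrix for ``state`` at ``age``."""
    cfg = params.config
    n = space.n
    row = np.zeros(n)
    death_i = space.index[ExpandedState("Death")]

    if state.name == "Death":
        row[death_i] = 1.0
        return row

    if state.name == "TKR":
        y = state.tunnel_year
        n_tab = params.tkrr_risk.n_years
        x = (params.tkrr_risk.risk(n_tab + 1) if y == n_tab + 1
             else params.tkrr_risk.by_year[y])
        q = mortality_for("TKR", age, y == 1, params.mortality)
        row[_tkrr_entry(space)] = x
        nxt = ExpandedState("TKR", tunnel_year=min(y + 1, n_tab + 1))
        row[space.index[nxt]] += 1.0 - x
        row[death_i] += q

    elif state.name == "TKRR":
        q = mortality_for("TKRR", age, not state.post_op, params.mortality)
        row[_tkrr_post(space)] = 1.0
        row[death_i] = q

    else:  # pre-surgical disease states
        raw = collapse_decline(params.transitions.rows.get(state.name, {}),
                               state.name)
        if not raw:
            raw = {state.name: 1.0}  # no published row: stay put (until death)
        treats = (cfg.arm in TREATED_ARMS and state.name == "KL_II"
                  and not state.lingering
                  and (cfg.redo_treatment or not state.treated))
        if treats:
            raw = dict(raw)
            raw[cfg.treatment_target_state] = cfg.effectiveness
        q = mortality_for(state.name, age, False, params.mortality)
        # Destination stratum: once a treatment has been administered the
        # patient moves to (or stays in) the ever-treated stratum.
        dst_treated = space.once_only and (state.treated or treats)
        has_lingering = ExpandedState("KL_II", lingering=True) in space.index
        for dst, p in raw.items():
            if p == 0.0:
                continue
            if dst == "TKR":
                j = space.index[ExpandedState("TKR", tunnel_year=1)]
            elif dst == "TKRR":
                j = _tkrr_entry(space)
            elif dst == "Death":
                j = death_i
            elif (dst == "KL_II" and state.name == "KL_II" and has_lingering):
                # staying in KL II is not a new entry: failed patients wait
                # untreated until they cycle out and back in
                j = space.index[ExpandedState("KL_II", lingering=True)]
            else:
                j = space.index[ExpandedState(dst, treated=dst_treated)]
            row[j] += p
        if cfg.effectiveness_is_absolute and treats:
            # Hold success and death fixed; the remaining destinations share
            # whatever probability mass is left.
            e = cfg.effectiveness
            tgt = space.index[ExpandedState(cfg.treatment_target_state,
                                            treated=dst_treated)]
            succ = row[tgt]
            others = row.sum() - succ
            rest = max(1.0 - e - q, 0.0)
            if others > 0:
                row *= rest / others
            row[tgt] = e
            row[death_i] += q
            s = row.sum()
            if s <= 0:
                raise ValueError(f"zero row sum for state {state}")
            row /= s
            return row
        row[death_i] += q

    s = row.sum()
    if s <= 0:
        raise ValueError(f"zero row sum for state {state}")
    return row / s


def build_cycle_matrix(space: ExpandedStateSpace, cycle: int,
                       params: ParameterSet) -> np.ndarray:
    """The row-stochastic transition matrix for one cycle (age varies)."""
    age = params.config.start_age + cycle
    mat = np.empty((space.n, space.n))
    for i, st in enumerate(space.states):
        mat[i] = assemble_row(st, age, params, space)
    sums = mat.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=ROW_TOL, rtol=0.0):
        raise RuntimeError("assembled matrix is not row-stochastic")
    return mat


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class CohortTrace:
    """State occupancancy and inflow history of one cohort run.

    ``occupancy`` has one row per cycle 0..horizon over the expanded
    states; ``agg_occupancy`` and ``agg_inflow`` aggregate tunnel years and
    strata back to the eight published states.  ``agg_inflow[k]`` is the
    probability mass newly entering each aggregate state at cycle k (mass
    advancing between tunnel years of TKR is not "new").
    ``administrations[k]`` is the treated-KL II occupancy billed one
    treatment unit during cycle k.
    """

    space: ExpandedStateSpace
    occupancy: np.ndarray          # (horizon+1, n_states)
    agg_occupancy: np.ndarray      # (horizon+1, 8)
    agg_inflow: np.ndarray         # (horizon+1, 8)
    administrations: np.ndarray    # (horizon,)
    ages: np.ndarray               # (horizon+1,)
    params: ParameterSet = field(repr=False, default=None)

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[0] - 1

    def aggregate_index(self, name: str) -> int:
        return STATE_NAMES.index(name)

    def to_dataframe(self):
        import pandas as pd

        cols = {"cycle": np.arange(self.horizon + 1), "age": self.ages}
        for i, name in enumerate(STATE_NAMES):
            cols[name] = self.agg_occupancy[:, i]
        for name in ("TKR", "TKRR", "Death", "KL_II"):
            cols[f"inflow_{name}"] = self.agg_inflow[:, self.aggregate_index(name)]
        return pd.DataFrame(cols)


def _aggregation_matrix(space: ExpandedStateSpace) -> np.ndarray:
    agg = np.zeros((space.n, len(STATE_NAMES)))
    for i, st in enumerate(space.states):
        agg[i, STATE_NAMES.index(st.name)] = 1.0
    return agg


def run_cohort(arm: str, params: ParameterSet) -> CohortTrace:
    """Propagate the cohort (all mass in untreated KL II at cycle 0).

    Deterministic: identical inputs give identical traces.
    """
    if arm != params.config.arm:
        params = params.copy()
        params.config.arm = arm
    cfg = params.config
    space = build_state_space(params)
    n, horizon = space.n, cfg.horizon

    occ = np.zeros((horizon + 1, n))
    occ[0, space.index[ExpandedState("KL_II")]] = 1.0
    agg_mat = _aggregation_matrix(space)
    agg_inflow = np.zeros((horizon + 1, len(STATE_NAMES)))
    admins = np.zeros(horizon)

    treat_idx = []
    if cfg.arm in TREATED_ARMS:
        treat_idx = [i for i, st in enumerate(space.states)
                     if st.name == "KL_II" and not st.lingering
                     and (cfg.redo_treatment or not st.treated)]

    for k in range(horizon):
        mat = build_cycle_matrix(space, k, params)
        occ[k + 1] = occ[k] @ mat
        if abs(occ[k + 1].sum() - 1.0) > OCCUPANCY_TOL:
            raise RuntimeError("cohort mass not conserved")
        # inflow: mass arriving in aggregate a from a different aggregate
        flows = occ[k][:, None] * mat                     # (src, dst)
        agg_flows = agg_mat.T @ flows @ agg_mat            # (agg_src, agg_dst)
        agg_inflow[k + 1] = agg_flows.sum(axis=0) - np.diag(agg_flows)
        if treat_idx:
            admins[k] = occ[k, treat_idx].sum()

    ages = cfg.start_age + np.arange(horizon + 1)
    return CohortTrace(space=space, occupancy=occ,
                       agg_occupancy=occ @ agg_mat, agg_inflow=agg_inflow,
                       administrations=admins, ages=ages, params=params)


# ---------------------------------------------------------------------------
# accrual
# ---------------------------------------------------------------------------

def _state_cost_vector(trace: CohortTrace, params: ParameterSet) -> np.ndarray:
    c = params.costs.annual_state_cost
    return np.array([c.get(st.name, 0.0) for st in trace.space.states])


def _utility_vector(trace: CohortTrace, params: ParameterSet) -> np.ndarray:
    u = params.utilities
    out = np.empty(trace.space.n)
    for i, st in enumerate(trace.space.states):
        if st.name == "Death":
            out[i] = 0.0
        elif st.name == "TKR":
            out[i] = (u.tkr_operation_cycle if st.tunnel_year == 1
                      else u.state_utility["TKR"])
        elif st.name == "TKRR":
            out[i] = (u.state_utility["TKRR"] if st.post_op
                      else u.tkrr_operation_cycle)
        else:
            out[i] = u.state_utility[st.name]
    return out


def round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def count_surgeries(trace: CohortTrace) -> tuple[int, int]:
    """Cumulative TKR and TKRR operations per 1,000 patients, 40 years."""
    tkr = trace.agg_inflow[:, trace.aggregate_index("TKR")].sum()
    tkrr = trace.agg_inflow[:, trace.aggregate_index("TKRR")].sum()
    return round_half_away(1000.0 * tkr), round_half_away(1000.0 * tkrr)


def accrue(trace: CohortTrace, params: ParameterSet) -> ArmOutcomes:
    """Discounted per-patient cost and QALY totals over the horizon.

    State costs/utilities accrue on the occupancy of cycles 0..horizon-1,
    discounted by (1+r)^-k with cycle 0 undiscounted.  One-time event costs
    (TKR operation, TKRR operation, death) attach to the inflow mass at the
    cycle it arrives; operation-cycle utilities are carried by the tunnel
    entry states.  Treatment units are billed per cycle of treated-KL II
    occupancy.
    """
    cfg = params.config
    if trace.params is not None and trace.params.config.arm != cfg.arm:
        raise ValueError("trace was produced under a different arm")
    horizon = trace.horizon
    k = np.arange(horizon + 1)
    dfc = (1.0 + cfg.discount_cost) ** (-k)
    dfe = (1.0 + cfg.discount_effect) ** (-k)

    c_state = _state_cost_vector(trace, params)
    u_state = _utility_vector(trace, params)

    state_cost_per_cycle = trace.occupancy @ c_state           # (horizon+1,)
    qaly_per_cycle = trace.occupancy @ u_state

    if cfg.half_cycle_correction:
        wc = np.ones(horizon + 1)
        wc[0] = wc[-1] = 0.5
        cost = float((wc * dfc * state_cost_per_cycle).sum())
        qalys = float((wc * dfe * qaly_per_cycle).sum())
    else:
        cost = float((dfc[:horizon] * state_cost_per_cycle[:horizon]).sum())
        qalys = float((dfe[:horizon] * qaly_per_cycle[:horizon]).sum())

    inflow = trace.agg_inflow
    idx = trace.aggregate_index
    cost += float((dfc * inflow[:, idx("TKR")]).sum()) * params.costs.tkr_operation
    cost += float((dfc * inflow[:, idx("TKRR")]).sum()) * params.costs.tkrr_operation
    cost += float((dfc * inflow[:, idx("Death")]).sum()) * params.costs.death

    if cfg.arm in TREATED_ARMS:
        unit = (printed_unit_cost(cfg.arm) if cfg.use_printed_unit_costs
                else params.costs.treatment_unit)
        cost += float((dfc[:horizon] * trace.administrations).sum()) * unit

    tkr, tkrr = count_surgeries(trace)
    return ArmOutcomes(arm=cfg.arm, perspective=cfg.perspective,
                       total_cost=cost, total_qalys=qalys,
                       tkr_per_1000=tkr, tkrr_per_1000=tkrr)


def run_arm(arm: str, params: ParameterSet) -> ArmOutcomes:
    """Convenience: simulate one arm and accrue its outcomes."""
    if arm != params.config.arm:
        params = params.copy()
        params.config.arm = arm
    return accrue(run_cohort(arm, params), params)
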