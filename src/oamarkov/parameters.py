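"""Model inputs: domain types, the published base case, validation and bounds.

All monetary inputs are 2024 euros; probabilities are per one-year cycle.
The base case compares four production arms of a regenerative knee-OA
therapy (hiMSC cells or hiMSC-derived extracellular vesicles, each made by
an automated or a manual process) against standard of care, from a hospital
or a societal costing perspective.

Raw per-cycle transition rows are stored exactly as published: rows need
NOT sum to one.  The cohort engine appends the age-specific death
probability and renormalises each row proportionally.
"""

from __future__ import annotations

import copy
import csv
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Callable, NamedTuple

import yaml

from .states import ARMS, DISEASE_CHAIN, PERSPECTIVES, STATE_NAMES

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class RawTransitionTable:
    """Published per-cycle transition probabilities, before renormalisation.

    ``rows[src][dst]`` is the raw probability of moving from aggregate state
    ``src`` to ``dst`` in one cycle.  Death and TKR-revision timing are
    handled separately (mortality layering and the tunnel-year risk table).
    """

    rows: dict[str, dict[str, float]]

    def get(self, src: str, dst: str) -> float:
        return self.rows.get(src, {}).get(dst, 0.0)


@dataclass
class MortalityInputs:
    """Background life-table mortality plus disease-specific excesses.

    ``background`` maps integer age to the annual probability of death.
    ``drug_excess`` is added while in KL II-IV (chronic OA-drug use);
    ``operation_excess`` is added in the first cycle after TKR or TKRR
    surgery only.
    """

    background: dict[int, float]
    drug_excess: float = 0.0012
    operation_excess: float = 0.002


@dataclass
class TkrrRiskTable:
    """Yearly probability of revision surgery, by year since the TKR.

    ``terminal_rule`` controls extrapolation beyond the last tabulated
    year: ``"persist"`` keeps the last value, ``"zero"`` drops the risk
    to nothing.
    """

    by_year: dict[int, float]
    terminal_rule: str = "persist"

    @property
    def n_years(self) -> int:
        return max(self.by_year)

    def risk(self, tunnel_year: int) -> float:
        if tunnel_year in self.by_year:
            return self.by_year[tunnel_year]
        if tunnel_year < 1:
            raise ValueError("tunnel_year must be >= 1")
        return self.by_year[self.n_years] if self.terminal_rule == "persist" else 0.0


@dataclass
class CostSet:
    perspective: str
    annual_state_cost: dict[str, float]
    tkr_operation: float
    tkrr_operation: float
    death: float
    treatment_unit: float = 0.0


@dataclass
class UtilitySet:
    state_utility: dict[str, float]
    tkr_operation_cycle: float = 0.76
    tkrr_operation_cycle: float = 0.73


@dataclass
class ManufacturingInputs:
    """Annual production-facility cost components and yearly unit output."""

    facility: float
    staffing: float
    equipment_depreciation: float
    consumables: float
    quality_control: float
    units_per_year: float
    label: str = "hiMSC_automated"

    @property
    def total_annual_cost(self) -> float:
        return (self.facility + self.staffing + self.equipment_depreciation
                + self.consumables + self.quality_control)


@dataclass
class ModelConfig:
    start_age: int = 45
    horizon: int = 40
    cycle_length: float = 1.0
    discount_cost: float = 0.04
    discount_effect: float = 0.015
    arm: str = "SoC"
    perspective: str = "hospital"
    effectiveness: float = 0.69
    redo_treatment: bool = True
    treatment_target_state: str = "Healthy"
    # "per_entry": treatment (effect and cost) applies in the cycle a
    # patient enters KL II; failures wait untreated until they cycle back.
    # "per_cycle": every cycle spent in KL II is treated and billed.
    treatment_frequency: str = "per_entry"
    # When True (default) the treatment-success probability is excluded
    # from the proportional renormalisation: success stays at its stated
    # value and the remaining destinations share the left-over mass.  When
    # False the success entry joins the row and is scaled like every other
    # entry.
    effectiveness_is_absolute: bool = True
    half_cycle_correction: bool = False
    use_printed_unit_costs: bool = False


@dataclass
class ParameterSet:
    """Every input the cohort engine needs, for one perspective/arm."""

    transitions: RawTransitionTable
    mortality: MortalityInputs
    tkrr_risk: TkrrRiskTable
    costs: CostSet
    utilities: UtilitySet
    manufacturing: ManufacturingInputs
    config: ModelConfig
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)


class Violation(NamedTuple):
    field: str
    rule: str
    level: str  # "error" | "warning"


class ConfigurationError(ValueError):
    """Unknown label, missing parameter or unreadable configuration."""


# ---------------------------------------------------------------------------
# published base case
# ---------------------------------------------------------------------------

_RAW_TRANSITIONS = {
    "Healthy": {"Healthy": 0.5398, "KL_I": 0.5165},
    "KL_I": {"KL_I": 0.7407, "KL_II": 0.2626, "TKR": 0.0046},
    "KL_II": {"KL_II": 0.928, "KL_III": 0.0291, "TKR": 0.0092},
    "KL_III": {"KL_III": 0.8598, "TKR": 0.0864},
    "KL_IV": {"KL_IV": 0.7, "TKR": 0.3},
    "TKRR": {"TKRR": 1.0},
    "Death": {"Death": 1.0},
}

# Annual health-state costs, 2024 EUR/year: (base, low, high) per perspective.
# KL IV has no published cost; it is unreachable from the KL II start state
# (the KL III row has no KL IV mass) and defaults to the KL III value.
_STATE_COSTS = {
    "hospital": {
        "Healthy": (0.0, 0.0, 0.0),
        "KL_I": (1927.30, 931.31, 2561.11),
        "KL_II": (2569.73, 1241.75, 3414.81),
        "KL_III": (3212.17, 1522.19, 4268.52),
        "TKR": (0.0, 0.0, 0.0),
        "TKRR": (1380.42, 519.04, 2654.55),
    },
    "societal": {
        "Healthy": (0.0, 0.0, 0.0),
        "KL_I": (11266.30, 1384.03, 15521.88),
        "KL_II": (15021.73, 1845.38, 20695.84),
        "KL_III": (18777.16, 2306.72, 25869.80),
        "TKR": (0.0, 0.0, 0.0),
        "TKRR": (1380.42, 519.04, 2654.55),
    },
}

_EVENT_COSTS = {
    # identical across perspectives
    "tkr_operation": (16565.05, 11602.44, 22398.71),
    "tkrr_operation": (27608.42, 22463.59, 33276.43),
}

# The hospital lower bound exceeds the base value as printed; loaded
# verbatim and flagged as a warning by validate().
_DEATH_COST = {
    "hospital": (1082.28, 1163.91, 1745.87),
    "societal": (1082.28, 865.83, 1298.74),
}

_UTILITIES = {
    "Healthy": (1.00, 1.00, 1.00),
    "KL_I": (0.80, 0.64, 0.96),
    "KL_II": (0.82, 0.66, 0.98),
    "KL_III": (0.77, 0.62, 0.92),
    "TKR": (0.79, 0.76, 0.82),
    "TKRR": (0.75, 0.72, 0.78),
}
_UTIL_OP = {
    "tkr_operation_cycle": (0.76, 0.73, 0.79),
    "tkrr_operation_cycle": (0.73, 0.70, 0.76),
}

# Manufacturing: annual cost components (EUR/year) and yearly unit output.
# The automated facility runs 330 manufacturing days per year, the manual
# one 250; the combined cell+EV arms spread the same facility cost over
# twice the unit output.
_MFG_COMPONENTS = {
    "automated": {
        "facility": (156864.00, 125491.20, 188236.80),
        "staffing": (421814.00, 337451.20, 506176.80),
        "equipment_depreciation": (136697.00, 109357.60, 164036.40),
        "consumables": (249238.00, 199390.40, 299085.60),
        "quality_control": (190000.00, 152000.00, 228000.00),
    },
    "manual": {
        "facility": (231775.00, 185420.00, 278130.00),
        "staffing": (454955.00, 363964.00, 545946.00),
        "equipment_depreciation": (49646.00, 39716.80, 59575.20),
        "consumables": (176656.00, 141324.80, 211987.20),
        "quality_control": (135000.00, 108000.00, 162000.00),
    },
}
_MFG_UNITS = {
    "hiMSC_auto": (750, 600, 900),
    "hiMSC_manual": (480, 384, 576),
    "hiMSC_EV_auto": (1500, 1200, 1800),
    "hiMSC_EV_manual": (960, 768, 1152),
}
_PRINTED_UNIT_COST = {
    "hiMSC_auto": 1539.00,
    "hiMSC_manual": 2183.00,
    "hiMSC_EV_auto": 770.00,
    "hiMSC_EV_manual": 1092.00,
}
_ARM_PROCESS = {
    "hiMSC_auto": "automated",
    "hiMSC_manual": "manual",
    "hiMSC_EV_auto": "automated",
    "hiMSC_EV_manual": "manual",
    "SoC": "automated",  # irrelevant: no treatment administered
}
_MFG_LABEL = {
    "hiMSC_auto": "hiMSC_automated",
    "hiMSC_manual": "hiMSC_manual",
    "hiMSC_EV_auto": "hiMSC_EV_automated",
    "hiMSC_EV_manual": "hiMSC_EV_manual",
    "SoC": "hiMSC_automated",
}


def load_probability_csv(path_or_file) -> dict[int, float]:
    """Read a 2-column CSV (integer key, probability); header row required.

    Used for both the age-indexed annual death probabilities and the
    revision-risk-by-year-after-TKR table; any header names are accepted.
    """
    if hasattr(path_or_file, "read"):
        reader = csv.reader(path_or_file)
        rows = list(reader)
    else:
        with open(path_or_file, newline="") as fh:
            rows = list(csv.reader(fh))
    if not rows or len(rows[0]) < 2:
        raise ConfigurationError(f"not a 2-column CSV table: {path_or_file!r}")
    out: dict[int, float] = {}
    for row in rows[1:]:
        if not row or not row[0].strip():
            continue
        out[int(row[0])] = float(row[1])
    if not out:
        raise ConfigurationError(f"empty probability table: {path_or_file!r}")
    return out


def _packaged_table(filename: str) -> dict[int, float]:
    ref = resources.files("oamarkov.data").joinpath(filename)
    with ref.open("r", newline="") as fh:
        return load_probability_csv(fh)


_warned: set[str] = set()


def _warn_once(key: str, message: str) -> None:
    if key not in _warned:
        _warned.add(key)
        log.warning(message)


def default_mortality_table() -> dict[int, float]:
    """Packaged synthetic life table (Gompertz stand-in for the Dutch one)."""
    _warn_once("mortality",
               "Using the packaged SYNTHETIC background-mortality table "
               "(Gompertz stand-in for the Dutch life table); supply a CSV "
               "to override.")
    return _packaged_table("synthetic_mortality.csv")


def default_tkrr_table() -> dict[int, float]:
    """Packaged synthetic revision-risk-by-year table (registry stand-in)."""
    _warn_once("tkrr",
               "Using the packaged SYNTHETIC revision-risk-by-year table; "
               "supply a CSV to override.")
    return _packaged_table("synthetic_tkrr_risk.csv")


def paper_baseline(
    perspective: str,
    arm: str,
    mortality_csv=None,
    tkrr_csv=None,
) -> ParameterSet:
    """The published base case for one perspective/arm combination.

    ``mortality_csv`` / ``tkrr_csv`` optionally point at user-supplied
    (age, q) and (year, X) tables; otherwise the packaged synthetic
    stand-ins are used (with a warning logged).
    """
    if perspective not in PERSPECTIVES:
        raise ConfigurationError(f"unknown perspective {perspective!r}")
    if arm not in ARMS:
        raise ConfigurationError(f"unknown arm {arm!r}")

    background = (load_probability_csv(mortality_csv) if mortality_csv is not None
                  else default_mortality_table())
    tkrr_years = (load_probability_csv(tkrr_csv) if tkrr_csv is not None
                  else default_tkrr_table())

    process = _ARM_PROCESS[arm]
    comp = _MFG_COMPONENTS[process]
    units = _MFG_UNITS.get(arm, _MFG_UNITS["hiMSC_auto"])
    mfg = ManufacturingInputs(
        facility=comp["facility"][0],
        staffing=comp["staffing"][0],
        equipment_depreciation=comp["equipment_depreciation"][0],
        consumables=comp["consumables"][0],
        quality_control=comp["quality_control"][0],
        units_per_year=units[0],
        label=_MFG_LABEL[arm],
    )

    sc = _STATE_COSTS[perspective]
    annual = {s: sc[s][0] for s in sc}
    annual["KL_IV"] = annual["KL_III"]  # unpublished; unreachable in base case
    costs = CostSet(
        perspective=perspective,
        annual_state_cost=annual,
        tkr_operation=_EVENT_COSTS["tkr_operation"][0],
        tkrr_operation=_EVENT_COSTS["tkrr_operation"][0],
        death=_DEATH_COST[perspective][0],
        treatment_unit=mfg.total_annual_cost / mfg.units_per_year,
    )

    util = {s: _UTILITIES[s][0] for s in _UTILITIES}
    util["KL_IV"] = util["KL_III"]
    utilities = UtilitySet(
        state_utility=util,
        tkr_operation_cycle=_UTIL_OP["tkr_operation_cycle"][0],
        tkrr_operation_cycle=_UTIL_OP["tkrr_operation_cycle"][0],
    )

    config = ModelConfig(arm=arm, perspective=perspective)

    bounds: dict[str, tuple[float, float]] = {
        "c_KLI": sc["KL_I"][1:],
        "c_KLII": sc["KL_II"][1:],
        "c_KLIII": sc["KL_III"][1:],
        "c_TKR": sc["TKR"][1:],
        "c_TKRR": sc["TKRR"][1:],
        "c_Healthy": sc["Healthy"][1:],
        "c_TKR_operation": _EVENT_COSTS["tkr_operation"][1:],
        "c_TKRR_operation": _EVENT_COSTS["tkrr_operation"][1:],
        "c_death": _DEATH_COST[perspective][1:],
        "u_Healthy": _UTILITIES["Healthy"][1:],
        "u_KLI": _UTILITIES["KL_I"][1:],
        "u_KLII": _UTILITIES["KL_II"][1:],
        "u_KLIII": _UTILITIES["KL_III"][1:],
        "u_TKR": _UTILITIES["TKR"][1:],
        "u_TKRR": _UTILITIES["TKRR"][1:],
        "u_TKR_operation": _UTIL_OP["tkr_operation_cycle"][1:],
        "u_TKRR_operation": _UTIL_OP["tkrr_operation_cycle"][1:],
        "mfg_facility": comp["facility"][1:],
        "mfg_staffing": comp["staffing"][1:],
        "mfg_equipment_depreciation": comp["equipment_depreciation"][1:],
        "mfg_consumables": comp["consumables"][1:],
        "mfg_quality_control": comp["quality_control"][1:],
        "mfg_units_per_year": units[1:],
        "redo_MSCTx": (0.0, 1.0),
    }
    # Raw transition probabilities and remaining scalars: +/-20%.
    for src, row in _RAW_TRANSITIONS.items():
        if src in ("TKRR", "Death"):
            continue
        for dst, p in row.items():
            key = f"p_{src.replace('_', '')}_{dst.replace('_', '')}"
            bounds[key] = (0.8 * p, min(1.0, 1.2 * p))
    bounds["p_KLII_Healthy_MSC"] = (0.8 * 0.69, min(1.0, 1.2 * 0.69))
    bounds["p_mortalityOAdrugs"] = (0.8 * 0.0012, 1.2 * 0.0012)
    bounds["p_mortality_operation"] = (0.8 * 0.002, 1.2 * 0.002)

    return ParameterSet(
        transitions=RawTransitionTable(rows=copy.deepcopy(_RAW_TRANSITIONS)),
        mortality=MortalityInputs(background=background),
        tkrr_risk=TkrrRiskTable(by_year=tkrr_years),
        costs=costs,
        utilities=utilities,
        manufacturing=mfg,
        config=config,
        bounds=bounds,
    )


def printed_unit_cost(arm: str) -> float:
    """The whole-euro per-unit treatment cost as published."""
    try:
        return _PRINTED_UNIT_COST[arm]
    except KeyError:
        raise ConfigurationError(f"no printed unit cost for arm {arm!r}") from None


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def _check_prob(violations, name, p):
    if not (0.0 <= p <= 1.0):
        violations.append(Violation(name, f"probability {p} outside [0, 1]", "error"))


def validate(params: ParameterSet) -> list[Violation]:
    """All invariant violations in ``params`` (empty list means clean).

    Errors mark data the engine must not run on; warnings flag published
    oddities (e.g. a lower bound above its base value) that are loaded
    verbatim on purpose.
    """
    v: list[Violation] = []
    for src, row in params.transitions.rows.items():
        if src not in STATE_NAMES:
            v.append(Violation(f"transitions[{src}]", "unknown source state", "error"))
            continue
        for dst, p in row.items():
            if dst not in STATE_NAMES:
                v.append(Violation(f"transitions[{src}][{dst}]",
                                   "unknown destination state", "error"))
            else:
                _check_prob(v, f"transitions[{src}][{dst}]", p)
    if params.transitions.get("Death", "Death") != 1.0:
        v.append(Violation("transitions[Death]", "Death must be absorbing", "error"))

    for age, q in params.mortality.background.items():
        _check_prob(v, f"mortality.background[{age}]", q)
    _check_prob(v, "mortality.drug_excess", params.mortality.drug_excess)
    _check_prob(v, "mortality.operation_excess", params.mortality.operation_excess)
    for year, x in params.tkrr_risk.by_year.items():
        _check_prob(v, f"tkrr_risk.by_year[{year}]", x)

    for s, c in params.costs.annual_state_cost.items():
        if c < 0:
            v.append(Violation(f"costs.annual_state_cost[{s}]", "negative cost", "error"))
    for name in ("tkr_operation", "tkrr_operation", "death", "treatment_unit"):
        if getattr(params.costs, name) < 0:
            v.append(Violation(f"costs.{name}", "negative cost", "error"))

    for s, u in params.utilities.state_utility.items():
        _check_prob(v, f"utilities.state_utility[{s}]", u)
    _check_prob(v, "utilities.tkr_operation_cycle", params.utilities.tkr_operation_cycle)
    _check_prob(v, "utilities.tkrr_operation_cycle", params.utilities.tkrr_operation_cycle)

    m = params.manufacturing
    for name in ("facility", "staffing", "equipment_depreciation",
                 "consumables", "quality_control"):
        if getattr(m, name) < 0:
            v.append(Violation(f"manufacturing.{name}", "negative cost", "error"))
    if m.units_per_year <= 0:
        v.append(Violation("manufacturing.units_per_year", "must be positive", "error"))

    cfg = params.config
    if cfg.horizon <= 0:
        v.append(Violation("config.horizon", "must be positive", "error"))
    if cfg.discount_cost < 0 or cfg.discount_effect < 0:
        v.append(Violation("config.discounts", "must be non-negative", "error"))
    _check_prob(v, "config.effectiveness", cfg.effectiveness)
    if cfg.arm not in ARMS:
        v.append(Violation("config.arm", f"unknown arm {cfg.arm!r}", "error"))
    if cfg.perspective not in PERSPECTIVES:
        v.append(Violation("config.perspective", "unknown perspective", "error"))
    if cfg.treatment_target_state not in DISEASE_CHAIN:
        v.append(Violation("config.treatment_target_state",
                           "must be a pre-surgical state", "error"))
    if cfg.treatment_frequency not in ("per_entry", "per_cycle"):
        v.append(Violation("config.treatment_frequency",
                           "must be 'per_entry' or 'per_cycle'", "error"))

    for name, (lo, hi) in params.bounds.items():
        try:
            base = get_parameter(params, name)
        except ConfigurationError:
            base = None
        if base is not None and not (lo <= base <= hi):
            v.append(Violation(f"bounds[{name}]",
                               f"bounds ({lo}, {hi}) do not bracket base {base}",
                               "warning"))
    return v


def errors_of(violations: list[Violation]) -> list[Violation]:
    return [x for x in violations if x.level == "error"]


# ---------------------------------------------------------------------------
# sensitivity-parameter registry
# ---------------------------------------------------------------------------

def _mfg_setter(attr: str) -> Callable[[ParameterSet, float], None]:
    def set_(p: ParameterSet, value: float) -> None:
        setattr(p.manufacturing, attr, value)
        p.costs.treatment_unit = (p.manufacturing.total_annual_cost
                                  / p.manufacturing.units_per_year)
    return set_


def _trans_getter(src, dst):
    return lambda p: p.transitions.get(src, dst)


def _trans_setter(src, dst):
    def set_(p: ParameterSet, value: float) -> None:
        p.transitions.rows.setdefault(src, {})[dst] = value
    return set_


def _build_registry() -> dict[str, tuple[Callable, Callable]]:
    reg: dict[str, tuple[Callable, Callable]] = {}

    def cost_state(key, state):
        reg[key] = (
            lambda p, s=state: p.costs.annual_state_cost[s],
            lambda p, v, s=state: p.costs.annual_state_cost.__setitem__(s, v),
        )

    cost_state("c_Healthy", "Healthy")
    cost_state("c_KLI", "KL_I")
    cost_state("c_KLII", "KL_II")
    cost_state("c_KLIII", "KL_III")
    cost_state("c_KLIV", "KL_IV")
    cost_state("c_TKR", "TKR")
    cost_state("c_TKRR", "TKRR")
    for key, attr in (("c_TKR_operation", "tkr_operation"),
                      ("c_TKRR_operation", "tkrr_operation"),
                      ("c_death", "death")):
        reg[key] = (
            lambda p, a=attr: getattr(p.costs, a),
            lambda p, v, a=attr: setattr(p.costs, a, v),
        )

    def util_state(key, state):
        reg[key] = (
            lambda p, s=state: p.utilities.state_utility[s],
            lambda p, v, s=state: p.utilities.state_utility.__setitem__(s, v),
        )

    util_state("u_Healthy", "Healthy")
    util_state("u_KLI", "KL_I")
    util_state("u_KLII", "KL_II")
    util_state("u_KLIII", "KL_III")
    util_state("u_TKR", "TKR")
    util_state("u_TKRR", "TKRR")
    reg["u_TKR_operation"] = (
        lambda p: p.utilities.tkr_operation_cycle,
        lambda p, v: setattr(p.utilities, "tkr_operation_cycle", v),
    )
    reg["u_TKRR_operation"] = (
        lambda p: p.utilities.tkrr_operation_cycle,
        lambda p, v: setattr(p.utilities, "tkrr_operation_cycle", v),
    )

    for src, row in _RAW_TRANSITIONS.items():
        if src in ("TKRR", "Death"):
            continue
        for dst in row:
            key = f"p_{src.replace('_', '')}_{dst.replace('_', '')}"
            reg[key] = (_trans_getter(src, dst), _trans_setter(src, dst))

    reg["p_KLII_Healthy_MSC"] = (
        lambda p: p.config.effectiveness,
        lambda p, v: setattr(p.config, "effectiveness", v),
    )
    reg["p_mortalityOAdrugs"] = (
        lambda p: p.mortality.drug_excess,
        lambda p, v: setattr(p.mortality, "drug_excess", v),
    )
    reg["p_mortality_operation"] = (
        lambda p: p.mortality.operation_excess,
        lambda p, v: setattr(p.mortality, "operation_excess", v),
    )
    reg["redo_MSCTx"] = (
        lambda p: 1.0 if p.config.redo_treatment else 0.0,
        lambda p, v: setattr(p.config, "redo_treatment", v >= 0.5),
    )

    for attr in ("facility", "staffing", "equipment_depreciation",
                 "consumables", "quality_control"):
        reg[f"mfg_{attr}"] = (
            lambda p, a=attr: getattr(p.manufacturing, a),
            _mfg_setter(attr),
        )
    reg["mfg_units_per_year"] = (
        lambda p: p.manufacturing.units_per_year,
        _mfg_setter("units_per_year"),
    )
    return reg


PARAM_REGISTRY = _build_registry()


def get_parameter(params: ParameterSet, name: str) -> float:
    try:
        getter, _ = PARAM_REGISTRY[name]
    except KeyError:
        raise ConfigurationError(f"unknown parameter {name!r}") from None
    return getter(params)


def with_parameter(params: ParameterSet, name: str, value: float) -> ParameterSet:
    """A deep copy of ``params`` with one named parameter replaced."""
    try:
        _, setter = PARAM_REGISTRY[name]
    except KeyError:
        raise ConfigurationError(f"unknown parameter {name!r}") from None
    out = params.copy()
    setter(out, value)
    return out


def bounds_for(params: ParameterSet, name: str) -> tuple[float, float]:
    """Sensitivity bounds: published when available, else +/-20% of base."""
    if name in params.bounds:
        return tuple(params.bounds[name])
    base = get_parameter(params, name)  # raises for unknown names
    lo, hi = 0.8 * base, 1.2 * base
    return (min(lo, hi), max(lo, hi))


# ---------------------------------------------------------------------------
# serialisation (YAML round trip)
# ---------------------------------------------------------------------------

def to_dict(params: ParameterSet) -> dict:
    cfg = params.config
    return {
        "transitions": copy.deepcopy(params.transitions.rows),
        "mortality": {
            "background": dict(params.mortality.background),
            "drug_excess": params.mortality.drug_excess,
            "operation_excess": params.mortality.operation_excess,
        },
        "tkrr_risk": {
            "by_year": dict(params.tkrr_risk.by_year),
            "terminal_rule": params.tkrr_risk.terminal_rule,
        },
        "costs": {
            "perspective": params.costs.perspective,
            "annual_state_cost": dict(params.costs.annual_state_cost),
            "tkr_operation": params.costs.tkr_operation,
            "tkrr_operation": params.costs.tkrr_operation,
            "death": params.costs.death,
            "treatment_unit": params.costs.treatment_unit,
        },
        "utilities": {
            "state_utility": dict(params.utilities.state_utility),
            "tkr_operation_cycle": params.utilities.tkr_operation_cycle,
            "tkrr_operation_cycle": params.utilities.tkrr_operation_cycle,
        },
        "manufacturing": {
            "facility": params.manufacturing.facility,
            "staffing": params.manufacturing.staffing,
            "equipment_depreciation": params.manufacturing.equipment_depreciation,
            "consumables": params.manufacturing.consumables,
            "quality_control": params.manufacturing.quality_control,
            "units_per_year": params.manufacturing.units_per_year,
            "label": params.manufacturing.label,
        },
        "config": {k: getattr(cfg, k) for k in (
            "start_age", "horizon", "cycle_length", "discount_cost",
            "discount_effect", "arm", "perspective", "effectiveness",
            "redo_treatment", "treatment_target_state", "treatment_frequency",
            "effectiveness_is_absolute", "half_cycle_correction",
            "use_printed_unit_costs")},
        "bounds": {k: list(v) for k, v in params.bounds.items()},
    }


def from_dict(doc: dict) -> ParameterSet:
    try:
        return ParameterSet(
            transitions=RawTransitionTable(rows=doc["transitions"]),
            mortality=MortalityInputs(
                background={int(a): float(q)
                            for a, q in doc["mortality"]["background"].items()},
                drug_excess=doc["mortality"]["drug_excess"],
                operation_excess=doc["mortality"]["operation_excess"],
            ),
            tkrr_risk=TkrrRiskTable(
                by_year={int(y): float(x)
                         for y, x in doc["tkrr_risk"]["by_year"].items()},
                terminal_rule=doc["tkrr_risk"]["terminal_rule"],
            ),
            costs=CostSet(**doc["costs"]),
            utilities=UtilitySet(**doc["utilities"]),
            manufacturing=ManufacturingInputs(**doc["manufacturing"]),
            config=ModelConfig(**doc["config"]),
            bounds={k: tuple(v) for k, v in doc.get("bounds", {}).items()},
        )
    except KeyError as exc:
        raise ConfigurationError(f"missing configuration section: {exc}") from exc


def to_yaml(params: ParameterSet, path=None) -> str:
    text = yaml.safe_dump(to_dict(params), sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def from_yaml(path_or_text) -> ParameterSet:
    if hasattr(path_or_text, "read"):
        doc = yaml.safe_load(path_or_text.read())
    elif "\n" in str(path_or_text):
        doc = yaml.safe_load(path_or_text)
    else:
        with open(path_or_text) as fh:
            doc = yaml.safe_load(fh)
    return from_dict(doc)
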