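"""One-way sensitivity (tornado), scenario analyses and results tables.

The tornado sweeps each input parameter between its lower and upper bound
(published 95% CIs where available, otherwise ±20% of base), re-running the
full cohort model with everything else held at base, and ranks parameters
by the width of the resulting outcome range.  The default outcome metric is
the expected discounted cost per patient — the published rankings are
"main cost drivers" — with net monetary benefit available as a switch.

Four scenario analyses modify the base case: (1) treatment may be given
only once per patient; (2) a general-population incidence for
Healthy → KL I (p = 0.04345); (3) treatment effectiveness 0.76 from the
small-animal studies; (4) successful treatment regresses patients to KL I
rather than Healthy.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import engine
from .economics import DEFAULT_THRESHOLD, ArmOutcomes, compute_icer
from .parameters import (ConfigurationError, ParameterSet, bounds_for,
                         with_parameter)
from .states import ARMS

SCENARIO_DESCRIPTIONS = {
    1: "patients can receive the cell/EV treatment only once",
    2: "general-population Healthy to KL I transition (p = 0.04345)",
    3: "treatment effectiveness 0.76 (small-animal studies)",
    4: "successful treatment regresses to KL I instead of Healthy",
}


@dataclass
class TornadoEntry:
    parameter: str
    low_value: float
    high_value: float
    outcome_at_low: float
    outcome_at_high: float

    @property
    def range(self) -> float:
        return abs(self.outcome_at_high - self.outcome_at_low)


@dataclass
class TornadoTable:
    arm: str
    perspective: str
    metric: str
    entries: list[TornadoEntry]  # sorted by range desc, ties alphabetical

    def ranked(self) -> list[tuple[int, TornadoEntry]]:
        return list(enumerate(self.entries, start=1))

    def rank_of(self, parameter: str) -> int:
        for rank, e in self.ranked():
            if e.parameter == parameter:
                return rank
        raise KeyError(parameter)

    def top(self, n: int) -> list[str]:
        return [e.parameter for e in self.entries[:n]]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"rank": rank, "parameter": e.parameter,
             "low_value": e.low_value, "high_value": e.high_value,
             "outcome_at_low": e.outcome_at_low,
             "outcome_at_high": e.outcome_at_high, "range": e.range}
            for rank, e in self.ranked()
        ])


def _metric(outcomes: ArmOutcomes, metric: str) -> float:
    if metric == "cost":
        return outcomes.total_cost
    if metric == "nmb":
        return DEFAULT_THRESHOLD * outcomes.total_qalys - outcomes.total_cost
    raise ConfigurationError(f"unknown tornado metric {metric!r}")


def one_way_sensitivity(params: ParameterSet, arm: str, perspective: str,
                        metric: str = "cost",
                        parameter_names: list[str] | None = None) -> TornadoTable:
    """Sweep every bounded parameter one at a time; rank by outcome range.

    Deterministic: re-running yields identical ranks (ties broken
    alphabetically by parameter name).
    """
    if params.config.arm != arm or params.config.perspective != perspective:
        params = params.copy()
        params.config.arm = arm
        params.config.perspective = perspective
    names = (sorted(params.bounds) if parameter_names is None
             else list(parameter_names))
    entries = []
    for name in names:
        lo, hi = bounds_for(params, name)  # raises for unknown parameters
        out_lo = _metric(engine.run_arm(arm, with_parameter(params, name, lo)),
                         metric)
        out_hi = _metric(engine.run_arm(arm, with_parameter(params, name, hi)),
                         metric)
        entries.append(TornadoEntry(name, lo, hi, out_lo, out_hi))
    entries.sort(key=lambda e: (-e.range, e.parameter))
    return TornadoTable(arm=arm, perspective=perspective, metric=metric,
                        entries=entries)


def apply_scenario(scenario_id: int, params: ParameterSet) -> ParameterSet:
    """A deep copy of ``params`` with one scenario's overrides applied."""
    if scenario_id not in SCENARIO_DESCRIPTIONS:
        raise ConfigurationError(f"unknown scenario id {scenario_id!r}")
    out = params.copy()
    if scenario_id == 1:
        out.config.redo_treatment = False
    elif scenario_id == 2:
        out.transitions.rows["Healthy"]["KL_I"] = 0.04345
    elif scenario_id == 3:
        out.config.effectiveness = 0.76
    elif scenario_id == 4:
        out.config.treatment_target_state = "KL_I"
    return out


def run_all(params_by_arm: dict[str, ParameterSet]) -> pd.DataFrame:
    """One results row per arm: QALYs, costs, ICER vs standard of care.

    All supplied parameter sets must share a perspective; the standard-of-
    care arm is the mandatory comparator.
    """
    if "SoC" not in params_by_arm:
        raise ConfigurationError("standard-of-care arm missing (no comparator)")
    perspectives = {p.config.perspective for p in params_by_arm.values()}
    if len(perspectives) != 1:
        raise ConfigurationError("mixed perspectives in one results table")

    outcomes = {arm: engine.run_arm(arm, p) for arm, p in params_by_arm.items()}
    soc = outcomes["SoC"]
    rows = []
    for arm in [a for a in ARMS if a in outcomes]:
        o = outcomes[arm]
        row = {
            "arm": arm,
            "perspective": o.perspective,
            "qalys": o.total_qalys,
            "cost": o.total_cost,
            "icer_vs_soc": None,
            "dominance": None,
            "tkr_per_1000": o.tkr_per_1000,
            "tkrr_per_1000": o.tkrr_per_1000,
        }
        if arm != "SoC":
            res = compute_icer(o, soc)
            row["icer_vs_soc"] = res.icer
            row["dominance"] = res.dominance
        rows.append(row)
    return pd.DataFrame(rows)


def relative_reduction(treated_count: float, soc_count: float) -> float:
    """Percent reduction versus standard of care, one decimal."""
    if soc_count == 0:
        raise ZeroDivisionError("comparator count is zero; reduction undefined")
    return round(100.0 * (soc_count - treated_count) / soc_count, 1)


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def write_tornado_csv(table: TornadoTable, path) -> None:
    df = table.to_dataframe()
    for col in ("outcome_at_low", "outcome_at_high", "range"):
        df[col] = df[col].map(lambda x: f"{x:.2f}")
    df.to_csv(path, index=False)


def write_results_csv(df: pd.DataFrame, path) -> None:
    out = df.copy()
    for col in ("qalys", "cost", "icer_vs_soc"):
        out[col] = out[col].map(
            lambda x: "" if x is None or pd.isna(x) else f"{x:.2f}")
    out.to_csv(path, index=False)


def plot_tornado(table: TornadoTable, path, top_n: int = 10) -> None:
    """Horizontal-bar tornado diagram of the top-n parameters (optional)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    entries = table.entries[:top_n][::-1]
    fig, ax = plt.subplots(figsize=(7, 0.4 * len(entries) + 1.5))
    labels = [e.parameter for e in entries]
    for i, e in enumerate(entries):
        lo, hi = sorted((e.outcome_at_low, e.outcome_at_high))
        ax.barh(i, hi - lo, left=lo, color="#4477aa", alpha=0.8)
    ax.set_yticks(range(len(entries)), labels)
    ax.set_xlabel(f"expected discounted {table.metric} per patient (EUR)")
    ax.set_title(f"{table.arm}, {table.perspective} perspective")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
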