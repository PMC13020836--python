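"""Health-economic arithmetic: unit costs, indexation, discounting, ICERs.

The incremental cost-effectiveness ratio (ICER) is the incremental cost
divided by the incremental effect (QALYs), intervention minus comparator.
An intervention that is cheaper and more effective *dominates* the
comparator; a negative ICER with ΔC < 0 and ΔE > 0 denotes dominance, not
"cost per QALY lost".
"""

from __future__ import annotations

import math
from dataclasses import dataclass

DEFAULT_THRESHOLD = 20_000.0  # EUR per QALY, Dutch low-burden-of-illness cap


@dataclass
class ArmOutcomes:
    """Discounted per-patient totals for one arm over the model horizon."""

    arm: str
    perspective: str
    total_cost: float
    total_qalys: float
    tkr_per_1000: int
    tkrr_per_1000: int


@dataclass
class ICERResult:
    delta_cost: float
    delta_effect: float
    icer: float | None
    dominance: str  # dominant | dominated | tradeoff_NE | tradeoff_SW | indifferent


def treatment_unit_cost(m) -> float:
    """Per-unit production cost: total annual facility cost / annual output.

    ``m`` supplies the five annual cost components (facility, staffing,
    equipment depreciation, consumables, quality control) and the yearly
    unit output.  Full precision is returned; report with
    :func:`round_unit_cost` to match whole-euro price lists.
    """
    if m.units_per_year <= 0:
        raise ValueError("units_per_year must be positive")
    total = (m.facility + m.staffing + m.equipment_depreciation
             + m.consumables + m.quality_control)
    return total / m.units_per_year


def round_unit_cost(cost: float) -> int:
    """Whole-euro reporting of a per-unit cost (half away from zero)."""
    return int(math.floor(cost + 0.5))


def index_to_2024(amount: float, source_year: int,
                  index_table: dict[int, float]) -> float:
    """Chain-index an amount from ``source_year`` euros to 2024 euros.

    ``index_table[y]`` is the annual inflation factor applied going from
    year ``y`` to ``y+1``; the factors for source_year..2023 must all be
    present.
    """
    if source_year > 2024:
        raise ValueError("source_year is beyond 2024")
    out = amount
    for year in range(source_year, 2024):
        if year not in index_table:
            raise KeyError(f"missing price-index factor for {year}")
        out *= index_table[year]
    return out


def discount_factor(rate: float, cycle: int) -> float:
    """(1+rate)^-cycle with cycle 0 undiscounted."""
    if rate < -1.0:
        raise ValueError("discount rate below -100%")
    return (1.0 + rate) ** (-cycle)


def compute_icer(intervention: ArmOutcomes, comparator: ArmOutcomes) -> ICERResult:
    """ICER and dominance class from unrounded totals.

    Quadrants: dominant (cheaper, more effective), dominated (dearer, less
    effective), tradeoff_NE (dearer, more effective), tradeoff_SW (cheaper,
    less effective).  The ratio is undefined when ΔE = 0.
    """
    if intervention.perspective != comparator.perspective:
        raise ValueError("cannot compare outcomes across perspectives")
    dc = intervention.total_cost - comparator.total_cost
    de = intervention.total_qalys - comparator.total_qalys
    icer = dc / de if de != 0.0 else None
    if dc == 0.0 and de == 0.0:
        dom = "indifferent"
    elif dc < 0.0 and de > 0.0:
        dom = "dominant"
    elif dc > 0.0 and de < 0.0:
        dom = "dominated"
    elif de >= 0.0:
        dom = "tradeoff_NE"
    else:
        dom = "tradeoff_SW"
    return ICERResult(delta_cost=dc, delta_effect=de, icer=icer, dominance=dom)


def threshold_check(result: ICERResult,
                    threshold: float = DEFAULT_THRESHOLD) -> bool:
    """True when the intervention is acceptable at the willingness-to-pay.

    Dominant interventions pass outright; otherwise the ICER must lie in
    [0, threshold] with a genuine health gain (inclusive upper bound).
    """
    if result.dominance == "dominant":
        return True
    if result.icer is None or result.delta_effect <= 0:
        return False
    return 0.0 <= result.icer <= threshold
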