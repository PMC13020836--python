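"""Health states of the knee-osteoarthritis disease model.

The model follows a cohort of Kellgren-Lawrence (KL) grade II knee
osteoarthritis patients through eight aggregate health states: Healthy,
KL I-IV (increasing radiographic severity), total knee replacement (TKR),
revision of a TKR (TKRR), and Death.  Severity is ordered
Healthy < KL I < KL II < KL III < KL IV < TKR < TKRR; "decline" means a
move towards the more severe end of that chain.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Aggregate state names in severity order (Death last, absorbing).
SEVERITY_CHAIN = ["Healthy", "KL_I", "KL_II", "KL_III", "KL_IV", "TKR", "TKRR"]
DEATH = "Death"
STATE_NAMES = SEVERITY_CHAIN + [DEATH]

#: The pre-surgical disease chain: the collapse rule for multi-step decline
#: operates on these states only; surgery and death are reachable from any
#: of them without counting as a "multi-step" decline.
DISEASE_CHAIN = ["Healthy", "KL_I", "KL_II", "KL_III", "KL_IV"]

ARMS = ["SoC", "hiMSC_auto", "hiMSC_manual", "hiMSC_EV_auto", "hiMSC_EV_manual"]
TREATED_ARMS = [a for a in ARMS if a != "SoC"]
PERSPECTIVES = ["hospital", "societal"]


@dataclass(frozen=True)
class HealthState:
    """One aggregate health state, optionally a TKR tunnel-year copy.

    ``tunnel_year`` (years since TKR surgery, 1-based) is present iff the
    state is TKR: the yearly revision risk depends on time since surgery,
    so the cohort engine expands TKR into one copy per tunnel year.
    """

    name: str
    tunnel_year: int | None = None

    def __post_init__(self) -> None:
        if self.name not in STATE_NAMES:
            raise ValueError(f"unknown health state {self.name!r}")
        if (self.tunnel_year is not None) != (self.name == "TKR"):
            raise ValueError("tunnel_year must be present iff the state is TKR")
        if self.tunnel_year is not None and self.tunnel_year < 1:
            raise ValueError("tunnel_year must be a positive integer")


def severity_index(name: str) -> int:
    """Position of a state on the severity chain (Death is beyond TKRR)."""
    if name == DEATH:
        return len(SEVERITY_CHAIN)
    return SEVERITY_CHAIN.index(name)


def is_decline(src: str, dst: str) -> bool:
    """True when a move goes to a strictly more severe non-Death state."""
    if dst == DEATH or src == DEATH:
        return False
    return severity_index(dst) > severity_index(src)
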