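"""Battery-budget arithmetic for the wearable module.

A constant-current linear discharge model: remaining capacity
C_rem = C_init − I_dis·t, and endurance t_max = C_init / I_avg.  No
voltage-curve or Peukert correction — adequate for what-if comparisons of
operating modes, not for battery chemistry.

Three named presets cover the measured/estimated average currents of the
device's operating modes: ``full`` (GNSS tracking + radio connected,
72 mA), ``idle`` (radio idle, GNSS on demand, 20 mA) and
``wake_on_shake`` (MCU asleep until the IMU wakes it, 5 mA), all on the
2000 mAh pack.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

__all__ = [
    "PowerSpec",
    "CapacityResult",
    "remaining_capacity",
    "operating_time",
    "SCENARIO_PRESETS",
    "DEFAULT_CAPACITY_MAH",
]

DEFAULT_CAPACITY_MAH = 2000.0

#: average discharge current (mA) per operating mode
SCENARIO_PRESETS = {
    "full": 72.0,
    "idle": 20.0,
    "wake_on_shake": 5.0,
}


@dataclass(frozen=True)
class PowerSpec:
    """Initial capacity (mAh), discharge current (mA), elapsed time (h)."""

    c_init: float
    i_dis: float
    t: float

    def __post_init__(self) -> None:
        if self.c_init <= 0:
            raise ValueError("c_init must be strictly positive")
        if self.i_dis <= 0:
            raise ValueError("i_dis must be strictly positive")
        if self.t < 0:
            raise ValueError("t must be non-negative")


@dataclass(frozen=True)
class CapacityResult:
    """Remaining capacity, as mAh and as percent of the initial capacity.

    When the demanded discharge exceeds the pack, ``depleted`` is set and
    ``depleted_at_h`` holds the time the pack actually ran out; the
    remaining capacity is reported as 0, never negative.
    """

    remaining_mah: float
    percent: float
    depleted: bool = False
    depleted_at_h: Optional[float] = None


def remaining_capacity(spec: PowerSpec) -> CapacityResult:
    """C_rem = C_init − I_dis·t, with explicit depletion handling."""
    used = spec.i_dis * spec.t
    if used > spec.c_init:
        return CapacityResult(
            remaining_mah=0.0, percent=0.0, depleted=True,
            depleted_at_h=spec.c_init / spec.i_dis,
        )
    rem = spec.c_init - used
    return CapacityResult(remaining_mah=rem,
                          percent=100.0 * rem / spec.c_init)


def operating_time(c_init: float, i_avg: float) -> float:
    """Hours until depletion at a constant average current."""
    if i_avg <= 0:
        raise ValueError("i_avg must be strictly positive")
    if c_init <= 0:
        raise ValueError("c_init must be strictly positive")
    return c_init / i_avg
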