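"""Transport-distance budget for the water-column methanotroph stock.

Treats the water column above a seep region as a box of depth z (m) swept
by a current of speed v (m s^-1), continuously seeded from below by a
bubble-mediated flux F of methanotroph cells (cells m^-2 s^-1). The
along-current distance over which that input accumulates to the observed
water-column concentration c (cells m^-3) is

    delta_x = c * v * z / F

and the corresponding transport time t = delta_x / v = c * z / F is
independent of the current speed. Growth, mortality and dispersion are
deliberately excluded: the budget asks only how far upstream seep input
must extend to explain the standing stock.
"""

from __future__ import annotations

from dataclasses import dataclass

SECONDS_PER_DAY = 86_400.0
SECONDS_PER_HOUR = 3_600.0


@dataclass
class BudgetScenario:
    """Inputs of the transport-distance budget (all strictly positive)."""

    c: float   # water-column MOB concentration, cells m^-3
    v: float   # current velocity, m s^-1
    z: float   # water depth, m
    f: float   # sediment-born MOB flux, cells m^-2 s^-1

    def __post_init__(self):
        for name in ("c", "v", "z", "f"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class BudgetResult:
    delta_x: float        # m
    transport_time: float  # s

    @property
    def delta_x_km(self) -> float:
        return self.delta_x / 1000.0

    @property
    def transport_time_hours(self) -> float:
        return self.transport_time / SECONDS_PER_HOUR

    @property
    def transport_time_days(self) -> float:
        return self.transport_time / SECONDS_PER_DAY


def transport_distance(s: BudgetScenario) -> BudgetResult:
    """delta_x = c v z / F and the transport time delta_x / v."""
    delta_x = s.c * s.v * s.z / s.f
    return BudgetResult(delta_x=delta_x, transport_time=delta_x / s.v)


def flux_from_areal(areal_cells_m2_d: float) -> float:
    """Convert an areal flux (cells m^-2 d^-1) to per-second units."""
    if areal_cells_m2_d < 0:
        raise ValueError("areal flux must be non-negative")
    return areal_cells_m2_d / SECONDS_PER_DAY
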