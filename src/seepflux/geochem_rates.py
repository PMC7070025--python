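"""Methane oxidation (MOx) rate calculator for tracer incubations.

Water samples are incubated with a trace amount of radiolabelled methane;
the fraction of tracer recovered in the oxidized pool over the incubation
time gives a first-order rate constant k (d^-1), and multiplying by the in
situ methane concentration gives the methane oxidation rate
MOx = k * [CH4] (nmol L^-1 d^-1). Dividing by the methanotroph abundance
yields a cell-specific rate (fmol cell^-1 h^-1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass


@dataclass
class TracerIncubation:
    """One radiotracer incubation.

    activity_product / activity_total is the fraction of tracer oxidized;
    blank_activity (optional) is subtracted from the product pool before
    forming the fraction (hook for killed-control correction).
    """

    activity_product: float     # counts in the oxidized pool
    activity_total: float       # total tracer counts
    incubation_time: float      # days
    ch4_concentration: float    # nmol L^-1
    blank_activity: float = 0.0

    def __post_init__(self):
        if self.activity_total <= 0:
            raise ValueError("activity_total must be positive")
        if not 0 <= self.activity_product <= self.activity_total:
            raise ValueError("activity_product must lie in [0, activity_total]")
        if self.incubation_time <= 0:
            raise ValueError("incubation_time must be positive")
        if self.ch4_concentration < 0:
            raise ValueError("ch4_concentration must be non-negative")


def rate_constant(inc: TracerIncubation) -> float:
    """First-order rate constant k (d^-1): fraction oxidized per day."""
    fraction = max(inc.activity_product - inc.blank_activity, 0.0) / inc.activity_total
    if fraction >= 1.0:
        warnings.warn("tracer fully oxidized: rate constant saturated, "
                      "k is a lower bound")
    return fraction / inc.incubation_time


def mox_rate(k_per_day: float, ch4_nmol_l: float) -> float:
    """MOx (nmol L^-1 d^-1) = k * [CH4]."""
    if k_per_day < 0 or ch4_nmol_l < 0:
        raise ValueError("rate constant and methane concentration must be >= 0")
    return k_per_day * ch4_nmol_l


def cell_specific_rate(mox_nmol_l_d: float, mob_cells_ml: float) -> float:
    """Per-cell oxidation rate (fmol cell^-1 h^-1).

    nmol L^-1 d^-1 -> fmol L^-1 d^-1 (x 1e6), divided by cells L^-1
    (mob x 1e3) and by 24 h d^-1.
    """
    if mob_cells_ml <= 0:
        raise ValueError("MOB abundance must be positive")
    return (mox_nmol_l_d * 1e6) / (mob_cells_ml * 1e3) / 24.0
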