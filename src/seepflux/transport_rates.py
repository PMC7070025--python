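"""Bubble Catcher transport rates: corrections and normalizations.

A Bubble Catcher deployment yields cell concentrations (DAPI totals and
CARD-FISH methanotroph counts) in the residual water after capturing a
known gas volume over a known duration. This module converts those raw
concentrations into the four transport-rate normalizations used to compare
vents:

* cells per mL of emitted gas          (per_gas)
* cells per second                     (per_time = per_gas * Q)
* cells per cm^2 of bubble surface     (per_area = per_time / A)
* cells per m^2 of seabed per day      (areal = per_time * vent_density * 86400)

after subtracting pre-deployment background and the contamination level
measured in bubble-free "BC control" deployments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

SECONDS_PER_DAY = 86_400.0


@dataclass
class CatcherExperiment:
    """One Bubble Catcher deployment with its measured concentrations.

    Concentrations are cells per mL of residual water; gas volume in litres;
    vent_density in vents m^-2 (vent experiments only). Control experiments
    capture no gas (gas_volume_l == 0).
    """

    id: str
    kind: str                       # vent / engineered / control
    gas_volume_l: float
    duration_min: float
    residual_water_volume_ml: float
    conc_total_sample: float
    conc_mob_sample: float
    conc_total_predeploy: float = 0.0
    conc_mob_predeploy: float = 0.0
    control_conc_total: float = 0.0
    control_conc_mob: float = 0.0
    vent_density: float = np.nan    # vents m^-2

    def __post_init__(self):
        if self.kind not in ("vent", "engineered", "control"):
            raise ValueError(f"unknown experiment kind {self.kind!r}")
        if self.kind == "control" and self.gas_volume_l != 0:
            raise ValueError("control experiments must have gas_volume = 0")
        for name in ("gas_volume_l", "duration_min", "residual_water_volume_ml"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class TransportRates:
    """The four normalizations for one cell class (total or MOB)."""

    per_gas: float      # cells mL_gas^-1
    per_time: float     # cells s^-1
    per_area: float     # cells cm^-2 (NaN if no A available)
    areal: float        # cells m^-2 d^-1 (NaN without vent density)
    floored: bool = False  # corrected concentration hit the zero floor


def volumetric_flow(gas_volume_l: float, duration_min: float) -> float:
    """Q (mL s^-1) from collected gas volume (L) and duration (min)."""
    if gas_volume_l < 0:
        raise ValueError("gas volume must be non-negative")
    if duration_min <= 0:
        raise ValueError("duration must be positive")
    return 1000.0 * gas_volume_l / (60.0 * duration_min)


def corrected_concentration(sample: float, predeploy: float, control: float):
    """Sample concentration minus pre-deployment background minus the
    control (contamination) level, floored at zero.

    Returns (corrected cells mL^-1, floored flag); negative differences are
    physically impossible cell counts and are floored with a warning.
    """
    for v in (sample, predeploy, control):
        if v < 0:
            raise ValueError("concentrations must be non-negative")
    corrected = sample - predeploy - control
    if corrected < 0:
        warnings.warn(
            f"corrected concentration negative ({corrected:.3g}); floored to 0")
        return 0.0, True
    return corrected, False


def normalize(conc_corrected: float, residual_water_volume_ml: float,
              gas_volume_ml: float, q_ml_s: float,
              a_cm2_s: float = None, a_over_q: float = None,
              vent_density: float = None, floored: bool = False) -> TransportRates:
    """Chain a corrected concentration through the four normalizations.

    total transported cells = concentration x residual water volume;
    per_gas = total / gas volume; per_time = per_gas x Q;
    per_area = per_time / A with A given directly or as (A/Q) x Q;
    areal = per_time x vent_density x 86400.
    """
    if gas_volume_ml <= 0:
        raise ValueError("gas volume must be positive to normalize per gas")
    total_cells = conc_corrected * residual_water_volume_ml
    per_gas = total_cells / gas_volume_ml
    per_time = per_gas * q_ml_s
    if a_cm2_s is None and a_over_q is not None:
        a_cm2_s = a_over_q * q_ml_s
    per_area = per_time / a_cm2_s if a_cm2_s else np.nan
    areal = (per_time * vent_density * SECONDS_PER_DAY
             if vent_density is not None and np.isfinite(vent_density) else np.nan)
    return TransportRates(per_gas=per_gas, per_time=per_time,
                          per_area=per_area, areal=areal, floored=floored)


def enrichment_factor(vent_conc: float, reference_conc: float) -> float:
    """Ratio of vent to reference (e.g. control) concentration."""
    if reference_conc <= 0:
        raise ValueError("reference concentration must be positive")
    return vent_conc / reference_conc


def experiment_rates(exp: CatcherExperiment, a_over_q: float = None,
                     a_cm2_s: float = None) -> dict:
    """Full chain for one experiment: Q, corrections, and TransportRates for
    total cells and MOB. A/Q from the vent-matched bubble-imaging ratio may
    be supplied to derive the surface-area normalization."""
    q = volumetric_flow(exp.gas_volume_l, exp.duration_min)
    out = {"id": exp.id, "kind": exp.kind, "q_ml_s": q}
    for label, sample, pre, ctrl in (
            ("total", exp.conc_total_sample, exp.conc_total_predeploy, exp.control_conc_total),
            ("mob", exp.conc_mob_sample, exp.conc_mob_predeploy, exp.control_conc_mob)):
        conc, floored = corrected_concentration(sample, pre, ctrl)
        out[label] = normalize(conc, exp.residual_water_volume_ml,
                               exp.gas_volume_l * 1000.0, q,
                               a_cm2_s=a_cm2_s, a_over_q=a_over_q,
                               vent_density=exp.vent_density, floored=floored)
    return out


def rates_table(experiments, a_over_q_by_id: dict = None) -> pd.DataFrame:
    """Tidy rates table: one row per experiment x {total, mob}."""
    rows = []
    for exp in experiments:
        if exp.kind == "control":
            continue
        aq = (a_over_q_by_id or {}).get(exp.id)
        res = experiment_rates(exp, a_over_q=aq)
        for label in ("total", "mob"):
            tr: TransportRates = res[label]
            rows.append({"id": exp.id, "kind": exp.kind, "cells": label,
                         "q_ml_s": res["q_ml_s"], "per_gas": tr.per_gas,
                         "per_time": tr.per_time, "per_area": tr.per_area,
                         "areal": tr.areal, "floored": tr.floored})
    return pd.DataFrame(rows)


def pooled_control_mean(experiments, field: str = "conc_total_sample",
                        site_of=None, site: str = None) -> float:
    """Mean concentration over control experiments; with ``site_of`` (a
    mapping id -> site) and ``site`` given, only that site's controls are
    pooled (site-matched correction), else all controls."""
    vals = []
    for exp in experiments:
        if exp.kind != "control":
            continue
        if site is not None and site_of is not None and site_of.get(exp.id) != site:
            continue
        vals.append(getattr(exp, field))
    if not vals:
        raise ValueError("no matching control experiments")
    return float(np.mean(vals))
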