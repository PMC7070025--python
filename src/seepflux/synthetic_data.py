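"""Synthetic generators for seep-bubble streams, Bubble Catcher experiments
and cross-compartment taxon abundance tables.

Every downstream stage of the pipeline (emission size distributions,
transport-rate normalization, community pattern classification) is exercised
against data from these generators, whose ground truth is known exactly, so
parameter recovery can be asserted rather than eyeballed.

The bubble-stream generator emulates video observations of a rising bubble
stream: bubbles arrive as an (optionally pulsed) Poisson process, draw a
radius from a mixture of Gaussian size modes, rise at the clean- or
dirty-bubble terminal velocity plus an upwelling offset, and are recorded
once per video frame while inside a finite field of view. One output row per
(track, frame), with best-fit-ellipse axes consistent with the volume-
equivalent spherical radius.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rise_velocity import rise_velocity

SAMPLE_GROUPS = ("sediment", "BC_vent", "water_column", "BC_engineered", "control")

TRACK_COLUMNS = ["track_id", "frame", "t_s", "x_cm", "a_um", "b_um"]


# ---------------------------------------------------------------------------
# bubble streams
# ---------------------------------------------------------------------------

@dataclass
class StreamSpec:
    """Parameters of a synthetic bubble stream.

    modes: list of (mu_r um, sigma_r um, weight) Gaussian size modes,
    weights summing to 1. emission_rate is the mean arrival rate
    (bubbles s^-1); pulse_period > 0 switches on a square-wave pulse whose
    "on" phase has rate emission_rate * pulse_amplitude (duty cycle chosen so
    the mean rate is preserved). fov_height is the imaged vertical extent.
    """

    modes: list = field(default_factory=lambda: [(1500.0, 150.0, 1.0)])
    emission_rate: float = 50.0        # bubbles s^-1, mean
    pulse_period: float = 0.0          # s; 0 = steady emission
    pulse_amplitude: float = 1.0       # multiplicative, >= 1
    duration: float = 10.0             # s
    fps: float = 60.0                  # frames s^-1
    fov_height: float = 5.0            # cm
    cleanliness: str = "clean"
    v_up: float = 0.0                  # cm s^-1 upwelling offset
    tilt_deg: float = 0.0              # camera tilt
    noise_sd_r: float = 0.0            # um, per-detection radius jitter
    aspect_ratio: float = 1.2          # mean a/b of the oblate spheroid
    seed: int = 0

    def validate(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.fov_height <= 0:
            raise ValueError("fov_height must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not self.modes:
            raise ValueError("at least one size mode required")
        w = sum(m[2] for m in self.modes)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"mode weights must sum to 1 (got {w})")
        if any(m[0] <= 0 for m in self.modes):
            raise ValueError("mode radii must be positive")
        if self.pulse_amplitude < 1.0:
            raise ValueError("pulse_amplitude must be >= 1")
        if self.emission_rate < 0:
            raise ValueError("emission_rate must be non-negative")


def _pulse_factor(t: np.ndarray, spec: StreamSpec) -> np.ndarray:
    """Square-wave pulse factor normalised to unit mean rate.

    With amplitude a and duty cycle 1/a, the on-phase rate is a*lambda and
    the off-phase rate 0, so the mean stays at emission_rate.
    """
    if spec.pulse_period <= 0 or spec.pulse_amplitude <= 1.0:
        return np.ones_like(t)
    duty = 1.0 / spec.pulse_amplitude
    phase = np.mod(t, spec.pulse_period) / spec.pulse_period
    return np.where(phase < duty, spec.pulse_amplitude, 0.0)


def sample_radii_gaussian_mixture(modes, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n radii (um) from a Gaussian mixture, truncated at r > 0."""
    mus = np.array([m[0] for m in modes])
    sigmas = np.array([m[1] for m in modes])
    weights = np.array([m[2] for m in modes])
    comp = rng.choice(len(modes), size=n, p=weights / weights.sum())
    r = rng.normal(mus[comp], sigmas[comp])
    # redraw the (rare) non-positive samples rather than clipping
    bad = r <= 0
    while bad.any():
        r[bad] = rng.normal(mus[comp[bad]], sigmas[comp[bad]])
        bad = r <= 0
    return r


def sample_radii_power_law(n: int, rng: np.random.Generator,
                           exponent: float = 3.5,
                           r_min: float = 500.0, r_max: float = 2600.0) -> np.ndarray:
    """Draw n radii (um) from a truncated power law p(r) ~ r^-exponent.

    Inverse-CDF sampling; the fragmentation-dominated ("major") plume shape.
    """
    if r_min <= 0 or r_max <= r_min:
        raise ValueError("need 0 < r_min < r_max")
    u = rng.uniform(size=n)
    if abs(exponent - 1.0) < 1e-12:
        return r_min * (r_max / r_min) ** u
    a = 1.0 - exponent
    return (r_min**a + u * (r_max**a - r_min**a)) ** (1.0 / a)


def simulate_bubble_stream(spec: StreamSpec) -> pd.DataFrame:
    """Simulate per-frame detections of a rising bubble stream.

    Returns a table with one row per (track, frame):
    columns track_id, frame, t_s, x_cm (apparent vertical position),
    a_um, b_um (best-fit-ellipse semi-axes). Deterministic given spec.seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    # inhomogeneous Poisson arrivals by thinning a homogeneous stream at the
    # peak rate
    peak = spec.emission_rate * max(spec.pulse_amplitude, 1.0)
    n_cand = rng.poisson(peak * spec.duration)
    t_cand = np.sort(rng.uniform(0.0, spec.duration, size=n_cand))
    keep = rng.uniform(size=n_cand) * max(spec.pulse_amplitude, 1.0) <= _pulse_factor(t_cand, spec)
    t_arrive = t_cand[keep]
    n = t_arrive.size

    r_true = sample_radii_gaussian_mixture(spec.modes, n, rng)
    v = rise_velocity(r_true, spec.cleanliness) + spec.v_up  # cm s^-1, true vertical
    if np.any(v <= 0):
        raise ValueError("non-positive rise velocity; check v_up")

    cos_tilt = np.cos(np.deg2rad(spec.tilt_deg))
    if cos_tilt <= 0:
        raise ValueError("tilt must be < 90 degrees")

    rows = []
    dt = 1.0 / spec.fps
    for i in range(n):
        # frames while the bubble is inside [0, fov_height)
        t_exit = t_arrive[i] + spec.fov_height / v[i]
        f0 = int(np.ceil(t_arrive[i] / dt))
        f1 = int(np.ceil(t_exit / dt))  # exclusive
        if f1 <= f0:
            continue
        frames = np.arange(f0, f1)
        t_f = frames * dt
        x_true = v[i] * (t_f - t_arrive[i])
        r_obs = np.full(frames.size, r_true[i])
        if spec.noise_sd_r > 0:
            r_obs = r_obs + rng.normal(0.0, spec.noise_sd_r, size=frames.size)
        r_obs = np.maximum(r_obs, 1.0)
        # oblate spheroid a = b * e with r^3 = a^2 b  =>  a = r e^(1/3)
        e = spec.aspect_ratio
        a_um = r_obs * e ** (1.0 / 3.0)
        b_um = r_obs * e ** (-2.0 / 3.0)
        rows.append(pd.DataFrame({
            "track_id": i,
            "frame": frames,
            "t_s": t_f,
            "x_cm": x_true / cos_tilt,  # apparent (projected) position
            "a_um": a_um,
            "b_um": b_um,
        }))

    if not rows:
        return pd.DataFrame(columns=TRACK_COLUMNS)
    out = pd.concat(rows, ignore_index=True)
    out["track_id"] = out["track_id"].astype(int)
    out["frame"] = out["frame"].astype(int)
    return out


def emitted_gas_volume(stream: pd.DataFrame) -> float:
    """Total emitted gas volume (mL) of a simulated stream, from per-track
    mean radii: sum over tracks of (4/3) pi r^3. Independent bookkeeping
    oracle for the integrated volumetric flux Q."""
    if stream.empty:
        return 0.0
    r = _track_radii(stream)
    return float(np.sum(4.0 / 3.0 * np.pi * r**3) / 1e12)


def _track_radii(stream: pd.DataFrame) -> np.ndarray:
    r_det = (stream["a_um"] ** 2 * stream["b_um"]) ** (1.0 / 3.0)
    return r_det.groupby(stream["track_id"]).mean().to_numpy()


# ---------------------------------------------------------------------------
# Bubble Catcher experiments
# ---------------------------------------------------------------------------

@dataclass
class CatcherSpec:
    """Ground truth for a synthetic Bubble Catcher deployment.

    true_per_gas_* are the planted transport rates (cells per mL of captured
    gas); predeploy_conc and control_conc are additive contamination levels
    (cells mL^-1 of residual water); counting_cv is the lognormal
    multiplicative counting noise CV (cell counts are positive, hence
    lognormal rather than additive Gaussian).
    """

    true_per_gas_total: float = 1e4    # cells mL_gas^-1
    true_per_gas_mob: float = 1e2      # cells mL_gas^-1
    q: float = 1.0                     # mL s^-1
    duration: float = 60.0             # min
    residual_water_volume: float = 6000.0  # mL
    predeploy_conc: float = 0.0        # cells mL^-1 (total); MOB scaled by mob fraction
    control_conc: float = 0.0          # cells mL^-1
    counting_cv: float = 0.0
    kind: str = "vent"
    vent_density: float = 5.0          # vents m^-2
    seed: int = 0

    def validate(self) -> None:
        if self.residual_water_volume <= 0:
            raise ValueError("residual_water_volume must be positive")
        for name in ("true_per_gas_total", "true_per_gas_mob", "q",
                     "predeploy_conc", "control_conc", "counting_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


def _lognormal_noise(rng: np.random.Generator, cv: float, size=None):
    """Unit-mean multiplicative lognormal noise with coefficient of
    variation cv."""
    if cv <= 0:
        return 1.0 if size is None else np.ones(size)
    s2 = np.log(1.0 + cv**2)
    return rng.lognormal(-0.5 * s2, np.sqrt(s2), size=size)


def simulate_catcher_experiment(spec: CatcherSpec) -> dict:
    """Simulate the measured concentrations of one Bubble Catcher experiment.

    gas_volume = q * duration; the planted per-gas rate appears in the
    residual water as true_per_gas * gas_volume / residual_water_volume,
    on top of pre-deployment and control contamination.
    Returns a record matching the transport_rates.CatcherExperiment schema.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    gas_ml = spec.q * spec.duration * 60.0

    def measured(true_per_gas, contamination):
        conc = true_per_gas * gas_ml / spec.residual_water_volume + contamination
        return conc * _lognormal_noise(rng, spec.counting_cv)

    mob_frac = (spec.true_per_gas_mob / spec.true_per_gas_total
                if spec.true_per_gas_total > 0 else 0.0)
    return {
        "id": f"synthetic-{spec.seed}",
        "kind": spec.kind,
        "gas_volume_l": gas_ml / 1000.0,
        "duration_min": spec.duration,
        "residual_water_volume_ml": spec.residual_water_volume,
        "conc_total_predeploy": spec.predeploy_conc,
        "conc_mob_predeploy": spec.predeploy_conc * mob_frac,
        "conc_total_sample": float(measured(spec.true_per_gas_total,
                                            spec.predeploy_conc + spec.control_conc)),
        "conc_mob_sample": float(measured(spec.true_per_gas_mob,
                                          (spec.predeploy_conc + spec.control_conc) * mob_frac)),
        "control_conc_total": spec.control_conc,
        "control_conc_mob": spec.control_conc * mob_frac,
        "vent_density": spec.vent_density,
    }


# ---------------------------------------------------------------------------
# taxon abundance tables
# ---------------------------------------------------------------------------

@dataclass
class PlantedPattern:
    """A taxon with a known group-presence pattern and abundance tier."""

    taxon_id: str
    present_in: tuple            # subset of SAMPLE_GROUPS
    abundance_tier: float = 100.0  # mean counts per sample where present

    def validate(self) -> None:
        if not self.present_in:
            raise ValueError("present_in must be non-empty")
        unknown = set(self.present_in) - set(SAMPLE_GROUPS)
        if unknown:
            raise ValueError(f"unknown sample groups: {sorted(unknown)}")


def simulate_abundance_table(patterns, samples_per_group: int = 3,
                             noise: float = 0.0, seed: int = 0):
    """Build a (samples x taxa) count table with planted presence patterns.

    Where a taxon is planted, counts are Poisson around its tier (plus one,
    so presence is guaranteed); elsewhere zero, except for sparse noise:
    with probability ``noise`` an absent cell gets a single stray count
    (below any reasonable detection floor).

    Returns (counts DataFrame, sample->group Series).
    """
    patterns = list(patterns)
    if not patterns:
        raise ValueError("at least one pattern required")
    if samples_per_group < 1:
        raise ValueError("samples_per_group must be >= 1")
    ids = [p.taxon_id for p in patterns]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate taxon_id in patterns")
    for p in patterns:
        p.validate()

    rng = np.random.default_rng(seed)
    samples, groups = [], []
    for g in SAMPLE_GROUPS:
        for i in range(samples_per_group):
            samples.append(f"{g}_s{i}")
            groups.append(g)
    counts = np.zeros((len(samples), len(patterns)), dtype=int)
    for j, p in enumerate(patterns):
        for i, g in enumerate(groups):
            if g in p.present_in:
                counts[i, j] = 1 + rng.poisson(p.abundance_tier)
            elif noise > 0 and rng.uniform() < noise:
                counts[i, j] = 1
    table = pd.DataFrame(counts, index=samples, columns=ids)
    group_map = pd.Series(groups, index=samples, name="group")
    return table, group_map
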