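"""Bubble emission size distributions, fluxes and plume classification.

Turns tables of tracked bubble detections (one row per track per video
frame) into the quantities that characterise a seep vent:

* the emission size distribution Phi(r) — bubbles crossing a reference
  plane per second per unit radius — with a multiple-count correction: a
  bubble of radius r rising at V_x(r) through a field of view of height H
  imaged at ``fps`` frames per second is detected H*fps/V_x(r) times, so
  detection counts are converted to emission counts by the factor
  V_x(r)/(H*fps);
* a polynomial model of vertical velocity vs radius, V_x(r), fitted to the
  tracks (correcting for camera tilt), which supplies that correction;
* volumetric gas flux Q (mL s^-1) and bubble surface-area flux A (cm^2 s^-1)
  by integrating Phi(r) over r, and their ratio A/Q (cm^-1) which equals
  3/r32 (Sauter mean radius) and is insensitive to emission pulsing;
* mode fits (Gaussian mixture vs power law) and the major/minor plume
  classification: fragmentation-formed "major" plumes follow a power law,
  grain-size-controlled "minor" plumes show Gaussian modes;
* the upwelling velocity V_up and bubble cleanliness regime, from the offset
  between observed velocities and the clean/dirty terminal-velocity laws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, signal

from .rise_velocity import clean_rise_velocity, dirty_rise_velocity

UM3_TO_ML = 1e-12   # 1 um^3 = 1e-12 mL
UM2_TO_CM2 = 1e-8   # 1 um^2 = 1e-8 cm^2
UM_TO_CM = 1e-4

PULSING_VELOCITY_ERROR = 0.30  # documented relative error of the single
                               # global V_x(r) for strongly pulsing plumes


def equivalent_radius(a_um, b_um):
    """Volume-equivalent spherical radius of an oblate spheroid bubble.

    The best-fit ellipse of a rising bubble has semi-major axis a
    (horizontal) and semi-minor axis b (vertical, the flattened axis);
    rotating about the minor axis gives volume (4/3) pi a^2 b, hence
    r = (a^2 b)^(1/3).
    """
    a = np.asarray(a_um, dtype=float)
    b = np.asarray(b_um, dtype=float)
    if np.any(b <= 0):
        raise ValueError("ellipse axes must be positive")
    if np.any(a < b):
        raise ValueError("semi-major axis a must be >= semi-minor axis b")
    r = (a**2 * b) ** (1.0 / 3.0)
    return float(r) if r.ndim == 0 else r


def tracks_from_observations(obs: pd.DataFrame, use_convex_hull: bool = False) -> pd.DataFrame:
    """Collapse per-frame detections into per-track summaries.

    Per track: mean equivalent radius r (um), observed vertical velocity vx
    (cm s^-1, least-squares slope of x vs t over the whole track — more
    robust to detection jitter than a first/last difference), and n_frames.
    Tracks with a single frame get vx = NaN.

    With use_convex_hull=True, the convex-hull ellipse axes (columns
    a_hull_um/b_hull_um) are used if present.
    """
    a_col, b_col = ("a_hull_um", "b_hull_um") if use_convex_hull else ("a_um", "b_um")
    if a_col not in obs.columns:
        if use_convex_hull:
            raise ValueError("no convex-hull axis columns in observations")
        raise ValueError("observations lack ellipse axis columns a_um/b_um")

    r_det = equivalent_radius(obs[a_col].to_numpy(), obs[b_col].to_numpy())
    df = obs.assign(_r=r_det)

    def _summ(g: pd.DataFrame) -> pd.Series:
        t = g["t_s"].to_numpy()
        x = g["x_cm"].to_numpy()
        if len(g) >= 2:
            vx = np.polyfit(t, x, 1)[0]
        else:
            vx = np.nan
        return pd.Series({"r": g["_r"].mean(), "vx": vx, "n_frames": len(g)})

    out = df.groupby("track_id").apply(_summ, include_groups=False).reset_index()
    out["n_frames"] = out["n_frames"].astype(int)
    return out


# ---------------------------------------------------------------------------
# velocity model
# ---------------------------------------------------------------------------

@dataclass
class VelocityModel:
    """Polynomial V_x(r): tilt-corrected vertical velocity (cm s^-1) as a
    function of equivalent radius (um)."""

    coeffs: np.ndarray          # highest power first (np.polyval order)
    degree: int
    tilt_deg: float
    resid_scale: float          # RMS residual, cm s^-1
    r_range: tuple              # (min, max) radius of the fitted tracks, um
    coeff_se: np.ndarray = field(default=None)  # standard errors, same order

    def __call__(self, r_um):
        return np.polyval(self.coeffs, np.asarray(r_um, dtype=float))


def fit_velocity_model(tracks: pd.DataFrame, degree: int = 2,
                       tilt_deg: float = 0.0) -> VelocityModel:
    """Least-squares polynomial fit of tilt-corrected velocity vs radius.

    Observed velocities are projected by cos(tilt) to correct for camera
    tilt. Raises if there are fewer than degree+1 usable tracks or if the
    fitted V_x(r) is non-positive anywhere on the observed radius range.
    """
    ok = tracks.dropna(subset=["vx"])
    ok = ok[ok["n_frames"] >= 2]
    if len(ok) < degree + 1:
        raise ValueError(
            f"need at least {degree + 1} tracks with defined velocity, got {len(ok)}")
    r = ok["r"].to_numpy(dtype=float)
    v = ok["vx"].to_numpy(dtype=float) * np.cos(np.deg2rad(tilt_deg))
    if np.ptp(r) == 0 and degree >= 1:
        raise ValueError("degenerate design matrix: all radii identical")

    if degree == 0:
        coeffs = np.array([v.mean()])
        n = len(v)
        se = np.array([v.std(ddof=1) / np.sqrt(n)]) if n > 1 else np.array([np.inf])
    else:
        coeffs, cov = np.polyfit(r, v, degree, cov=True)
        se = np.sqrt(np.diag(cov))
    resid = v - np.polyval(coeffs, r)
    resid_scale = float(np.sqrt(np.mean(resid**2)))

    grid = np.linspace(r.min(), r.max(), 256)
    if np.any(np.polyval(coeffs, grid) <= 0):
        raise ValueError("fitted V_x(r) is non-positive on the observed radius range")
    return VelocityModel(coeffs=np.asarray(coeffs), degree=degree, tilt_deg=tilt_deg,
                         resid_scale=resid_scale, r_range=(float(r.min()), float(r.max())),
                         coeff_se=np.asarray(se))


# ---------------------------------------------------------------------------
# emission size distribution
# ---------------------------------------------------------------------------

@dataclass
class EmissionSizeDistribution:
    """Binned emission size distribution Phi(r), bubbles um^-1 s^-1."""

    bin_edges: np.ndarray       # um, length n_bins + 1
    phi: np.ndarray             # bubbles um^-1 s^-1, length n_bins
    duration: float             # analyzed duration, s
    phi_t: np.ndarray = None    # optional (n_windows, n_bins) time-resolved
    window_edges: np.ndarray = None   # s, length n_windows + 1
    pulsing_warning: str = None

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def total_rate(self) -> float:
        """Total emission rate, bubbles s^-1 (integral of Phi over r)."""
        return float(np.sum(self.phi) * self.bin_width)

    def sauter_radius(self) -> float:
        """Sauter mean radius r32 = <r^3>/<r^2> of the distribution, um."""
        r = self.bin_centers
        w = self.phi
        denom = np.sum(w * r**2)
        if denom == 0:
            return np.nan
        return float(np.sum(w * r**3) / denom)


def emission_distribution(observations: pd.DataFrame, velocity_model: VelocityModel,
                          fov_height: float, fps: float, bin_width: float = 100.0,
                          time_window: float = None,
                          duration: float = None) -> EmissionSizeDistribution:
    """Multiple-count-corrected emission size distribution.

    Each detection is one sighting, not one bubble: a bubble of radius r is
    expected in H*fps/V_x(r) consecutive frames. Binning detections by
    radius and correcting, Phi(r) = D * V_x(r) / (H * fps * T * dr) with D
    the detection count in the bin, H the field-of-view height (cm), T the
    analyzed duration (s) and dr the bin width (um).

    ``duration`` defaults to the observed time span. With ``time_window``
    set, a time-resolved Phi(r, t) is also computed per window, still using
    the single global V_x(r); for strongly pulsing plumes this single-model
    assumption carries an estimated ~30% error on Q and A (not on A/Q),
    recorded in ``pulsing_warning``.
    """
    if fov_height <= 0 or fps <= 0:
        raise ValueError("fov_height and fps must be positive")
    if observations.empty:
        edges = np.arange(0.0, 2.0 * bin_width, bin_width)
        return EmissionSizeDistribution(bin_edges=edges, phi=np.zeros(1),
                                        duration=duration or 0.0)

    r_det = equivalent_radius(observations["a_um"].to_numpy(),
                              observations["b_um"].to_numpy())
    t = observations["t_s"].to_numpy(dtype=float)
    if duration is None:
        duration = float(t.max() - t.min() + 1.0 / fps)

    lo = np.floor(r_det.min() / bin_width) * bin_width
    hi = np.ceil(r_det.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])

    r_lo, r_hi = velocity_model.r_range
    margin = bin_width
    counts, _ = np.histogram(r_det, bins=edges)
    for c, d in zip(centers, counts):
        if d > 0 and not (r_lo - margin <= c <= r_hi + margin):
            raise ValueError(
                f"bin centred at {c:.0f} um lies outside the velocity model "
                f"support [{r_lo:.0f}, {r_hi:.0f}] um")

    vx = velocity_model(centers)
    phi = counts * vx / (fov_height * fps * duration * bin_width)

    phi_t = window_edges = warn = None
    if time_window is not None and time_window > 0:
        t0 = t.min()
        # cover the full detection span (bubbles emitted near the end of the
        # record are still in view after `duration`)
        span = max(t.max() - t0, duration)
        n_win = max(1, int(np.ceil(span / time_window + 1e-9)))
        window_edges = t0 + np.arange(n_win + 1) * time_window
        phi_t = np.zeros((n_win, len(centers)))
        for w in range(n_win):
            sel = (t >= window_edges[w]) & (t < window_edges[w + 1])
            cw, _ = np.histogram(r_det[sel], bins=edges)
            phi_t[w] = cw * vx / (fov_height * fps * time_window * bin_width)
        warn = ("time-resolved Phi uses a single global V_x(r); for pulsing "
                f"plumes this carries an estimated {PULSING_VELOCITY_ERROR:.0%} "
                "error on Q and A (not on A/Q)")
        warnings.warn(warn)

    return EmissionSizeDistribution(bin_edges=edges, phi=phi, duration=duration,
                                    phi_t=phi_t, window_edges=window_edges,
                                    pulsing_warning=warn)


# ---------------------------------------------------------------------------
# mode fitting and classification
# ---------------------------------------------------------------------------

def _gaussian_mixture(r, *params):
    out = np.zeros_like(r, dtype=float)
    for i in range(0, len(params), 3):
        a, mu, sigma = params[i:i + 3]
        out += a * np.exp(-0.5 * ((r - mu) / sigma) ** 2)
    return out


def _power_law(r, c, s):
    return c * r ** (-s)


def _aicc(rss: float, n: int, k: int) -> float:
    """Small-sample-corrected Akaike criterion on least-squares residuals."""
    rss = max(rss, 1e-300)
    aic = n * np.log(rss / n) + 2 * k
    if n - k - 1 > 0:
        aic += 2 * k * (k + 1) / (n - k - 1)
    else:
        aic = np.inf
    return aic


@dataclass
class ModeFit:
    """Gaussian-mixture and power-law fits to a binned Phi(r)."""

    gaussian_params: np.ndarray      # (k, 3): amplitude, mu (um), sigma (um)
    gaussian_aicc: float
    power_params: tuple              # (C, exponent s)
    power_aicc: float

    @property
    def mode_radii(self) -> np.ndarray:
        """Detected Gaussian mode radii, sorted ascending (um).

        Components below a tenth of the strongest amplitude are fit
        residue, not detected modes, and are excluded.
        """
        amp = self.gaussian_params[:, 0]
        keep = amp >= 0.1 * amp.max()
        return np.sort(self.gaussian_params[keep, 1])

    @property
    def dominant_mode(self) -> float:
        """Radius of the highest-amplitude Gaussian component (um)."""
        return float(self.gaussian_params[np.argmax(self.gaussian_params[:, 0]), 1])


def fit_modes(dist: EmissionSizeDistribution, max_gaussians: int = 3) -> ModeFit:
    """Fit Gaussian mixtures (1..max_gaussians, chosen by corrected AIC) and
    a power law to the binned distribution; return both with goodness.

    Least squares are weighted by the Poisson-like uncertainty of each bin
    (sigma ~ sqrt(Phi)), so high bins do not dominate; Gaussian mode centres
    are constrained to the observed radius range — a "mode" at or below the
    smallest observed radius is a monotone decay, not a detected mode.
    """
    r = dist.bin_centers
    y = dist.phi
    nz = y > 0
    if nz.sum() < 5:
        raise ValueError("need at least 5 nonzero bins to fit modes")
    n = len(r)
    span = r.max() - r.min()
    sigma = np.sqrt(np.maximum(y, y[nz].min()))

    best_params, best_aicc = None, np.inf
    order = np.argsort(y)[::-1]
    peaks, _ = signal.find_peaks(y)
    peaks = peaks[np.argsort(y[peaks])[::-1]]
    for k in range(1, max_gaussians + 1):
        # initial centres: detected peaks, topped up with highest bins
        cand = list(r[peaks[:k]])
        for idx in order:
            if len(cand) >= k:
                break
            if all(abs(r[idx] - c) > span / (2 * k + 1) for c in cand):
                cand.append(r[idx])
        while len(cand) < k:
            cand.append(r.min() + span * (len(cand) + 0.5) / k)
        p0, lo, hi = [], [], []
        for mu0 in cand[:k]:
            a0 = max(np.interp(mu0, r, y), y.max() * 0.1)
            p0 += [a0, mu0, max(span / (4 * k), dist.bin_width)]
            lo += [0.0, r.min(), dist.bin_width / 4]
            hi += [np.inf, r.max(), 2 * span]
        try:
            popt, _ = optimize.curve_fit(_gaussian_mixture, r, y, p0=p0,
                                         sigma=sigma, bounds=(lo, hi), maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum(((y - _gaussian_mixture(r, *popt)) / sigma) ** 2))
        aicc = _aicc(rss, n, 3 * k)
        if aicc < best_aicc:
            best_aicc, best_params = aicc, np.asarray(popt).reshape(k, 3)
    if best_params is None:
        raise ValueError("Gaussian mixture fit failed for all component counts")

    # power law: log-log regression on nonzero bins for the start, then
    # nonlinear least squares on all bins so both models see the same data
    slope, icpt = np.polyfit(np.log(r[nz]), np.log(y[nz]), 1)
    try:
        (c_pl, s_pl), _ = optimize.curve_fit(
            _power_law, r, y, p0=[np.exp(icpt), -slope], sigma=sigma, maxfev=20000)
        rss_pl = float(np.sum(((y - _power_law(r, c_pl, s_pl)) / sigma) ** 2))
        aicc_pl = _aicc(rss_pl, n, 2)
    except (RuntimeError, ValueError):
        c_pl, s_pl, aicc_pl = np.exp(icpt), -slope, np.inf

    return ModeFit(gaussian_params=best_params, gaussian_aicc=best_aicc,
                   power_params=(float(c_pl), float(s_pl)), power_aicc=aicc_pl)


def classify_plume(fit: ModeFit) -> str:
    """"major" (fragmentation, power-law Phi) if the power law fits better
    than the selected Gaussian mixture, else "minor"; ties break to minor."""
    if fit.power_aicc < fit.gaussian_aicc:
        return "major"
    if fit.power_aicc == fit.gaussian_aicc:
        warnings.warn("power-law and Gaussian fits tie exactly; classifying as minor")
    return "minor"


# ---------------------------------------------------------------------------
# flux integration and upwelling
# ---------------------------------------------------------------------------

@dataclass
class VentFluxSummary:
    """Per-vent fluxes from an emission size distribution."""

    q: float                     # volumetric gas flux, mL s^-1
    a: float                     # surface-area flux, cm^2 s^-1
    a_over_q: float              # cm^-1 (NaN when Q = 0)
    v_up: float = None           # cm s^-1
    cleanliness: str = None      # clean / dirty
    classification: str = None   # major / minor
    q_time_series: np.ndarray = None   # mL s^-1 per window


def integrate_fluxes(dist: EmissionSizeDistribution) -> VentFluxSummary:
    """Q = sum Phi dr (4/3) pi r^3 (um^3 -> mL) and
    A = sum Phi dr 4 pi r^2 (um^2 -> cm^2); A/Q in cm^-1."""
    r = dist.bin_centers
    dr = dist.bin_width

    def _qa(phi):
        q = np.sum(phi * dr * (4.0 / 3.0) * np.pi * r**3) * UM3_TO_ML
        a = np.sum(phi * dr * 4.0 * np.pi * r**2) * UM2_TO_CM2
        return float(q), float(a)

    q, a = _qa(dist.phi)
    a_over_q = a / q if q > 0 else np.nan
    q_t = None
    if dist.phi_t is not None:
        q_t = np.array([_qa(row)[0] for row in dist.phi_t])
    return VentFluxSummary(q=q, a=a, a_over_q=a_over_q, q_time_series=q_t)


def estimate_upwelling(tracks: pd.DataFrame, velocity_model: VelocityModel = None,
                       bin_width: float = 100.0):
    """Upwelling velocity and cleanliness regime from track velocities.

    For each terminal-velocity law (clean, dirty) the per-track offset
    vx - V_b(r) is computed; its median is the candidate upwelling velocity
    V_up and the median absolute deviation around it the residual scale.
    The law with the smaller residual wins. Velocities are tilt-corrected
    using the model's tilt if a model is given.

    Returns (v_up cm s^-1, cleanliness).
    """
    ok = tracks.dropna(subset=["vx"])
    if ok["r"].pipe(lambda s: np.unique(np.floor(s / bin_width))).size < 3:
        raise ValueError("tracks must span at least 3 distinct radius bins")
    tilt = velocity_model.tilt_deg if velocity_model is not None else 0.0
    r = ok["r"].to_numpy(dtype=float)
    vx = ok["vx"].to_numpy(dtype=float) * np.cos(np.deg2rad(tilt))

    best = None
    for law, fn in (("clean", clean_rise_velocity), ("dirty", dirty_rise_velocity)):
        offset = vx - fn(r)
        v_up = float(np.median(offset))
        resid = float(np.median(np.abs(offset - v_up)))
        if best is None or resid < best[2]:
            best = (v_up, law, resid)
    return best[0], best[1]


def analyze_vent(observations: pd.DataFrame, fov_height: float, fps: float,
                 bin_width: float = 100.0, degree: int = 2, tilt_deg: float = 0.0,
                 time_window: float = None, duration: float = None,
                 max_gaussians: int = 3) -> dict:
    """Full per-vent pipeline: tracks -> V_x(r) -> Phi(r) -> modes, fluxes,
    classification and upwelling. Returns a dict of the pieces."""
    tracks = tracks_from_observations(observations)
    model = fit_velocity_model(tracks, degree=degree, tilt_deg=tilt_deg)
    dist = emission_distribution(observations, model, fov_height=fov_height,
                                 fps=fps, bin_width=bin_width,
                                 time_window=time_window, duration=duration)
    fluxes = integrate_fluxes(dist)
    try:
        modes = fit_modes(dist, max_gaussians=max_gaussians)
        fluxes.classification = classify_plume(modes)
    except ValueError:
        modes = None
    try:
        fluxes.v_up, fluxes.cleanliness = estimate_upwelling(tracks, model)
    except ValueError:
        pass
    return {"tracks": tracks, "velocity_model": model, "distribution": dist,
            "mode_fit": modes, "fluxes": fluxes}
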