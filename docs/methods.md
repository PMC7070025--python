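# Methods

This note records the models, parameter choices and numerical decisions
behind `seepflux`, and what the synthetic-data tests do and do not
demonstrate about real observations.

## Bubble stream model and emission size distribution

A seep vent is modelled as a point source emitting bubbles whose radii are
drawn from a mixture of Gaussian size modes (minor, grain-size-controlled
plumes) or a truncated power law (major, fragmentation-driven plumes).
Arrivals follow an inhomogeneous Poisson process; pulsing is a square wave
of period `pulse_period` whose on-phase rate is `pulse_amplitude` times the
mean with duty cycle 1/`pulse_amplitude`, so the mean emission rate is
preserved. The square wave reproduces the few-second bubble pulses seen at
minor vents without asserting any particular within-pulse arrival law,
which the observations do not constrain.

Each bubble rises at the terminal velocity of its size and surfactant
regime plus a constant upwelling offset `v_up`, and is recorded once per
frame while inside a field of view of height `fov_height` (default 5 cm —
an instrument property that must be supplied with real track data) at
`fps` frames per second (default 60, the video digitization rate). Camera
tilt scales apparent displacements by 1/cos(tilt); the analysis multiplies
observed velocities by cos(tilt) to undo it. Bubble outlines are oblate
spheroids of aspect ratio a/b = 1.2 flattened along the vertical axis, so
the volume-equivalent radius is r = (a²b)^(1/3); per-detection radius
jitter is Gaussian with standard deviation `noise_sd_r`.

The emission size distribution corrects detection counts for multiple
sightings: a bubble of radius r is seen H·fps/V_x(r) times, so
Φ(r) = D·V_x(r)/(H·fps·T·Δr) per radius bin (Δr default 100 µm, Φ
normalized per µm). V_x(r) is a least-squares polynomial (default degree 2)
in radius, fitted to per-track velocities; the per-track velocity is the
least-squares slope of position against time over the whole track, which
is less sensitive to detection jitter than a first-to-last difference. The
fit refuses models that go non-positive anywhere on the observed radius
range. A single global V_x(r) is used even when Φ is computed
time-resolved; for strongly pulsing plumes, where V_x varies with time,
this is known to carry an error of roughly 30% on Q and A (not on A/Q),
and the distribution object carries that warning rather than attempting a
correction.

Fluxes integrate the binned distribution at bin centres:
Q = ΣΦΔr(4/3)πr³ (µm³→mL: ÷10¹²) and A = ΣΦΔr4πr² (µm²→cm²: ÷10⁸). For any
distribution A/Q = 3/r₃₂ with r₃₂ the Sauter mean radius, an identity the
tests assert exactly; it is the reason A/Q is stable under pulsing and can
be transferred from imaging to Bubble Catcher flows measured at other
times.

## Terminal rise velocity laws

Clean (surfactant-free) bubbles: the smaller of the Hadamard–Rybczynski
creeping-flow velocity V = g·r²·ρ/(3µ) and the Mendelson wave-analogy
velocity V = √(σ/(ρr) + g·r), with ρ = 1025 kg m⁻³, µ = 1.09·10⁻³ Pa s,
σ = 0.073 N m⁻¹, g = 9.81 m s⁻². Dirty (surfactant-coated) bubbles behave
as rigid spheres: the drag balance V = √(8gr/(3C_d)) with Schiller–Naumann
drag C_d = (24/Re)(1 + 0.15·Re^0.687) solved by fixed-point iteration, and
capped at the Davies–Taylor spherical-cap velocity 0.711·√(2gr) that large
deforming contaminated bubbles approach. Over the 0.2–3 mm radius range
relevant here the clean curve lies above the dirty curve, clean velocities
peak near r ≈ 500 µm at ~38 cm s⁻¹ and settle to 23–25 cm s⁻¹ at
millimetre radii, and the dirty curve rises monotonically — the qualitative
features the upwelling/cleanliness estimator relies on. Any standard
parameterization with these features would serve; coefficient-level
accuracy matters only for the absolute value of V_up.

The upwelling estimator computes per-track offsets vx − V_b(r; law) for
each law, takes the median as the candidate V_up and the median absolute
deviation about it as the residual scale, and returns the law with the
smaller residual. It requires tracks spanning at least three 100 µm radius
bins, since a single size class cannot distinguish an offset from a wrong
law.

## Mode fitting and plume classification

Gaussian mixtures with 1..3 components and a two-parameter power law
C·r^(−s) are both fitted to the binned Φ(r) by nonlinear least squares,
weighted by the Poisson-like bin uncertainty (σ ∝ √Φ, floored at the
smallest nonzero bin) so that the tallest bins do not dominate. The
mixture size is selected by the small-sample-corrected Akaike criterion
(AICc) on the weighted residuals; mode centres are constrained to the
observed radius range, since a "mode" at or below the smallest observed
radius is simply a monotone decay. A plume is classified *major* when the
power law's AICc beats the selected mixture's, *minor* otherwise; an exact
tie goes to minor with a warning. Components below a tenth of the
strongest amplitude are treated as fit residue and excluded from the
reported mode radii. With ≥ 2000 bubbles, planted mode radii are recovered
within 5% and classification accuracy exceeds 95% over seeded replicates
of both plume kinds.

## Bubble Catcher transport rates

Measured concentrations (cells per mL of residual Catcher water) are
corrected by subtracting first the pre-deployment concentration, then the
control level measured in bubble-free deployments; the subtraction order
is fixed for reproducibility though immaterial for the linear correction.
Negative corrected concentrations are floored at zero and flagged, as cell
counts cannot be negative. Controls are site-matched by default, with a
pooled-mean option. The normalization chain is exact bookkeeping:
total cells = concentration × residual volume; per mL of gas = total ÷ gas
volume; per second = per-gas × Q (Q = collected volume ÷ duration); per
cm² = per-second ÷ A, with A taken as (A/Q) × Q using the vent-matched
imaging ratio when A is not measured directly; per m² of seabed per day =
per-second × vent density × 86 400.

The synthetic Catcher generator plants true per-gas rates and adds
pre-deployment and control contamination plus multiplicative lognormal
counting noise of a given CV (cell counts are positive, so noise is
multiplicative, and the lognormal is parameterized to unit mean so it
introduces no bias). With zero noise the round trip through the correction
and normalization chain recovers the planted rates exactly; with noise the
estimator is unbiased, with error scaling as CV/√replicates.

## Transport-distance budget

Δx = c·v·z/F treats the water column as a box of depth z swept at speed v
and continuously seeded from below at flux F, and asks over what upstream
distance that input must have accumulated to produce concentration c. The
transport time Δx/v = c·z/F is independent of v. Growth (MOB division
times of days), mortality, dispersion and deposition are deliberately
excluded; the budget is an order-of-magnitude consistency argument, not a
population model. Default scenario values (c = 10⁹ cells m⁻³, v =
0.1 m s⁻¹, z = 10–16 m, F = 1.38 × 10⁶ cells m⁻² s⁻¹ strong /
7.1 × 10⁸ cells m⁻² d⁻¹ weak) correspond to the shallow coastal setting
the package targets. Full-precision and presentation-rounded (1
significant figure) values are both reported; tests compare full
precision.

## Methane oxidation rates

The tracer incubation model is first order: the fraction of tracer
recovered in the oxidized pool divided by the incubation time is the rate
constant k (d⁻¹), and MOx = k·[CH₄]. A saturation warning fires when the
tracer is fully consumed (k is then a lower bound). An optional blank
activity is subtracted from the product pool before forming the fraction,
as a hook for killed-control corrections that the core calculation leaves
out. Cell-specific rates convert nmol L⁻¹ d⁻¹ to fmol cell⁻¹ h⁻¹ against a
MOB abundance in cells mL⁻¹; the per-cell unit reading is adopted because
a volumetric unit would make the quantity independent of abundance.

## Community transport patterns

Taxon tables are samples × taxa counts with each sample assigned to one of
five groups (sediment, BC vent, water column, BC engineered, control).
Processing order is fixed and idempotent: (1) every taxon with any nonzero
count in any control sample is removed — the strictest reading of the
contamination rule, a deliberate default since a contamination floor would
need calibration data; (2) relative abundances are recomputed on the
retained taxa; (3) taxa present in fewer than k (default 2) non-control
groups are dropped; (4) each taxon's presence set over the four
non-control groups is labelled (all_groups; bentho_pelagic = sediment +
BC vent + water column; transported_not_established = sediment + BC vent;
sediment_only; water_associated = water column and/or BC engineered
without sediment; other). Presence means group-mean relative abundance
above a detection floor, default 0 (presence/absence); a nonzero floor is
available for noisy data, where near-empty samples can otherwise inflate
relative abundances. Group means are arithmetic means over the group's
samples, and the denominator can optionally be restricted to a taxon
subset (e.g. methanotroph reads only).

## What the synthetic tests do and do not show

The generators reproduce the structural features the pipeline's
correctness depends on — finite field of view with multiple counting,
size-dependent rise velocities, pulsed arrivals, additive contamination
with multiplicative counting noise, block-structured presence patterns —
with known ground truth, so recovery can be asserted. They do not emulate
manual-tracking errors (missed or split tracks), non-spheroidal bubble
shapes or wobble-induced velocity oscillations, bubble dissolution over
the imaged height, temporal drift in contamination, compositional noise in
amplicon counts, or taxonomic misannotation. Passing tests therefore
demonstrate that the estimators are correct and unbiased under the stated
model, not that the model captures every feature of field data.

## Problem sizes and numerics

Simulation-backed tests use streams of ~1000–2500 bubbles and 100-seed
classification sweeps, sizes at which Monte-Carlo error is comfortably
below the asserted tolerances (mode recovery 5%, volume conservation 5%,
classification ≥ 95%). Unit conversions are fixed constants (µm³→mL ÷10¹²,
µm²→cm² ÷10⁸, d→s ×86 400) covered by closed-form tests. Degenerate inputs
have defined behaviour throughout: empty observation tables give Φ ≡ 0 and
zero fluxes with A/Q reported as missing; all-zero distributions refuse
mode fitting; zero reference concentrations, non-positive budget
parameters and axis-order violations raise validation errors.
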