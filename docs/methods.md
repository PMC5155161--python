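# Methods

This note documents the models implemented in `spaint`, the defaults chosen
where the design was open, and what the synthetic-data generator does and
does not emulate.

## Optical model

A blazed transmission grating (default 300 grooves/mm, 8.6° blaze) sits a
distance D = 20 mm before the detector.  The first-order displacement of a
wavelength λ follows the grating equation, sin θ₁ = λ/d, projected onto the
chip: Δ = D·tan θ₁ / a_chip with a_chip = 16 μm.  Over the 480–760 nm
detection passband this is nearly linear (≤ 0.5 px deviation from the
best-fit line), so both the simulator's ground-truth dispersion and the
fitted calibration use the linear form

    Z₀Z₁ = β₀ + β₁·λ + β₂·x + β₃·y ,

where the small β₂, β₃ slopes (defaults 0.0015 and 0.002 px/px in the
simulator) model grating aberration across the field of view.  The
dispersion axis is +y (first order below the spatial region); axis and sign
are fixed by the frame-stack layout, with the spatial region occupying the
top `spatial_height_px` rows.

Photon budget: the grating diverts ~60% of the emission into the zeroth
(spatial) order; the diffracted ~40% loses ~30% to grating transmission
inefficiency, so the first order receives (1 − 0.60)(1 − 0.30) = 28% of
emitted photons.  Both fractions are configurable on `GratingGeometry`.

## Camera model

The EMCCD readout is simulated as: Poisson photoelectrons with QE = 0.9,
gamma-distributed electron multiplication (shape = electron count, scale =
EM gain 250), conversion gain 1/9 ADU per output electron, a 100 ADU
baseline, additive Gaussian read noise (5 ADU rms), and clipping to the
16-bit range.  The gamma approximation to the EM register is the standard
high-gain limit; it reproduces the factor-2 excess noise variance.  The
total conversion gain GainTotal = GainCamera × GainEM × QE = 25 ADU per
incident photon; spot integrals in ADU divided by GainTotal are photon
counts.  The effective sample-plane pixel is 16 μm / (60× objective × 2.5×
relay) ≈ 106.7 nm.

## Synthetic samples

* **Calibration beads** — static emitters, each carrying three Gaussian
  spectral peaks at 512.7, 581.5 and 676.5 nm (σ = 10 nm, 8,000 photons per
  dye per frame), placed uniformly at random in the spatial region.
* **Vesicle fields (`luv_field`)** — structures modeled as their equatorial
  projection: 12 binding sites on a ring of diameter 110 nm (the extruded
  LUV mean), on a grid 8 px apart.  Binding events arrive per site as a
  Poisson process (default 1 event/s per vesicle); each persists for
  ⌈τ/Δt⌉ frames with τ exponential (mean 30 ms, so most events span a
  single 50 ms frame).  While bound, emitters deliver 1,300 photons per
  frame (≈ 780 detected in the spatial order, matching typical peak photon
  values for this kind of experiment) with a Gaussian emission spectrum
  (σ = 20 nm) peaked at the site's local hydrophobicity-reporting
  wavelength.
* **Fiducial stability tables** — the instrument-stability measurement does
  not need rendered frames: per-frame localizations and spectral centers of
  fixed beads are drawn directly, with scatter following the instrument's
  empirical stability curve σ(N) = σ∞ + A·e^(−N/k) (spatial: σ∞ = 6.6 nm
  and 18 nm at 800 photons; spectral: σ∞ = 1.3 nm and 3.8 nm at 800
  photons; k = 500 photons).  The exponential family is used because it is
  the empirical form the stability analysis itself fits; a pure
  shot-noise-in-quadrature curve √(σ_f² + c/N) approaches its floor so
  slowly over 100–10,000 photons that an exponential fit of it overshoots
  the floor substantially (by ~50% at matched shot-noise levels) — the
  robustness of the fit to a quadrature-form truth is therefore only
  asserted at modest shot noise (c = 250·σ_f²), and this mismatch is a
  documented limitation of the exponential asymptote.

What the generator does **not** emulate: skewed (non-Gaussian) dye spectra,
wavelength-dependent detection efficiency, sample drift, photobleaching of
the dye reservoir, vectorial/astigmatic PSFs, axial structure, and spatially
structured background.  Passing tests therefore demonstrate correctness of
the analysis chain under the stated forward model, not performance on data
from a real instrument.

## Localization

Candidates are local maxima of a difference-of-Gaussians filter (σ and 3σ of
the PSF) whose amplitude estimate exceeds the signal-strength threshold
(default 30) times a robust noise estimate (1.4826 × MAD of the high-pass
residual).  The "signal strength" metric is defined here as fitted amplitude
over local noise sd; with the default instrument, ~780-photon events sit at
strength ~35.  Fits are least-squares 2D Gaussians (amplitude, x, y, σ,
offset) on a window of half-width ⌈3σ_psf⌉; fits with non-positive amplitude
or σ outside 0.5–4 px are rejected.  Per-localization precision uses the
Mortensen least-squares formula with σ_a² = σ² + a²/12 and the variance
doubled for EM excess noise; it is an estimate used for rendering widths and
size corrections, not a measured precision.

## Spectral calibration and assignment

Profiles are cut 15 px either side of the user-estimated Z₀Z₁ distance,
averaged over 3 px transversely, and background-subtracted with the median
of the 5-sample tails (the printed procedure is silent on background; tail
medians are robust to a peak anywhere near the center).  Gaussian peak fits
are quality-controlled by the four rules: amplitude > 0, center inside the
sampled range, width within 1.5–20 px.  The regression of accepted Z₀Z₁
distances on (λ, x, y) is unweighted OLS; it refuses rank-deficient designs
(e.g. all beads at one field position) and fewer than 10 beads.

For per-localization assignment the anchor distance is predicted for a
mid-passband wavelength (620 nm) and the profile half-width is widened to
cover the full 480–760 nm passband (≈ ±64 px at the default dispersion):
with a ±15 px window, wavelengths more than ~38 nm from the anchor would
fall outside the sampled range and be rejected by the center rule.
Assignment quality degrades gracefully: failures carry per-row reason codes
(window out of bounds, QC failures, outside passband) and the fraction
assigned is reported.

Bead density matters: when many beads share the field, first-order blobs of
different beads can enter each other's profile windows, inflating the
per-observation wavelength scatter (the QC rules catch most but not all
crowded fits).  With 50 beads on a 224 × 224 px spatial region the mean
recovered dye wavelengths are accurate to a few tenths of a nm.

## Clustering, kinetics, sizing

DBSCAN uses eps = 0.5 px and minPts = 10, with scikit-learn's convention
that the core-point count includes the point itself; only clustered
localizations are analysed further, which also discards the sparse
background typical of a blank field.  On-times merge localizations in
consecutive frames within 1 px (no frame gaps by default — binding events
are short and sparse); for an exponential dwell of mean T observed as
⌈τ/Δt⌉ frames the mean observed on-time is Δt/(1 − e^(−Δt/T)), and the
estimator inverts this discretization.  Cluster diameters are estimated from
the radial second moment corrected for localization noise,
d = 2·√(E[r²] − 2·E[prec²]), which is exact for sites on a ring blurred by
isotropic Gaussian noise.  Both event counts and localization counts are
reported for rate statistics, since multi-frame events make the two differ.

## Rendering

Each localization contributes a unit-mass discretized Gaussian whose
per-pixel mass is the product over axes of ½[erf((b−μ)/σ√2) − erf((a−μ)/σ√2)]
across pixel edges, truncated at 4σ; widths come from the per-localization
precision (floored at 1 nm), output grid 10 nm by default.  The
hydrophobicity overlay computes each pixel's photon-weighted mean wavelength
(weights: localization photons × per-pixel Gaussian mass), colored with the
jet map over 560–700 nm and brightness-modulated by density; pixels without
spectral mass render density-only.  Temporal maps apply Nadaraya–Watson
regression with a Gaussian kernel to the per-localization wavelengths inside
a moving window of 200 frames advancing by 16 (0.8 s at 20 Hz), giving
⌊(n−200)/16⌋+1 maps.  The kernel bandwidth is not dictated by the procedure
being reproduced; the default is 100 nm at the sample plane, chosen to be a
few localization precisions wide, and is configurable.  Photon counts (not
fitted amplitudes) are used as intensity weights.

## Precision analysis

Fiducial grouping is greedy: the densest unassigned 2×2 px cell seeds a
group, membership is the 4×4 px square about the running mean (three
refinement passes), and groups seen in fewer than half the frames are
dropped.  Beads closer than ~2 px merge into one group — a documented
limitation of the square rule.  Per-group precision is the wider of the
Gaussian-fit σ of the x and y scatter histograms (falling back to the sample
sd when the histogram fit is degenerate); the same estimator applied to
per-frame spectral centers gives the spectral precision.  Binned curves
(200-photon bins below 2,000, 500 above) are fit to σ∞ + A·e^(−N/k); the
additive offset is included because without it the infinite-photon asymptote
would be identically zero.  The quadrature alternative √(σ∞² + c/N) is
fitted alongside for comparison only.  Because max(σ_x, σ_y) is biased high
for small groups (~9% at 20 members), stability analyses should use a few
hundred localizations per fiducial; the bundled defaults use 250 frames per
bead, for which the bias is below 2%.

## Problem sizes

The bundled verification runs use 50 beads × 40 frames on a 224 px field for
calibration recovery, 40 fiducials × 250 frames for the stability floors,
and 90 vesicles × 1,000 frames for sizing — sizes at which every recovered
quantity is stable across seeds while a full run completes in about a minute
on one CPU.

## Numerical choices

Gaussian fits use `scipy.optimize` least squares (trust-region for 2D spots
with bounds, Levenberg–Marquardt-style `curve_fit` for 1D profiles and decay
curves); non-convergence is reported, never silently substituted.  Noise
floors: localization noise sd estimates fall back to 1.0 when the MAD is
zero (flat synthetic images); rendering floors precision at 1 nm to avoid
zero-width kernels.  Pixel coordinates are 0-based with integer coordinates
at pixel centers; sub-pixel positions are continuous.  All simulators accept
integer seeds or `numpy` generators and are bit-reproducible for a fixed
seed.
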