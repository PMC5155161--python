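# spaint

Spectrally-resolved PAINT (sPAINT) is a multi-dimensional super-resolution
method: a blazed transmission grating inserted before the camera of a
single-molecule localization microscope projects, onto one detector, both the
undiffracted image of each transiently binding dye molecule (zeroth order,
used for nanometre localization) and its dispersed emission spectrum (first
order).  With a solvatochromic dye such as nile red, every localization then
reports position *and* local hydrophobicity — enabling hydrophobicity maps of
membranes, vesicles and protein aggregates at super-resolution.

This package is for microscopists and image analysts who want to simulate,
calibrate, analyse and render sPAINT data without the original instrument.
It provides:

* **`spaint.synthetic`** — a physics-based forward simulator: point emitters
  with Gaussian emission spectra, PAINT binding/unbinding kinetics, the
  grating's ~60/40 order split with ~30% transmission loss on the diffracted
  beam, linear dispersion with field-position aberration, and the full EMCCD
  noise cascade (Poisson → gamma-distributed EM gain → read noise).  Every
  stack carries exact ground truth.
* **`spaint.localization`** — spot detection (band-pass + signal-strength
  threshold) and least-squares 2D Gaussian fitting; photon conversion via
  `GainTotal = GainCamera × GainEM × QE`; Mortensen precision estimates.
* **`spaint.calibration`** — the three-dye wavelength calibration: spectral
  profile extraction (±15 px along the dispersion axis, 3 px transverse
  average), Gaussian peak fits with quality control (amplitude > 0, center in
  range, width within 1.5–20 px), and the multiple linear regression

  &nbsp;&nbsp;&nbsp;&nbsp;Z₀Z₁ = β₀ + β₁·λ + β₂·x + β₃·y

  whose inverse λ = (Z₀Z₁ − β₀ − β₂x − β₃y)/β₁ converts any measured
  zeroth-to-first-order distance into a corrected emission wavelength.
* **`spaint.analysis`** — per-localization spectral assignment, DBSCAN
  clustering of structures (eps = 0.5 px, minPts = 10), binding-kinetics
  statistics (on-times, localization rates and densities) and spectral
  histograms.
* **`spaint.rendering`** — erf-discretized Gaussian density images,
  jet-colored hydrophobicity overlays, and moving-box Nadaraya–Watson
  spatio-temporal wavelength maps (default 200-frame window advancing by 16
  frames = 0.8 s at 20 Hz).
* **`spaint.precision`** — the instrument-stability methodology: 4×4 px
  fiducial grouping, scatter-histogram Gaussian fits, photon binning
  (200-wide bins below 2,000 photons, 500-wide above) and the single
  exponential decay σ(N) = σ∞ + A·e^(−N/k) whose offset is the
  infinite-photon precision floor.

## Worked example

```python
import numpy as np
from spaint.config import RunConfig
from spaint.pipeline import run_end_to_end

cfg = RunConfig(seed=7)
res = run_end_to_end(cfg, "demo_out", n_luvs=9, n_frames=300,
                     calib_beads=20, calib_frames=15)
m = res.calibration_model
print(f"calibration: beta1={m.beta1:.4f} px/nm, "
      f"residual sd={m.residual_sd_px:.2f} px, n={m.n_obs}")
print(f"localizations kept: {len(res.localizations)}, "
      f"clusters: {len(res.cluster_summaries)}")
s = res.cluster_summaries[0]
print(f"cluster 0: n={s.n_localizations}, diameter={s.diameter_nm:.0f} nm, "
      f"lambda = {s.mean_wavelength_nm:.1f} +/- {s.sd_wavelength_nm:.1f} nm")
```

prints

```
calibration: beta1=0.3923 px/nm, residual sd=2.33 px, n=819
localizations kept: 349, clusters: 9
cluster 0: n=48, diameter=104 nm, lambda = 639.2 +/- 7.8 nm
```

The fitted dispersion slope (~0.39 px/nm) matches the grating equation for a
300 grooves/mm grating 20 mm from a 16 μm-pixel detector; the nine simulated
110 nm vesicles are recovered as nine clusters whose corrected emission
wavelengths center on the 635 nm ground truth with a few-nm spread.

The same steps are available from the shell:

```bash
spaint simulate cal.tif --kind calibration --n-emitters 30 --n-frames 20 --seed 1
spaint calibrate cal.tif --out cal.txt
spaint simulate luv.tif --kind luv --n-frames 300 --seed 2
spaint analyze luv.tif --calib cal.txt --out-dir out/
spaint render out/localizations.csv --out-dir out/imgs
```

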