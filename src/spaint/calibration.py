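"""Spectral calibration: mapping zeroth-to-first-order distance to wavelength.

The instrument is calibrated with multi-dye beads whose three emission peaks
(512.7, 581.5, 676.5 nm) appear as three dispersed blobs below each bead's
zeroth-order image.  For each bead and peak, a 31-sample intensity profile is
cut along the dispersion axis about a user-estimated distance, averaged over
3 px transversely, and fit with a Gaussian; quality-controlled peak centers
(Z0Z1 distances) are then regressed on (wavelength, x, y) with ordinary least
squares:

    Z0Z1 = beta0 + beta1*lambda + beta2*x + beta3*y

The x,y terms absorb grating aberration over the field of view.  Inverting
the linear form converts any later measured distance into a corrected
wavelength.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import curve_fit

from .instrument import PASSBAND_NM, DispersionModel
from .synthetic import CALIBRATION_WAVELENGTHS_NM, FrameStack

__all__ = [
    "SpectralProfile",
    "PeakFitResult",
    "CalibrationModel",
    "extract_profile",
    "fit_peak",
    "fit_calibration",
    "wavelength_from_distance",
    "calibrate_stack",
    "write_calibration",
    "read_calibration",
]

#: QC bounds on fitted profile-peak widths, px.
QC_WIDTH_MIN_PX = 1.5
QC_WIDTH_MAX_PX = 20.0


@dataclass(frozen=True)
class SpectralProfile:
    """1D background-subtracted trace along the dispersion axis.

    ``offsets_px`` are integer offsets about the anchor distance (default
    −15…+15, 31 samples); intensities are ADU averaged over 3 px transverse
    with the tail median subtracted.
    """

    offsets_px: np.ndarray
    intensities: np.ndarray
    anchor_distance_px: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "offsets_px", np.asarray(self.offsets_px, dtype=int))
        object.__setattr__(self, "intensities", np.asarray(self.intensities, dtype=float))
        if self.offsets_px.shape != self.intensities.shape:
            raise ValueError("offsets and intensities must align")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("profile intensities must be finite")


@dataclass(frozen=True)
class PeakFitResult:
    """Gaussian fit of one spectral profile; ``center_px`` is the absolute
    Z0Z1 distance (anchor + fitted offset)."""

    amplitude: float
    center_px: float
    width_px: float
    offset: float
    qc_pass: bool
    qc_reason: str = ""


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted dispersion calibration with diagnostics.

    Coefficient naming: the regression *response* is the Z0Z1 distance; the
    spatial coordinate y enters only as the beta3 regressor.
    """

    beta0: float
    beta1: float
    beta2: float
    beta3: float
    residual_sd_px: float
    n_obs: int
    reference_wavelengths_nm: tuple[float, ...] = CALIBRATION_WAVELENGTHS_NM
    passband_nm: tuple[float, float] = PASSBAND_NM

    def __post_init__(self) -> None:
        if self.beta1 == 0:
            raise ValueError("beta1 must be nonzero")

    def as_dispersion(self) -> DispersionModel:
        return DispersionModel(self.beta0, self.beta1, self.beta2, self.beta3)

    def predict_distance(self, wavelength_nm, x_px=0.0, y_px=0.0):
        return self.as_dispersion().distance(wavelength_nm, x_px, y_px)


def extract_profile(
    full_frame: np.ndarray,
    anchor_x: float,
    anchor_y: float,
    estimated_distance_px: float,
    half_width_px: int = 15,
    transverse_px: int = 3,
) -> SpectralProfile:
    """Cut an intensity profile about ``anchor_y + estimated_distance`` along +y.

    Samples ``half_width_px`` either side of the anchor distance, averaging
    over ``transverse_px`` columns centered on the anchor x.  The local
    background (median of the 5-sample tails) is subtracted.

    Raises
    ------
    ValueError
        If the window leaves the frame.
    """
    img = np.asarray(full_frame, dtype=float)
    cx = int(round(anchor_x))
    cy = int(round(anchor_y + estimated_distance_px))
    ht = transverse_px // 2
    if (
        cy - half_width_px < 0
        or cy + half_width_px >= img.shape[0]
        or cx - ht < 0
        or cx + ht >= img.shape[1]
    ):
        raise ValueError("profile window out of bounds")
    strip = img[cy - half_width_px : cy + half_width_px + 1, cx - ht : cx + ht + 1]
    trace = strip.mean(axis=1)
    tails = np.concatenate([trace[:5], trace[-5:]])
    trace = trace - np.median(tails)
    offsets = np.arange(-half_width_px, half_width_px + 1)
    return SpectralProfile(
        offsets_px=offsets,
        intensities=trace,
        anchor_distance_px=float(cy - anchor_y),
    )


def _gauss1d(x, amp, mu, sigma, off):
    return amp * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2)) + off


def fit_peak(profile: SpectralProfile) -> PeakFitResult:
    """Nonlinear least-squares Gaussian + offset fit of a spectral profile.

    QC discards fits with negative amplitude, center outside the sampled
    range, or width < 1.5 px or > 20 px; non-convergence is flagged too.
    """
    x = profile.offsets_px.astype(float)
    yv = profile.intensities
    i_max = int(np.argmax(yv))
    p0 = [max(yv[i_max] - np.median(yv), 1e-3), x[i_max], 3.0, float(np.median(yv))]
    try:
        import warnings

        with warnings.catch_warnings():
            # singular covariance is expected for noise-only profiles; QC
            # rejects those fits anyway
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(_gauss1d, x, yv, p0=p0, maxfev=400)
    except Exception:
        return PeakFitResult(0.0, np.nan, np.nan, np.nan, False, "no_convergence")
    amp, mu, sigma, off = popt
    sigma = abs(float(sigma))
    center_abs = profile.anchor_distance_px + float(mu)
    if amp <= 0:
        return PeakFitResult(amp, center_abs, sigma, off, False, "negative_amplitude")
    if not (x.min() <= mu <= x.max()):
        return PeakFitResult(amp, center_abs, sigma, off, False, "center_out_of_range")
    if sigma < QC_WIDTH_MIN_PX:
        return PeakFitResult(amp, center_abs, sigma, off, False, "width_too_small")
    if sigma > QC_WIDTH_MAX_PX:
        return PeakFitResult(amp, center_abs, sigma, off, False, "width_too_large")
    return PeakFitResult(float(amp), center_abs, sigma, float(off), True)


def fit_calibration(
    distances_px: np.ndarray,
    wavelengths_nm: np.ndarray,
    x_px: np.ndarray,
    y_px: np.ndarray,
    min_beads: int = 10,
    n_beads: int | None = None,
    max_condition_number: float = 1e8,
) -> CalibrationModel:
    """OLS fit of Z0Z1 distance on (wavelength, x, y).

    ``n_beads`` (if given) is the number of distinct beads contributing; the
    fit refuses to proceed with fewer than ``min_beads`` or when the design is
    rank-deficient (for example all beads at one field position).
    """
    d = np.asarray(distances_px, dtype=float)
    lam = np.asarray(wavelengths_nm, dtype=float)
    xv = np.asarray(x_px, dtype=float)
    yv = np.asarray(y_px, dtype=float)
    n_units = n_beads if n_beads is not None else len(d) // 3
    if n_units < min_beads:
        raise ValueError(
            f"calibration needs >= {min_beads} beads with all three peaks; got {n_units}"
        )
    X = sm.add_constant(np.column_stack([lam, xv, yv]), has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design is rank-deficient: beads do not span x/y (aberration "
                         "terms unidentifiable)")
    fit = sm.OLS(d, X).fit()
    if fit.condition_number > max_condition_number:
        raise ValueError(f"ill-conditioned calibration design (cond={fit.condition_number:.2e})")
    resid_sd = float(np.sqrt(fit.mse_resid)) if len(d) > 4 else 0.0
    b0, b1, b2, b3 = fit.params
    return CalibrationModel(
        beta0=float(b0),
        beta1=float(b1),
        beta2=float(b2),
        beta3=float(b3),
        residual_sd_px=resid_sd,
        n_obs=len(d),
    )


def wavelength_from_distance(
    z0z1_px, x_px, y_px, model: CalibrationModel
) -> np.ndarray | float:
    """Corrected wavelength from a measured Z0Z1 distance:
    ``lambda = (Z0Z1 - beta0 - beta2*x - beta3*y) / beta1``.

    Values outside the 480-760 nm passband are returned as-is; callers flag
    them (see :func:`spaint.analysis.assign_spectra`).
    """
    return model.as_dispersion().wavelength(z0z1_px, x_px, y_px)


def calibrate_stack(
    stack: FrameStack,
    localizations: pd.DataFrame,
    estimated_distances_px: tuple[float, float, float],
    reference_wavelengths_nm: tuple[float, float, float] = CALIBRATION_WAVELENGTHS_NM,
    min_beads: int = 10,
) -> tuple[CalibrationModel, pd.DataFrame]:
    """Full Step-1 pipeline on a calibration-bead stack.

    For every localization (bead, frame) and each of the three user-estimated
    distances: extract a profile, fit its peak, apply QC.  Only localizations
    with all three peaks passing contribute to the regression.  Returns the
    fitted model and a tidy table of accepted (distance, wavelength, x, y)
    observations with recovered wavelengths filled in.
    """
    rows = []
    for rec in localizations.itertuples():
        frame_img = stack.frames[int(rec.frame)]
        trio = []
        for lam_ref, dist_est in zip(reference_wavelengths_nm, estimated_distances_px):
            try:
                prof = extract_profile(frame_img, rec.x_px, rec.y_px, dist_est)
            except ValueError:
                trio = []
                break
            pk = fit_peak(prof)
            if not pk.qc_pass:
                trio = []
                break
            trio.append((pk.center_px, lam_ref))
        for center, lam_ref in trio:
            rows.append((center, lam_ref, rec.x_px, rec.y_px))
    if not rows:
        raise ValueError("no calibration observations passed QC")
    obs = pd.DataFrame(rows, columns=["z0z1_px", "wavelength_nm", "x_px", "y_px"])
    # distinct beads: cluster accepted localizations on a coarse grid
    n_beads = len(
        {(int(round(x / 4.0)), int(round(y / 4.0))) for x, y in zip(obs.x_px, obs.y_px)}
    )
    model = fit_calibration(
        obs.z0z1_px.to_numpy(),
        obs.wavelength_nm.to_numpy(),
        obs.x_px.to_numpy(),
        obs.y_px.to_numpy(),
        min_beads=min_beads,
        n_beads=n_beads,
    )
    obs["recovered_nm"] = wavelength_from_distance(
        obs.z0z1_px.to_numpy(), obs.x_px.to_numpy(), obs.y_px.to_numpy(), model
    )
    return model, obs


def write_calibration(model: CalibrationModel, path, header_comment: str | None = None) -> None:
    """Plain-text calibration file: beta0..beta3, residual_sd, n_obs, passband."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write(f"beta0={model.beta0!r}\n")
        fh.write(f"beta1={model.beta1!r}\n")
        fh.write(f"beta2={model.beta2!r}\n")
        fh.write(f"beta3={model.beta3!r}\n")
        fh.write(f"residual_sd={model.residual_sd_px!r}\n")
        fh.write(f"n_obs={model.n_obs}\n")
        fh.write(f"passband_nm={model.passband_nm[0]},{model.passband_nm[1]}\n")
        fh.write(
            "reference_wavelengths_nm="
            + ",".join(str(w) for w in model.reference_wavelengths_nm)
            + "\n"
        )


def read_calibration(path) -> CalibrationModel:
    kv: dict[str, str] = {}
    for line in open(path):
        line = line.strip()
        if not line or line.startswith("#") or "=" not in line:
            continue
        k, v = line.split("=", 1)
        kv[k.strip()] = v.strip()
    pb = tuple(float(t) for t in kv.get("passband_nm", "480,760").split(","))
    refs = tuple(
        float(t)
        for t in kv.get(
            "reference_wavelengths_nm", ",".join(map(str, CALIBRATION_WAVELENGTHS_NM))
        ).split(",")
    )
    return CalibrationModel(
        beta0=float(kv["beta0"]),
        beta1=float(kv["beta1"]),
        beta2=float(kv.get("beta2", 0.0)),
        beta3=float(kv.get("beta3", 0.0)),
        residual_sd_px=float(kv.get("residual_sd", 0.0)),
        n_obs=int(kv.get("n_obs", 0)),
        reference_wavelengths_nm=refs,
        passband_nm=(pb[0], pb[1]),
    )
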