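"""Optical and camera models for a grating-based sPAINT microscope.

A blazed transmission grating inserted before the camera splits the emitted
fluorescence between the undiffracted zeroth order (used for spatial
super-localization) and the dispersed first order (used to read out the
emission spectrum), both landing on the same detector.  The classes here hold
the instrument constants; :func:`predict_first_order_displacement` is the
grating equation that ties wavelength to the zeroth-to-first-order distance
on the chip.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GratingGeometry",
    "CameraModel",
    "DispersionModel",
    "predict_first_order_displacement",
    "linear_dispersion_from_optics",
]

#: Detection passband of the instrument, nm.
PASSBAND_NM = (480.0, 760.0)


@dataclass(frozen=True)
class GratingGeometry:
    """Blazed transmission grating and its placement before the detector.

    Parameters
    ----------
    groove_spacing_d_nm
        Grating line spacing *d*.  Default corresponds to 300 grooves/mm.
    blaze_angle_gamma_deg
        Blaze angle γ between the facet structure and the grating plane.
        Controls the efficiency split between orders (held here as a record;
        the split itself is set by ``zeroth_order_fraction``).
    grating_to_detector_nm
        Optical path length *D* from the grating to the image plane.
    order_m
        Diffraction order of interest (0 or 1).
    zeroth_order_fraction
        Fraction of emitted photons diffracted into the zeroth order
        (~60% for the grating modeled here).
    first_order_loss
        Transmission inefficiency of the grating (~30%), charged against the
        diffracted beam only: the first order receives
        ``(1 - zeroth_order_fraction) * (1 - first_order_loss)``.
    """

    groove_spacing_d_nm: float = 1e6 / 300.0
    blaze_angle_gamma_deg: float = 8.6
    grating_to_detector_nm: float = 20e6
    order_m: int = 1
    zeroth_order_fraction: float = 0.60
    first_order_loss: float = 0.30

    def __post_init__(self) -> None:
        if self.groove_spacing_d_nm <= 0:
            raise ValueError("groove spacing must be positive")
        if not 0.0 < self.zeroth_order_fraction < 1.0:
            raise ValueError("zeroth_order_fraction must be in (0, 1)")
        if self.order_m not in (0, 1):
            raise ValueError("order_m must be 0 or 1")
        if not 0.0 <= self.first_order_loss < 1.0:
            raise ValueError("first_order_loss must be in [0, 1)")

    @property
    def first_order_fraction(self) -> float:
        """Photon fraction reaching the dispersed first order."""
        return (1.0 - self.zeroth_order_fraction) * (1.0 - self.first_order_loss)


@dataclass(frozen=True)
class CameraModel:
    """EMCCD detector model.

    The total conversion gain follows the cascade
    ``GainTotal = GainCamera * GainEM * QE`` (ADU per incident photon), so a
    fitted spot integral in ADU divided by ``gain_total`` is a photon count.
    """

    pixel_size_on_chip_um: float = 16.0
    magnification: float = 60.0 * 2.5  # objective x relay
    gain_camera: float = 1.0 / 9.0  # ADU per output electron
    gain_em: float = 250.0
    quantum_efficiency: float = 0.9
    baseline_offset: float = 100.0  # ADU
    read_noise: float = 5.0  # ADU rms
    frame_rate_hz: float = 20.0

    def __post_init__(self) -> None:
        if self.gain_camera <= 0 or self.gain_em <= 0:
            raise ValueError("gains must be positive")
        if not 0.0 < self.quantum_efficiency <= 1.0:
            raise ValueError("quantum efficiency must be in (0, 1]")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame rate must be positive")

    @property
    def gain_total(self) -> float:
        """ADU per incident photon: GainCamera x GainEM x QE."""
        return self.gain_camera * self.gain_em * self.quantum_efficiency

    @property
    def pixel_size_sample_nm(self) -> float:
        """Effective sample-plane pixel size (16 um / 150x = ~106.7 nm)."""
        return self.pixel_size_on_chip_um * 1e3 / self.magnification

    @property
    def frame_period_s(self) -> float:
        return 1.0 / self.frame_rate_hz


def predict_first_order_displacement(
    wavelength_nm: float | np.ndarray,
    geometry: GratingGeometry,
    pixel_size_on_chip_um: float = 16.0,
) -> float | np.ndarray:
    """Zeroth-to-first-order displacement on the chip, in detector pixels.

    Applies the grating equation ``sin(theta_m) = m * lambda / d`` followed by
    projection over the grating-to-detector distance:
    ``displacement = D * tan(theta_m)``, converted to pixels.  Strictly
    increasing in wavelength for m = 1; identically zero for m = 0.

    Raises
    ------
    ValueError
        If ``|m * lambda / d| >= 1`` (no propagating diffracted order).
    """
    lam = np.asarray(wavelength_nm, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("wavelength must be positive")
    s = geometry.order_m * lam / geometry.groove_spacing_d_nm
    if np.any(np.abs(s) >= 1.0):
        raise ValueError("m*lambda/d >= 1: no diffracted order exists")
    theta = np.arcsin(s)
    disp_nm = geometry.grating_to_detector_nm * np.tan(theta)
    disp_px = disp_nm / (pixel_size_on_chip_um * 1e3)
    if np.ndim(wavelength_nm) == 0:
        return float(disp_px)
    return disp_px


@dataclass(frozen=True)
class DispersionModel:
    """Linear dispersion map: distance = beta0 + beta1*lambda + beta2*x + beta3*y.

    Used both as the simulator's ground-truth dispersion and as the fitted
    calibration (see :mod:`spaint.calibration`).  ``beta2``/``beta3`` are the
    small field-position aberration slopes of the grating over the field of
    view.
    """

    beta0: float
    beta1: float
    beta2: float = 0.0
    beta3: float = 0.0

    def __post_init__(self) -> None:
        if self.beta1 == 0:
            raise ValueError("beta1 (dispersion slope) must be nonzero")

    def distance(self, wavelength_nm, x_px=0.0, y_px=0.0):
        """Forward map: Z0Z1 distance in px for a given wavelength and field position."""
        return (
            self.beta0
            + self.beta1 * np.asarray(wavelength_nm, dtype=float)
            + self.beta2 * np.asarray(x_px, dtype=float)
            + self.beta3 * np.asarray(y_px, dtype=float)
        )

    def wavelength(self, distance_px, x_px=0.0, y_px=0.0):
        """Inverse map: wavelength in nm from a measured Z0Z1 distance."""
        return (
            np.asarray(distance_px, dtype=float)
            - self.beta0
            - self.beta2 * np.asarray(x_px, dtype=float)
            - self.beta3 * np.asarray(y_px, dtype=float)
        ) / self.beta1


def linear_dispersion_from_optics(
    geometry: GratingGeometry | None = None,
    camera: CameraModel | None = None,
    passband_nm: tuple[float, float] = PASSBAND_NM,
) -> DispersionModel:
    """Least-squares linear approximation of the grating equation over the passband.

    The physical displacement D*tan(arcsin(lambda/d)) is very nearly linear in
    lambda over 480-760 nm (deviation < 0.25 px for the default optics); this
    returns the best-fit line as a :class:`DispersionModel` with zero
    aberration terms.  Serves as the default ground truth for the simulator
    and as the source of user-style "estimated distances" for calibration.
    """
    geometry = geometry or GratingGeometry()
    camera = camera or CameraModel()
    lam = np.linspace(passband_nm[0], passband_nm[1], 256)
    s = geometry.order_m * lam / geometry.groove_spacing_d_nm
    disp = geometry.grating_to_detector_nm * np.tan(np.arcsin(s)) / (
        camera.pixel_size_on_chip_um * 1e3
    )
    A = np.column_stack([np.ones_like(lam), lam])
    (b0, b1), *_ = np.linalg.lstsq(A, disp, rcond=None)
    return DispersionModel(beta0=float(b0), beta1=float(b1))
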