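"""Forward simulator of dual-order sPAINT camera frames with exact ground truth.

Stands in for the microscope: point emitters with Gaussian emission spectra
are imaged through a blazed transmission grating so that each emitter produces
a zeroth-order PSF in the spatial region of the detector and a dispersed blob
in the spectral region below it (dispersion axis +y).  PAINT binding/unbinding
kinetics, the 60/40 order split with ~30% grating loss, and the full EMCCD
noise cascade (Poisson photons -> gamma-distributed EM gain -> Gaussian read
noise -> baseline/clipping) are modeled.

All simulators are seeded and bit-reproducible.  Frames are 16-bit ADU images;
ground truth is a table with one row per emitting species per frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import tifffile
from scipy.special import erf

from .instrument import (
    PASSBAND_NM,
    CameraModel,
    DispersionModel,
    GratingGeometry,
    linear_dispersion_from_optics,
)

__all__ = [
    "EmitterSpecies",
    "SampleGeometry",
    "FrameStack",
    "InstabilityModel",
    "CALIBRATION_SPECIES",
    "luv_field",
    "simulate_calibration_stack",
    "simulate_spaint_stack",
    "simulate_fiducial_localizations",
    "write_stack",
    "read_stack",
]

GROUND_TRUTH_COLUMNS = ["frame", "x_px", "y_px", "photons", "wavelength_nm"]


@dataclass(frozen=True)
class EmitterSpecies:
    """A fluorescent species: Gaussian emission spectrum and PSF width.

    ``mean_photons_per_frame`` is the *emitted* photon budget per frame before
    the grating split; the zeroth order receives ``zeroth_order_fraction`` of
    it and the first order ``1 - zeroth_order_fraction - first_order_loss``.
    """

    peak_wavelength_nm: float
    spectral_sigma_nm: float = 20.0
    mean_photons_per_frame: float = 1300.0
    psf_sigma_px: float = 1.2

    def __post_init__(self) -> None:
        if not PASSBAND_NM[0] <= self.peak_wavelength_nm <= PASSBAND_NM[1]:
            raise ValueError("peak wavelength outside the 480-760 nm detection passband")
        if self.spectral_sigma_nm <= 0:
            raise ValueError("spectral sigma must be positive")
        if self.mean_photons_per_frame < 0:
            raise ValueError("photon budget must be non-negative")


#: The three reference dyes of multi-color calibration beads (peak emission, nm).
CALIBRATION_WAVELENGTHS_NM = (512.7, 581.5, 676.5)

CALIBRATION_SPECIES = tuple(
    EmitterSpecies(peak_wavelength_nm=w, spectral_sigma_nm=10.0, mean_photons_per_frame=8000.0)
    for w in CALIBRATION_WAVELENGTHS_NM
)


@dataclass(frozen=True)
class SampleGeometry:
    """Arrangement of PAINT binding sites and their kinetics.

    ``binding_site_map`` is an (n, 3) array of (x_px, y_px, local peak
    wavelength nm): each site transiently binds dye molecules whose emission
    peak reports the local hydrophobicity.  Events arrive per site as a
    Poisson process with rate ``binding_rate_per_site`` (events/s) and persist
    for an exponential on-time with mean ``on_time_mean_s``.
    """

    kind: str
    binding_site_map: np.ndarray
    structure_diameter_nm: float = 110.0
    binding_rate_per_site: float = 0.1
    on_time_mean_s: float = 0.030

    def __post_init__(self) -> None:
        sites = np.atleast_2d(np.asarray(self.binding_site_map, dtype=float))
        if sites.size and sites.shape[1] != 3:
            raise ValueError("binding_site_map must be (n, 3): x, y, wavelength")
        object.__setattr__(self, "binding_site_map", sites)
        if self.on_time_mean_s <= 0:
            raise ValueError("mean on-time must be positive")
        if self.binding_rate_per_site < 0:
            raise ValueError("binding rate must be non-negative")


def luv_field(
    n_luvs: int,
    *,
    diameter_nm: float = 110.0,
    wavelength_nm: float = 635.0,
    sites_per_luv: int = 12,
    spacing_px: float = 8.0,
    margin_px: float = 6.0,
    pixel_size_nm: float = CameraModel().pixel_size_sample_nm,
    binding_rate_per_site: float | None = None,
    binding_rate_per_luv: float = 1.0,
    on_time_mean_s: float = 0.030,
) -> SampleGeometry:
    """Grid of spatially isolated vesicles with binding sites on a ring.

    Each LUV is modeled as its equatorial projection: ``sites_per_luv`` sites
    equally spaced on a ring of the given diameter (default 110 nm, the
    extruded-vesicle mean).  LUVs sit on a square grid ``spacing_px`` apart so
    that density-based clustering cannot merge neighbors.
    """
    n_cols = math.ceil(math.sqrt(n_luvs))
    radius_px = 0.5 * diameter_nm / pixel_size_nm
    if binding_rate_per_site is None:
        binding_rate_per_site = binding_rate_per_luv / sites_per_luv
    phases = np.linspace(0.0, 2.0 * np.pi, sites_per_luv, endpoint=False)
    sites = []
    for i in range(n_luvs):
        cx = margin_px + (i % n_cols) * spacing_px
        cy = margin_px + (i // n_cols) * spacing_px
        for ph in phases:
            sites.append((cx + radius_px * np.cos(ph), cy + radius_px * np.sin(ph), wavelength_nm))
    return SampleGeometry(
        kind="luv_field",
        binding_site_map=np.array(sites),
        structure_diameter_nm=diameter_nm,
        binding_rate_per_site=binding_rate_per_site,
        on_time_mean_s=on_time_mean_s,
    )


@dataclass
class FrameStack:
    """Time-ordered detector frames plus instrument metadata and ground truth.

    ``frames`` has shape (n_frames, height, width) in ADU.  Rows
    ``[0, spatial_height_px)`` form the spatial (zeroth-order) region; the
    rows below receive the dispersed first order.
    """

    frames: np.ndarray
    camera: CameraModel
    geometry: GratingGeometry
    spatial_height_px: int
    ground_truth: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=GROUND_TRUTH_COLUMNS)
    )
    dispersion_truth: DispersionModel | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, H, W) array")
        if self.frames.size and self.frames.min() < 0:
            raise ValueError("pixel values must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def spatial_region(self, frame: int) -> np.ndarray:
        return self.frames[frame, : self.spatial_height_px, :]


# ---------------------------------------------------------------------------
# low-level rendering / noise


def _add_integrated_gaussian(
    img: np.ndarray, x: float, y: float, sigma_x: float, sigma_y: float, photons: float
) -> None:
    """Add a pixel-integrated 2D Gaussian (total mass = photons) in place.

    Pixel (i, j) covers [j-0.5, j+0.5] x [i-0.5, i+0.5] so that a source at
    (x, y) = (j, i) is centered on pixel (i, j).  Truncated at 5 sigma.
    """
    h, w = img.shape
    rx = max(3, int(math.ceil(5.0 * sigma_x)))
    ry = max(3, int(math.ceil(5.0 * sigma_y)))
    j0, j1 = max(0, int(math.floor(x)) - rx), min(w, int(math.floor(x)) + rx + 2)
    i0, i1 = max(0, int(math.floor(y)) - ry), min(h, int(math.floor(y)) + ry + 2)
    if j0 >= j1 or i0 >= i1:
        return
    jx = np.arange(j0, j1)
    iy = np.arange(i0, i1)
    fx = 0.5 * (
        erf((jx + 0.5 - x) / (sigma_x * math.sqrt(2.0)))
        - erf((jx - 0.5 - x) / (sigma_x * math.sqrt(2.0)))
    )
    fy = 0.5 * (
        erf((iy + 0.5 - y) / (sigma_y * math.sqrt(2.0)))
        - erf((iy - 0.5 - y) / (sigma_y * math.sqrt(2.0)))
    )
    img[i0:i1, j0:j1] += photons * np.outer(fy, fx)


def _apply_emccd_noise(
    expected_photons: np.ndarray, camera: CameraModel, rng: np.random.Generator
) -> np.ndarray:
    """EMCCD readout of an expected incident-photon map -> uint16 ADU frame.

    Poisson(QE * expected) photoelectrons, gamma-distributed electron
    multiplication (shape = n electrons, scale = EM gain), conversion gain,
    baseline offset, Gaussian read noise, clip to [0, 65535].
    """
    electrons_in = rng.poisson(camera.quantum_efficiency * expected_photons)
    electrons_out = rng.standard_gamma(electrons_in) * camera.gain_em
    adu = (
        electrons_out * camera.gain_camera
        + camera.baseline_offset
        + rng.normal(0.0, camera.read_noise, size=expected_photons.shape)
    )
    return np.clip(np.rint(adu), 0, 65535).astype(np.uint16)


def _spectral_blob_sigma_y(species: EmitterSpecies, beta1: float) -> float:
    # spectrum (Gaussian in lambda) maps through the dispersion slope and is
    # convolved with the PSF along the dispersion axis
    return math.sqrt(species.psf_sigma_px**2 + (beta1 * species.spectral_sigma_nm) ** 2)


def _render_emitter(
    img: np.ndarray,
    x: float,
    y: float,
    species: EmitterSpecies,
    geometry: GratingGeometry,
    dispersion: DispersionModel,
    photons: float | None = None,
) -> None:
    """Add zeroth-order PSF and first-order spectral blob for one emitter."""
    n = species.mean_photons_per_frame if photons is None else photons
    _add_integrated_gaussian(
        img, x, y, species.psf_sigma_px, species.psf_sigma_px, geometry.zeroth_order_fraction * n
    )
    dist = float(dispersion.distance(species.peak_wavelength_nm, x, y))
    _add_integrated_gaussian(
        img,
        x,
        y + dist,
        species.psf_sigma_px,
        _spectral_blob_sigma_y(species, dispersion.beta1),
        geometry.first_order_fraction * n,
    )


def _required_height(
    spatial_height: int, dispersion: DispersionModel, width: int, margin: int = 12
) -> int:
    max_dist = float(
        np.max(dispersion.distance(PASSBAND_NM[1], np.array([0.0, width]), spatial_height))
    )
    return int(math.ceil(spatial_height + max_dist + margin))


# ---------------------------------------------------------------------------
# stack simulators


def simulate_calibration_stack(
    n_beads: int,
    species_triplet: tuple[EmitterSpecies, ...] = CALIBRATION_SPECIES,
    camera: CameraModel | None = None,
    geometry: GratingGeometry | None = None,
    dispersion_truth: DispersionModel | None = None,
    *,
    n_frames: int = 100,
    spatial_size_px: tuple[int, int] = (128, 128),
    margin_px: float = 8.0,
    background_photons: float = 2.0,
    aberration: tuple[float, float] = (0.0015, 0.002),
    seed: int | np.random.Generator = 0,
) -> FrameStack:
    """Multi-dye calibration-bead stack: every bead shows one zeroth-order spot
    and three dispersed spectral peaks per frame.

    Beads are placed uniformly at random in the spatial sub-region; the
    first-order displacement of each dye follows ``dispersion_truth`` (default:
    the grating-equation linearization plus small x,y aberration slopes).
    """
    camera = camera or CameraModel()
    geometry = geometry or GratingGeometry()
    if dispersion_truth is None:
        base = linear_dispersion_from_optics(geometry, camera)
        dispersion_truth = replace(base, beta2=aberration[0], beta3=aberration[1])
    rng = np.random.default_rng(seed)
    sh, sw = spatial_size_px
    height = _required_height(sh, dispersion_truth, sw)
    if height <= sh:
        raise ValueError("spatial and spectral regions overlap: enlarge the detector")

    xs = rng.uniform(margin_px, sw - margin_px, size=n_beads)
    ys = rng.uniform(margin_px, sh - margin_px, size=n_beads)

    frames = np.empty((n_frames, height, sw), dtype=np.uint16)
    base_img = np.full((height, sw), float(background_photons))
    expected = base_img.copy()
    for x, y in zip(xs, ys):
        for sp in species_triplet:
            _render_emitter(expected, x, y, sp, geometry, dispersion_truth)
    for f in range(n_frames):
        frames[f] = _apply_emccd_noise(expected, camera, rng)

    rows = []
    for f in range(n_frames):
        for x, y in zip(xs, ys):
            for sp in species_triplet:
                rows.append((f, x, y, sp.mean_photons_per_frame, sp.peak_wavelength_nm))
    gt = pd.DataFrame(rows, columns=GROUND_TRUTH_COLUMNS)
    return FrameStack(
        frames=frames,
        camera=camera,
        geometry=geometry,
        spatial_height_px=sh,
        ground_truth=gt,
        dispersion_truth=dispersion_truth,
    )


def simulate_spaint_stack(
    sample: SampleGeometry,
    camera: CameraModel | None = None,
    geometry: GratingGeometry | None = None,
    dispersion_truth: DispersionModel | None = None,
    *,
    n_frames: int = 1000,
    species_template: EmitterSpecies | None = None,
    spatial_size_px: tuple[int, int] | None = None,
    background_photons: float = 2.0,
    seed: int | np.random.Generator = 0,
) -> FrameStack:
    """PAINT acquisition of a sample: stochastic binding events, each emitting
    while bound with the site's local emission wavelength.

    Events arrive per site as a Poisson process; each persists for
    ``ceil(tau / frame_period)`` frames with tau ~ Exponential(on_time_mean).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    camera = camera or CameraModel()
    geometry = geometry or GratingGeometry()
    if dispersion_truth is None:
        dispersion_truth = linear_dispersion_from_optics(geometry, camera)
    template = species_template or EmitterSpecies(peak_wavelength_nm=620.0)
    rng = np.random.default_rng(seed)

    sites = sample.binding_site_map
    if spatial_size_px is None:
        if sites.size:
            sw = int(math.ceil(sites[:, 0].max() + 8))
            sh = int(math.ceil(sites[:, 1].max() + 8))
        else:
            sh, sw = 64, 64
        spatial_size_px = (sh, sw)
    sh, sw = spatial_size_px
    height = _required_height(sh, dispersion_truth, sw)
    dt = camera.frame_period_s
    duration_s = n_frames * dt

    # draw binding events per site
    events = []  # (site_idx, first_frame, n_span_frames)
    if sites.size == 0:
        import warnings

        warnings.warn("empty binding_site_map: simulating a noise-only stack", stacklevel=2)
    for si in range(len(sites)):
        n_ev = rng.poisson(sample.binding_rate_per_site * duration_s)
        starts = rng.uniform(0.0, duration_s, size=n_ev)
        taus = rng.exponential(sample.on_time_mean_s, size=n_ev)
        for t0, tau in zip(starts, taus):
            f0 = int(t0 / dt)
            span = max(1, int(math.ceil(tau / dt)))
            events.append((si, f0, span))

    per_frame: dict[int, list[int]] = {}
    for ei, (si, f0, span) in enumerate(events):
        for f in range(f0, min(f0 + span, n_frames)):
            per_frame.setdefault(f, []).append(ei)

    frames = np.empty((n_frames, height, sw), dtype=np.uint16)
    rows = []
    for f in range(n_frames):
        expected = np.full((height, sw), float(background_photons))
        for ei in per_frame.get(f, ()):
            si, _, _ = events[ei]
            x, y, lam = sites[si]
            sp = replace(template, peak_wavelength_nm=float(lam))
            _render_emitter(expected, x, y, sp, geometry, dispersion_truth)
            rows.append((f, x, y, sp.mean_photons_per_frame, lam, ei))
        frames[f] = _apply_emccd_noise(expected, camera, rng)

    gt = pd.DataFrame(rows, columns=GROUND_TRUTH_COLUMNS + ["event_id"])
    return FrameStack(
        frames=frames,
        camera=camera,
        geometry=geometry,
        spatial_height_px=sh,
        ground_truth=gt,
        dispersion_truth=dispersion_truth,
    )


# ---------------------------------------------------------------------------
# fiducial localization tables (instrument-stability emulation)


@dataclass(frozen=True)
class InstabilityModel:
    """Empirical precision-vs-photons curves of the emulated instrument.

    Repeated localizations of a fixed emitter scatter with standard deviation
    ``sigma(N) = floor + amplitude * exp(-N / decay_photons)`` — the
    empirically observed single-exponential stability curve, anchored so that
    the spatial precision is 6.6 nm at infinite photons and ~18 nm at 800
    photons, and the spectral precision 1.3 nm / ~3.8 nm at the same points.
    """

    spatial_floor_nm: float = 6.6
    spatial_sigma_at_800_nm: float = 18.0
    spectral_floor_nm: float = 1.3
    spectral_sigma_at_800_nm: float = 3.8
    decay_photons: float = 500.0

    def spatial_sigma_nm(self, photons):
        amp = (self.spatial_sigma_at_800_nm - self.spatial_floor_nm) * math.exp(
            800.0 / self.decay_photons
        )
        return self.spatial_floor_nm + amp * np.exp(-np.asarray(photons, float) / self.decay_photons)

    def spectral_sigma_nm(self, photons):
        amp = (self.spectral_sigma_at_800_nm - self.spectral_floor_nm) * math.exp(
            800.0 / self.decay_photons
        )
        return self.spectral_floor_nm + amp * np.exp(
            -np.asarray(photons, float) / self.decay_photons
        )


def simulate_fiducial_localizations(
    n_beads: int = 40,
    frames_per_bead: int = 250,
    *,
    photon_range: tuple[float, float] = (100.0, 10000.0),
    stability: InstabilityModel | None = None,
    camera: CameraModel | None = None,
    spectral_center_nm: float = 580.0,
    spacing_px: float = 10.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Per-frame localization + spectral-center table for fixed bright beads.

    Emulates a stability measurement without rendering frames: beads on a
    grid, per-bead mean photon level log-uniform over ``photon_range``,
    per-frame positions scattered with the instrument's spatial stability
    curve and per-frame spectral centers (TetraSpeck "orange" ~580 nm) with
    the spectral stability curve.
    """
    stability = stability or InstabilityModel()
    camera = camera or CameraModel()
    rng = np.random.default_rng(seed)
    px_nm = camera.pixel_size_sample_nm

    n_cols = math.ceil(math.sqrt(n_beads))
    rows = []
    for b in range(n_beads):
        cx = 6.0 + (b % n_cols) * spacing_px
        cy = 6.0 + (b // n_cols) * spacing_px
        mean_n = math.exp(rng.uniform(math.log(photon_range[0]), math.log(photon_range[1])))
        photons = rng.poisson(mean_n, size=frames_per_bead).astype(float)
        photons = np.clip(photons, 1.0, None)
        s_xy = stability.spatial_sigma_nm(photons) / px_nm
        s_lam = stability.spectral_sigma_nm(photons)
        xs = cx + rng.normal(0.0, 1.0, frames_per_bead) * s_xy
        ys = cy + rng.normal(0.0, 1.0, frames_per_bead) * s_xy
        lams = spectral_center_nm + rng.normal(0.0, 1.0, frames_per_bead) * s_lam
        for f in range(frames_per_bead):
            rows.append((f, xs[f], ys[f], photons[f], lams[f]))
    df = pd.DataFrame(rows, columns=["frame", "x_px", "y_px", "photons", "wavelength_nm"])
    df.attrs["pixel_size_nm"] = px_nm
    df.attrs["n_frames"] = frames_per_bead
    return df


# ---------------------------------------------------------------------------
# stack I/O (multi-page TIFF + CSV/key-value side-cars)


def write_stack(stack: FrameStack, path) -> None:
    """Write frames as multi-page 16-bit TIFF with ground-truth CSV and
    metadata side-cars (``<stem>.truth.csv``, ``<stem>.meta.txt``)."""
    from pathlib import Path

    path = Path(path)
    if stack.n_frames == 0:
        raise ValueError("refusing to write an empty stack")
    tifffile.imwrite(path, stack.frames.astype(np.uint16))
    gt = stack.ground_truth
    cols = GROUND_TRUTH_COLUMNS + [c for c in gt.columns if c not in GROUND_TRUTH_COLUMNS]
    gt.reindex(columns=cols).to_csv(path.with_suffix(".truth.csv"), index=False)
    cam, geo = stack.camera, stack.geometry
    meta = {
        "spatial_height_px": stack.spatial_height_px,
        "pixel_size_on_chip_um": cam.pixel_size_on_chip_um,
        "magnification": cam.magnification,
        "gain_camera": cam.gain_camera,
        "gain_em": cam.gain_em,
        "quantum_efficiency": cam.quantum_efficiency,
        "baseline_offset": cam.baseline_offset,
        "read_noise": cam.read_noise,
        "frame_rate_hz": cam.frame_rate_hz,
        "groove_spacing_d_nm": geo.groove_spacing_d_nm,
        "blaze_angle_gamma_deg": geo.blaze_angle_gamma_deg,
        "grating_to_detector_nm": geo.grating_to_detector_nm,
        "order_m": geo.order_m,
        "zeroth_order_fraction": geo.zeroth_order_fraction,
        "first_order_loss": geo.first_order_loss,
    }
    if stack.dispersion_truth is not None:
        d = stack.dispersion_truth
        meta.update(
            dispersion_beta0=d.beta0, dispersion_beta1=d.beta1,
            dispersion_beta2=d.beta2, dispersion_beta3=d.beta3,
        )
    with open(path.with_suffix(".meta.txt"), "w") as fh:
        for k, v in meta.items():
            fh.write(f"{k}={v}\n")


def read_stack(path) -> FrameStack:
    """Read a stack written by :func:`write_stack` (lossless round trip)."""
    from pathlib import Path

    path = Path(path)
    try:
        frames = tifffile.imread(path)
    except Exception as exc:  # pragma: no cover - delegated format errors
        raise ValueError(f"malformed TIFF stack at {path}: {exc}") from exc
    if frames.ndim == 2:
        frames = frames[None, ...]
    meta: dict[str, float] = {}
    meta_path = path.with_suffix(".meta.txt")
    if meta_path.exists():
        for line in meta_path.read_text().splitlines():
            if "=" in line:
                k, v = line.split("=", 1)
                meta[k.strip()] = float(v.strip())
    camera = CameraModel(
        pixel_size_on_chip_um=meta.get("pixel_size_on_chip_um", 16.0),
        magnification=meta.get("magnification", 150.0),
        gain_camera=meta.get("gain_camera", 1.0 / 9.0),
        gain_em=meta.get("gain_em", 250.0),
        quantum_efficiency=meta.get("quantum_efficiency", 0.9),
        baseline_offset=meta.get("baseline_offset", 100.0),
        read_noise=meta.get("read_noise", 5.0),
        frame_rate_hz=meta.get("frame_rate_hz", 20.0),
    )
    geometry = GratingGeometry(
        groove_spacing_d_nm=meta.get("groove_spacing_d_nm", 1e6 / 300.0),
        blaze_angle_gamma_deg=meta.get("blaze_angle_gamma_deg", 8.6),
        grating_to_detector_nm=meta.get("grating_to_detector_nm", 20e6),
        order_m=int(meta.get("order_m", 1)),
        zeroth_order_fraction=meta.get("zeroth_order_fraction", 0.60),
        first_order_loss=meta.get("first_order_loss", 0.30),
    )
    dispersion = None
    if "dispersion_beta0" in meta:
        dispersion = DispersionModel(
            beta0=meta["dispersion_beta0"],
            beta1=meta["dispersion_beta1"],
            beta2=meta.get("dispersion_beta2", 0.0),
            beta3=meta.get("dispersion_beta3", 0.0),
        )
    truth_path = path.with_suffix(".truth.csv")
    gt = (
        pd.read_csv(truth_path)
        if truth_path.exists()
        else pd.DataFrame(columns=GROUND_TRUTH_COLUMNS)
    )
    return FrameStack(
        frames=frames,
        camera=camera,
        geometry=geometry,
        spatial_height_px=int(meta.get("spatial_height_px", frames.shape[1])),
        ground_truth=gt,
        dispersion_truth=dispersion,
    )
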