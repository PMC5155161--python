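"""Per-localization spectral assignment, structure clustering and kinetics.

After localization and calibration, each binding event's emission wavelength
is read out by cutting a profile in the spectral region at the distance
predicted for a mid-passband wavelength, fitting its peak, applying the
calibration QC rules and inverting the calibration.  Localizations are
grouped into structures with DBSCAN (eps = 0.5 px, minPts = 10; sklearn's
neighbor count includes the point itself, matching the R fpc convention);
only clustered localizations are analysed further.  Kinetic statistics
(on-times via frame linking, localization rates and densities) and spectral
histograms complete the per-structure summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.cluster import DBSCAN

from .calibration import CalibrationModel, extract_profile, fit_peak, wavelength_from_distance
from .instrument import PASSBAND_NM
from .synthetic import FrameStack

__all__ = [
    "ClusterParams",
    "ClusterSummary",
    "assign_spectra",
    "cluster_localizations",
    "compute_on_times",
    "estimate_mean_on_time",
    "localization_density",
    "spectral_histogram",
    "summarize_clusters",
    "estimate_cluster_diameter_nm",
]

#: Anchor wavelength for profile extraction during assignment (mid NR range).
ASSIGNMENT_ANCHOR_NM = 620.0


@dataclass(frozen=True)
class ClusterParams:
    """DBSCAN parameters for grouping localizations into structures."""

    eps_px: float = 0.5
    min_points: int = 10

    def __post_init__(self) -> None:
        if self.eps_px <= 0:
            raise ValueError("eps must be positive")
        if self.min_points < 1:
            raise ValueError("min_points must be >= 1")


@dataclass
class ClusterSummary:
    """Per-structure aggregate statistics."""

    cluster_id: int
    n_localizations: int
    centroid_x_px: float
    centroid_y_px: float
    radial_extent_px: float
    diameter_nm: float
    mean_wavelength_nm: float
    sd_wavelength_nm: float
    n_spectra: int
    localizations_per_frame: float
    mean_on_time_s: float
    spectral_histogram: tuple[np.ndarray, np.ndarray] = field(repr=False, default=None)


def assign_spectra(
    table: pd.DataFrame,
    stack: FrameStack,
    model: CalibrationModel,
    anchor_wavelength_nm: float = ASSIGNMENT_ANCHOR_NM,
    half_width_px: int | None = None,
) -> pd.DataFrame:
    """Fill per-localization emission wavelengths from the spectral region.

    For each row: predict the Z0Z1 distance at the anchor wavelength for that
    field position, extract a profile wide enough to cover the full passband,
    fit its peak, apply the calibration QC rules, and invert the calibration.
    Failures leave ``wavelength_nm`` unset with a reason code in
    ``qc_reason``.  Returns a copy; ``attrs['fraction_assigned']`` reports the
    yield.
    """
    out = table.copy()
    if half_width_px is None:
        span = abs(model.beta1) * (model.passband_nm[1] - model.passband_nm[0])
        half_width_px = int(math.ceil(span / 2.0)) + 8
    wavelengths = np.full(len(out), np.nan)
    reasons = np.array([""] * len(out), dtype=object)
    for k, rec in enumerate(out.itertuples()):
        frame_img = stack.frames[int(rec.frame)]
        dist_est = float(model.predict_distance(anchor_wavelength_nm, rec.x_px, rec.y_px))
        try:
            prof = extract_profile(
                frame_img, rec.x_px, rec.y_px, dist_est, half_width_px=half_width_px
            )
        except ValueError:
            reasons[k] = "window_oob"
            continue
        pk = fit_peak(prof)
        if not pk.qc_pass:
            reasons[k] = pk.qc_reason
            continue
        lam = float(wavelength_from_distance(pk.center_px, rec.x_px, rec.y_px, model))
        if not model.passband_nm[0] <= lam <= model.passband_nm[1]:
            reasons[k] = "outside_passband"
            continue
        wavelengths[k] = lam
    out["wavelength_nm"] = wavelengths
    out["qc_reason"] = reasons
    out.attrs.update(table.attrs)
    out.attrs["fraction_assigned"] = float(np.mean(np.isfinite(wavelengths))) if len(out) else 0.0
    return out


def cluster_localizations(
    table: pd.DataFrame, params: ClusterParams | None = None
) -> np.ndarray:
    """DBSCAN cluster labels over (x, y) in pixels; noise label is -1."""
    params = params or ClusterParams()
    if len(table) == 0:
        return np.empty(0, dtype=int)
    pts = table[["x_px", "y_px"]].to_numpy()
    return DBSCAN(eps=params.eps_px, min_samples=params.min_points).fit_predict(pts)


def compute_on_times(
    table: pd.DataFrame,
    link_radius_px: float = 1.0,
    max_gap_frames: int = 0,
    frame_period_s: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Merge localizations in consecutive frames within a radius into events.

    Returns ``(on_times_s, event_ids)`` where ``event_ids`` labels each row of
    the (frame-sorted) table and an event's on-time is its frame span times
    the frame period.
    """
    if frame_period_s is None:
        frame_period_s = table.attrs.get("frame_period_s", 0.05)
    n = len(table)
    if n == 0:
        return np.empty(0), np.empty(0, dtype=int)
    order = np.argsort(table["frame"].to_numpy(), kind="mergesort")
    frames = table["frame"].to_numpy()[order].astype(int)
    xy = table[["x_px", "y_px"]].to_numpy()[order]
    event_of = np.full(n, -1, dtype=int)
    next_event = 0
    open_events: dict[int, tuple[float, float, int]] = {}  # id -> (x, y, last_frame)
    for f in np.unique(frames):
        idx = np.nonzero(frames == f)[0]
        # retire stale events
        open_events = {
            e: v for e, v in open_events.items() if f - v[2] <= max_gap_frames + 1
        }
        if open_events:
            e_ids = list(open_events)
            tree = cKDTree(np.array([[open_events[e][0], open_events[e][1]] for e in e_ids]))
            dists, js = tree.query(xy[idx], k=1)
        else:
            dists = np.full(len(idx), np.inf)
            js = np.zeros(len(idx), dtype=int)
        claimed: set[int] = set()
        for i, dist, j in zip(idx, dists, js):
            if dist <= link_radius_px and e_ids[j] not in claimed:
                e = e_ids[j]
                claimed.add(e)
            else:
                e = next_event
                next_event += 1
            event_of[i] = e
            open_events[e] = (xy[i, 0], xy[i, 1], f)
    spans = np.zeros(next_event)
    first = np.full(next_event, np.inf)
    last = np.full(next_event, -np.inf)
    for i, e in enumerate(event_of):
        first[e] = min(first[e], frames[i])
        last[e] = max(last[e], frames[i])
    spans = last - first + 1
    on_times = spans * frame_period_s
    inv = np.empty(n, dtype=int)
    inv[order] = np.arange(n)
    return on_times, event_of[inv]


def estimate_mean_on_time(
    on_times_s: np.ndarray, frame_period_s: float, correct_discretization: bool = True
) -> float:
    """Mean on-time; optionally inverts the frame-quantization of an
    exponential dwell time.

    An exponential dwell tau with mean T observed as ceil(tau/dt) frames has
    mean observed on-time dt / (1 - exp(-dt/T)); solving that relation for T
    gives the corrected estimate.
    """
    m = float(np.mean(on_times_s))
    if not correct_discretization:
        return m
    dt = frame_period_s
    if m <= dt:
        return m
    q = 1.0 - dt / m  # = exp(-dt/T)
    return -dt / math.log(q)


def localization_density(
    n_localizations: int, area_um2: float, duration_s: float
) -> float:
    """Localizations per square micrometre per second."""
    if area_um2 <= 0 or duration_s <= 0:
        raise ValueError("area and duration must be positive")
    return n_localizations / (area_um2 * duration_s)


def spectral_histogram(
    wavelengths_nm: np.ndarray,
    bin_width_nm: float = 1.0,
    passband_nm: tuple[float, float] = PASSBAND_NM,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Counts per wavelength bin over the passband, plus mean and sd."""
    lam = np.asarray(wavelengths_nm, dtype=float)
    lam = lam[np.isfinite(lam)]
    if lam.size == 0:
        raise ValueError("no assigned wavelengths to histogram")
    edges = np.arange(passband_nm[0], passband_nm[1] + bin_width_nm, bin_width_nm)
    counts, edges = np.histogram(lam, bins=edges)
    return counts, edges, float(lam.mean()), float(lam.std(ddof=0))


def estimate_cluster_diameter_nm(
    member_table: pd.DataFrame, pixel_size_nm: float
) -> tuple[float, float]:
    """Structure diameter from the radial localization extent, corrected for
    localization precision.

    For sites on a ring of radius r blurred by isotropic localization noise
    sigma per axis, E[|p - centroid|^2] = r^2 + 2 sigma^2; the diameter
    estimate is ``2 * sqrt(max(mean d^2 - 2 mean(prec^2), 0))``.  Returns
    (diameter_nm, raw radial extent in px).
    """
    x = member_table["x_px"].to_numpy() * pixel_size_nm
    y = member_table["y_px"].to_numpy() * pixel_size_nm
    dx = x - x.mean()
    dy = y - y.mean()
    d2 = dx**2 + dy**2
    prec2 = (
        np.mean(member_table["precision_nm"].to_numpy() ** 2)
        if "precision_nm" in member_table
        else 0.0
    )
    r2 = max(float(d2.mean()) - 2.0 * float(prec2), 0.0)
    return 2.0 * math.sqrt(r2), math.sqrt(float(d2.mean())) / pixel_size_nm


def summarize_clusters(
    table: pd.DataFrame,
    labels: np.ndarray,
    params: ClusterParams | None = None,
    bin_width_nm: float = 1.0,
) -> list[ClusterSummary]:
    """Aggregate per-cluster statistics (noise label -1 is skipped)."""
    params = params or ClusterParams()
    px_nm = table.attrs.get("pixel_size_nm", 106.7)
    frame_period = table.attrs.get("frame_period_s", 0.05)
    n_frames = table.attrs.get("n_frames", int(table["frame"].max()) + 1 if len(table) else 1)
    summaries = []
    for cid in sorted(set(labels) - {-1}):
        members = table[labels == cid]
        diam_nm, extent_px = estimate_cluster_diameter_nm(members, px_nm)
        lam = (
            members["wavelength_nm"].to_numpy()
            if "wavelength_nm" in members
            else np.array([])
        )
        lam = lam[np.isfinite(lam)] if lam.size else lam
        if lam.size:
            counts, edges, mean_l, sd_l = spectral_histogram(lam, bin_width_nm)
            hist = (counts, edges)
        else:
            mean_l = sd_l = float("nan")
            hist = None
        on_times, _ = compute_on_times(members, frame_period_s=frame_period)
        summaries.append(
            ClusterSummary(
                cluster_id=int(cid),
                n_localizations=len(members),
                centroid_x_px=float(members["x_px"].mean()),
                centroid_y_px=float(members["y_px"].mean()),
                radial_extent_px=extent_px,
                diameter_nm=diam_nm,
                mean_wavelength_nm=mean_l,
                sd_wavelength_nm=sd_l,
                n_spectra=int(lam.size),
                localizations_per_frame=len(members) / float(n_frames),
                mean_on_time_s=float(np.mean(on_times)) if on_times.size else float("nan"),
                spectral_histogram=hist,
            )
        )
    return summaries


def summaries_to_frame(summaries: list[ClusterSummary]) -> pd.DataFrame:
    """Tabular view of cluster summaries (drops the raw histograms)."""
    return pd.DataFrame(
        [
            {
                "cluster_id": s.cluster_id,
                "n_localizations": s.n_localizations,
                "centroid_x_px": s.centroid_x_px,
                "centroid_y_px": s.centroid_y_px,
                "radial_extent_px": s.radial_extent_px,
                "diameter_nm": s.diameter_nm,
                "mean_wavelength_nm": s.mean_wavelength_nm,
                "sd_wavelength_nm": s.sd_wavelength_nm,
                "n_spectra": s.n_spectra,
                "localizations_per_frame": s.localizations_per_frame,
                "mean_on_time_s": s.mean_on_time_s,
            }
            for s in summaries
        ]
    )
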