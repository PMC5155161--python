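"""Empirical instrument-stability analysis: precision vs photon count.

Repeated localizations of fixed fiducial beads are grouped (localizations
within a 4x4 px square belong to one bead, beads seen in at least half of
the frames are kept), the scatter of each group is reduced to a precision
(1D Gaussian fits of the x and y histograms, the wider of the two), the
per-group (mean photons, precision) pairs are binned — 200-photon-wide bins
below 2,000 photons, 500-photon-wide above — and the binned curve is fit to
a single exponential decay with offset,

    sigma(N) = sigma_inf + A exp(-N / k),

whose offset sigma_inf is the asymptotic (infinite-photon) precision.  The
same machinery applies unchanged to per-frame fitted spectral centers,
yielding the spectral precision floor.  A quadrature-form alternative fit
``sqrt(sigma_inf^2 + c/N)`` is provided for comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "FiducialGroup",
    "PrecisionCurve",
    "group_fiducials",
    "precision_from_scatter",
    "spectral_precision_from_scatter",
    "bin_and_fit",
    "precision_curve_from_table",
]


@dataclass
class FiducialGroup:
    """Localizations attributed to one fiducial bead."""

    members: pd.DataFrame
    mean_x_px: float
    mean_y_px: float
    mean_photons: float


@dataclass
class PrecisionCurve:
    """Binned precision-vs-photons curve and its exponential-decay fit."""

    photon_bin_centers: np.ndarray
    sigma_nm: np.ndarray
    n_per_bin: np.ndarray
    sigma_inf_nm: float
    sigma_inf_se_nm: float
    amplitude_nm: float
    decay_photons: float
    # comparison-only quadrature fit sqrt(floor^2 + c/N)
    quadrature_floor_nm: float = float("nan")


def group_fiducials(
    table: pd.DataFrame,
    square_px: float = 4.0,
    min_frame_fraction: float = 0.5,
    n_frames: int | None = None,
) -> list[FiducialGroup]:
    """Greedy grouping: localizations within a ``square_px`` square are one bead.

    Seeds are taken in descending group-size order on a coarse grid, then
    membership is the axis-aligned square about the running mean.  Beads
    localized in fewer than ``min_frame_fraction`` of the frames are dropped.
    """
    if n_frames is None:
        n_frames = int(table.attrs.get("n_frames", table["frame"].max() + 1))
    pts = table[["x_px", "y_px"]].to_numpy()
    unassigned = np.ones(len(table), dtype=bool)
    groups: list[FiducialGroup] = []
    half = square_px / 2.0
    while unassigned.any():
        idx = np.nonzero(unassigned)[0]
        # seed at the densest coarse-grid cell among unassigned points
        cells = np.floor(pts[idx] / half).astype(int)
        _, inv, counts = np.unique(cells, axis=0, return_inverse=True, return_counts=True)
        seed = idx[inv == np.argmax(counts)]
        cx, cy = pts[seed, 0].mean(), pts[seed, 1].mean()
        for _ in range(3):  # refine center on the square membership
            member = idx[
                (np.abs(pts[idx, 0] - cx) <= half) & (np.abs(pts[idx, 1] - cy) <= half)
            ]
            if member.size == 0:
                break
            cx, cy = pts[member, 0].mean(), pts[member, 1].mean()
        if member.size == 0:
            unassigned[seed] = False
            continue
        unassigned[member] = False
        sub = table.iloc[member]
        if len(sub) >= min_frame_fraction * n_frames:
            groups.append(
                FiducialGroup(
                    members=sub,
                    mean_x_px=float(cx),
                    mean_y_px=float(cy),
                    mean_photons=float(sub["photons"].mean()),
                )
            )
    return groups


def _gauss(x, amp, mu, sigma):
    return amp * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def _histogram_sigma(values: np.ndarray) -> float:
    """Gaussian-fit sigma of a 1D scatter histogram (falls back to sample sd)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2 or np.ptp(v) == 0:
        return 0.0
    n_bins = max(10, int(math.sqrt(v.size) * 1.5))
    counts, edges = np.histogram(v, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    sd = v.std(ddof=1)
    try:
        popt, _ = curve_fit(
            _gauss, centers, counts, p0=[counts.max(), v.mean(), sd], maxfev=400
        )
        sig = abs(float(popt[2]))
        if not np.isfinite(sig) or sig <= 0 or sig > 10 * sd:
            return sd
        return sig
    except Exception:
        return sd


def precision_from_scatter(
    group: FiducialGroup, pixel_size_nm: float, min_members: int = 20
) -> float:
    """Spatial precision of one bead: Gaussian-fit sigma of the x and y
    position histograms, the wider of the two, in nm.

    Raises on degenerate (all-identical) scatter or too few members.
    """
    if len(group.members) < min_members:
        raise ValueError(f"need >= {min_members} localizations, got {len(group.members)}")
    sx = _histogram_sigma(group.members["x_px"].to_numpy())
    sy = _histogram_sigma(group.members["y_px"].to_numpy())
    if sx == 0.0 and sy == 0.0:
        raise ValueError("degenerate scatter: all localizations identical")
    return max(sx, sy) * pixel_size_nm


def spectral_precision_from_scatter(group: FiducialGroup, min_members: int = 20) -> float:
    """Spectral precision of one bead: Gaussian-fit sigma of its per-frame
    fitted spectral centers, in nm."""
    if len(group.members) < min_members:
        raise ValueError(f"need >= {min_members} localizations, got {len(group.members)}")
    lam = group.members["wavelength_nm"].to_numpy()
    lam = lam[np.isfinite(lam)]
    if lam.size < min_members:
        raise ValueError("too few assigned spectral centers")
    s = _histogram_sigma(lam)
    if s == 0.0:
        raise ValueError("degenerate spectral scatter")
    return s


def _bin_edges(max_photons: float) -> np.ndarray:
    """Printed binning scheme: 200-wide bins below 2,000 photons, 500-wide above."""
    low = np.arange(0.0, 2000.0, 200.0)
    high = np.arange(2000.0, max(2500.0, math.ceil(max_photons / 500.0) * 500.0) + 1, 500.0)
    return np.concatenate([low, high])


def _exp_decay(n, s_inf, amp, k):
    return s_inf + amp * np.exp(-n / k)


def _quadrature(n, floor, c):
    return np.sqrt(floor**2 + c / n)


def bin_and_fit(
    photons: np.ndarray, sigma_nm: np.ndarray, min_bins: int = 5
) -> PrecisionCurve:
    """Bin per-group (photons, sigma) pairs and fit the exponential decay.

    Binning follows the printed scheme exactly (a 1,999-photon group falls in
    a 200-wide bin, a 2,001-photon group in a 500-wide bin).  The fit model is
    ``sigma_inf + A exp(-N/k)``; the offset and its standard error are the
    asymptotic precision.  A quadrature-form fit is run alongside for
    comparison.
    """
    photons = np.asarray(photons, dtype=float)
    sigma_nm = np.asarray(sigma_nm, dtype=float)
    edges = _bin_edges(photons.max())
    which = np.digitize(photons, edges) - 1
    centers, means, counts = [], [], []
    for b in range(len(edges) - 1):
        sel = which == b
        if sel.any():
            centers.append(0.5 * (edges[b] + edges[b + 1]))
            means.append(sigma_nm[sel].mean())
            counts.append(int(sel.sum()))
    if len(centers) < min_bins:
        raise ValueError(f"need >= {min_bins} populated photon bins, got {len(centers)}")
    centers = np.array(centers)
    means = np.array(means)
    counts = np.array(counts)
    span = means.max() - means.min()
    p0 = [means.min(), max(span, 1e-3), 500.0]
    try:
        popt, pcov = curve_fit(
            _exp_decay, centers, means, p0=p0,
            bounds=([0.0, 0.0, 10.0], [np.inf, np.inf, 1e5]), maxfev=5000,
        )
    except Exception as exc:
        raise RuntimeError(f"exponential-decay fit failed: {exc}") from exc
    s_inf, amp, k = popt
    se = float(np.sqrt(pcov[0, 0])) if np.all(np.isfinite(pcov)) else float("nan")
    try:
        qopt, _ = curve_fit(
            _quadrature, centers, means, p0=[max(means.min(), 1e-3), span**2 * 500.0],
            bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=5000,
        )
        q_floor = float(qopt[0])
    except Exception:
        q_floor = float("nan")
    return PrecisionCurve(
        photon_bin_centers=centers,
        sigma_nm=means,
        n_per_bin=counts,
        sigma_inf_nm=float(s_inf),
        sigma_inf_se_nm=se,
        amplitude_nm=float(amp),
        decay_photons=float(k),
        quadrature_floor_nm=q_floor,
    )


def precision_curve_from_table(
    table: pd.DataFrame,
    pixel_size_nm: float | None = None,
    mode: str = "spatial",
    min_members: int = 20,
    n_frames: int | None = None,
) -> PrecisionCurve:
    """Full stability pipeline: group fiducials, measure per-group precision
    (spatial scatter or spectral centers), bin and fit the decay."""
    if pixel_size_nm is None:
        pixel_size_nm = table.attrs.get("pixel_size_nm", 106.7)
    groups = group_fiducials(table, n_frames=n_frames)
    photons, sigmas = [], []
    for g in groups:
        try:
            if mode == "spatial":
                s = precision_from_scatter(g, pixel_size_nm, min_members)
            elif mode == "spectral":
                s = spectral_precision_from_scatter(g, min_members)
            else:
                raise ValueError(f"unknown mode {mode!r}")
        except ValueError:
            continue
        photons.append(g.mean_photons)
        sigmas.append(s)
    return bin_and_fit(np.array(photons), np.array(sigmas))
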