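"""2D peak detection on the TIC raster.

Local maxima are found on a lightly smoothed raster, footprints are assigned
by watershed from the maxima down to a fractional-height floor, and peaks are
gated on signal-to-noise (default S/N ≥ 100, the threshold applied to every
feature entering the fingerprint).  The apex spectrum is taken literally from
the single largest cube point of the footprint, and the 2D peak volume is the
baseline-subtracted sum of raster counts over the footprint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .chroma import Chromatogram2D, MassSpectrum, coords_of


@dataclass(frozen=True)
class Peak2D:
    """One detected 2D peak."""

    rt1: float                  # minutes
    rt2: float                  # seconds
    volume: float               # baseline-subtracted counts over footprint
    height: float               # apex TIC above baseline
    snr: float
    apex_spectrum: MassSpectrum
    apex_index: tuple[int, int]
    footprint: np.ndarray       # (k, 2) int array of raster points

    def __post_init__(self):
        if self.snr < 0:
            raise ValueError("snr must be non-negative")


def estimate_noise(raster: np.ndarray | Chromatogram2D) -> float:
    """Robust noise-SD of a TIC raster.

    Median absolute deviation (×1.4826) of the lower half of the raster
    values around the raster median; insensitive to peaks, which only occupy
    the upper tail.  Returns 0 (with a warning) for an all-zero raster.
    """
    if isinstance(raster, Chromatogram2D):
        raster = raster.tic()
    vals = np.asarray(raster, dtype=float).ravel()
    if vals.size == 0 or not np.any(vals):
        warnings.warn("all-zero raster: noise estimate is 0")
        return 0.0
    med = float(np.median(vals))
    lower = vals[vals <= med]
    return float(1.4826 * np.median(np.abs(lower - med)))


def detect_peaks(chrom: Chromatogram2D, snr_min: float = 100.0,
                 smooth_sigma: tuple[float, float] = (1.0, 3.0),
                 floor_frac: float = 0.05) -> list[Peak2D]:
    """Detect 2D peaks on the TIC raster of a run.

    Parameters
    ----------
    snr_min : float
        Minimum apex S/N (height above baseline / robust noise SD).
    smooth_sigma : (float, float)
        Gaussian smoothing (modulations, points) applied before maxima
        detection only; heights/volumes are measured on the raw raster.
    floor_frac : float
        Watershed floor as a fraction of each peak's apex height above
        baseline.  A separable 2D Gaussian truncated at a fraction f of its
        apex retains exactly 1−f of its integral, so measured volumes are
        divided by 1−f to undo the truncation.
    """
    raster = chrom.tic()
    noise = estimate_noise(raster)
    baseline = float(np.median(raster))
    if noise == 0.0:
        noise = np.inf  # no noise estimate -> nothing can pass the S/N gate

    # per-channel spectral background (median and robust SD over a strided
    # subsample of cube points), used to clean apex spectra of the detector
    # baseline so weak peaks still produce library-quality match factors
    sub = chrom.cube[::7, ::5, :].reshape(-1, chrom.cube.shape[2]).astype(np.float64)
    ch_base = np.median(sub, axis=0)
    ch_noise = 1.4826 * np.median(np.abs(sub - ch_base), axis=0)

    smoothed = ndimage.gaussian_filter(raster, sigma=smooth_sigma)
    sm_base = float(np.median(smoothed))
    # candidate maxima must stand clear of the smoothed baseline
    sm_noise = estimate_noise(smoothed)
    coords = peak_local_max(
        smoothed, min_distance=2,
        threshold_abs=sm_base + max(5.0 * sm_noise, 1e-12),
        exclude_border=False,
    )
    if coords.size == 0:
        return []
    # deterministic tie-break: lower (mod, pt) index first
    coords = coords[np.lexsort((coords[:, 1], coords[:, 0]))]

    markers = np.zeros(raster.shape, dtype=np.int32)
    for i, (r, c) in enumerate(coords, start=1):
        markers[r, c] = i
    mask = smoothed > sm_base + 2.0 * sm_noise
    mask |= markers > 0
    labels = watershed(-smoothed, markers=markers, mask=mask)

    peaks: list[Peak2D] = []
    for i, (r, c) in enumerate(coords, start=1):
        region = labels == i
        apex_flat = np.argmax(np.where(region, raster, -np.inf))
        ar, ac = np.unravel_index(apex_flat, raster.shape)
        height = float(raster[ar, ac] - baseline)
        snr = height / noise
        if snr < snr_min:
            continue
        floor = baseline + floor_frac * height
        foot = region & (raster >= floor)
        volume = float(np.maximum(raster[foot] - baseline, 0.0).sum())
        volume /= (1.0 - floor_frac)  # Gaussian truncation correction
        rt1, rt2 = coords_of((int(ar), int(ac)), chrom)
        apex = chrom.cube[ar, ac, :].astype(np.float64) - ch_base
        apex[apex < 3.0 * ch_noise] = 0.0
        if not np.any(apex > 0):  # degenerate: keep the raw spectrum
            apex = chrom.cube[ar, ac, :].astype(np.float64)
        peaks.append(Peak2D(
            rt1=rt1, rt2=rt2, volume=volume, height=height, snr=snr,
            apex_spectrum=MassSpectrum.from_dense(apex),
            apex_index=(int(ar), int(ac)),
            footprint=np.argwhere(foot),
        ))
    peaks.sort(key=lambda p: (p.rt1, p.rt2))
    return peaks


def peak_table(peaks: list[Peak2D], sample_id: str = "") -> pd.DataFrame:
    """Delimited-text-ready peak table (one row per detected peak)."""
    return pd.DataFrame({
        "sample_id": sample_id,
        "rt1_min": [p.rt1 for p in peaks],
        "rt2_s": [p.rt2 for p in peaks],
        "height": [p.height for p in peaks],
        "volume": [p.volume for p in peaks],
        "snr": [p.snr for p in peaks],
        "base_peak_mz": [p.apex_spectrum.base_peak for p in peaks],
    })
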