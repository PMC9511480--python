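"""Spectral preprocessing: baseline subtraction, smoothing, peaks, integration.

The processing chain applied before any quantification is the conventional
linear-mode MALDI-TOF one: resample to a uniform grid, remove the slowly
varying chemical baseline with a morphological top-hat, then smooth with a
Savitzky-Golay filter.  Feature areas are trapezoidal integrals over fixed
m/z windows; whole-spectrum fingerprints are TIC-normalized binned vectors.

Conventions: integration windows are closed intervals on the grid; bins are
half-open ``[low, low + w)``.  The baseline operator is a grayscale opening
(erosion then dilation with a flat structuring element), so the corrected
signal is nonnegative and ``corrected + baseline`` reconstructs the input
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter1d, minimum_filter1d
from scipy.signal import find_peaks, savgol_filter

from .errors import ParameterError
from .io import Spectrum

__all__ = [
    "ProcessingParams",
    "resample",
    "tophat_baseline",
    "savgol_smooth",
    "detect_peaks",
    "integrate_feature",
    "bin_spectrum",
    "preprocess",
    "default_halfwidth",
]


@dataclass
class ProcessingParams:
    """Tunable preprocessing parameters (all in Da unless noted).

    ``integration_halfwidth=None`` selects the adaptive default
    ``max(5 Da, 0.001 * mz)``, which tracks the linear-mode peak width
    (sigma ~ mz / 2000).
    """

    grid_spacing: float = 1.0
    tophat_window: float = 400.0
    savgol_window: int = 9          # points, odd
    savgol_order: int = 3
    snr_threshold: float = 3.0
    integration_halfwidth: float | None = None
    bin_width: float = 5.0

    def __post_init__(self) -> None:
        if self.grid_spacing <= 0 or self.tophat_window <= 0 or self.bin_width <= 0:
            raise ParameterError("grid_spacing, tophat_window and bin_width must be > 0")
        if self.savgol_window != 1:
            if self.savgol_window % 2 == 0:
                raise ParameterError("savgol_window must be odd")
            if self.savgol_window <= self.savgol_order:
                raise ParameterError("savgol_window must exceed savgol_order")


def default_halfwidth(mz: float) -> float:
    """Adaptive integration half-width: max(5 Da, 0.001 x m/z)."""
    return max(5.0, 1e-3 * mz)


def _is_uniform(mz: np.ndarray, spacing: float) -> bool:
    d = np.diff(mz)
    return bool(np.allclose(d, spacing, rtol=1e-6, atol=1e-9))


def resample(spectrum: Spectrum, spacing: float = 1.0) -> Spectrum:
    """Linear-interpolate a spectrum onto a uniform grid of the given spacing."""
    if spacing <= 0:
        raise ParameterError("grid spacing must be > 0")
    if _is_uniform(spectrum.mz, spacing):
        return spectrum
    lo, hi = spectrum.mz[0], spectrum.mz[-1]
    grid = np.arange(lo, hi + spacing / 2, spacing)
    grid = grid[grid <= hi]
    inten = np.interp(grid, spectrum.mz, spectrum.intensity)
    return Spectrum(grid, inten, {**spectrum.metadata, "resampled": spacing})


def tophat_baseline(spectrum: Spectrum, window: float = 400.0) -> tuple[Spectrum, Spectrum]:
    """Morphological top-hat baseline subtraction.

    The baseline is the grayscale opening of the signal with a flat
    structuring element of width ``window`` (Da): a moving minimum (erosion)
    followed by a moving maximum (dilation), edges handled by edge-value
    replication.  Returns ``(corrected, baseline)`` with
    ``corrected = signal - baseline >= 0`` and exact reconstruction.
    """
    spacing = float(np.median(np.diff(spectrum.mz)))
    spec = spectrum if _is_uniform(spectrum.mz, spacing) else resample(spectrum, spacing)
    size = int(round(window / spacing))
    if size < 3:
        raise ParameterError(
            f"tophat window {window} Da spans {size} grid points; need >= 3"
        )
    if size % 2 == 0:
        size += 1  # symmetric flat structuring element
    eroded = minimum_filter1d(spec.intensity, size=size, mode="nearest")
    baseline = maximum_filter1d(eroded, size=size, mode="nearest")
    corrected = spec.intensity - baseline
    return (
        spec.copy_with(corrected, baseline_corrected=True),
        spec.copy_with(baseline),
    )


def savgol_smooth(spectrum: Spectrum, window: int = 9, order: int = 3) -> Spectrum:
    """Savitzky-Golay smoothing.

    Each output point is the value of the least-squares polynomial of degree
    ``order`` fitted over the surrounding ``window`` points; the terminal
    windows are handled by polynomial extrapolation (scipy's ``mode='interp'``).
    ``window=1`` is the identity.
    """
    if window == 1:
        return spectrum.copy_with(spectrum.intensity.copy(), smoothed=True)
    if window % 2 == 0:
        raise ParameterError("Savitzky-Golay window must be odd")
    if window <= order:
        raise ParameterError("Savitzky-Golay window must exceed the polynomial order")
    smoothed = savgol_filter(spectrum.intensity, window, order, mode="interp")
    return spectrum.copy_with(smoothed, smoothed=True)


def _local_noise(spec: Spectrum, apex_idx: int, sigma: float, halfspan: float = 100.0) -> float:
    """Robust local noise: 1.4826 x MAD within +/-100 Da, excluding +/-3 sigma of the apex."""
    mz = spec.mz
    center = mz[apex_idx]
    sel = (np.abs(mz - center) <= halfspan) & (np.abs(mz - center) > 3.0 * sigma)
    if not np.any(sel):
        return 0.0
    vals = spec.intensity[sel]
    return 1.4826 * float(np.median(np.abs(vals - np.median(vals))))


def detect_peaks(spectrum: Spectrum, params: ProcessingParams | None = None):
    """Find local maxima with SNR above threshold on a corrected, smoothed spectrum.

    Apices closer than 3 grid points are merged into one.  Returns a list of
    ``(mz_apex, intensity, snr)`` sorted by m/z; flat or all-noise spectra
    yield an empty list.
    """
    params = params or ProcessingParams()
    idx, _ = find_peaks(spectrum.intensity, distance=3)
    out = []
    for i in idx:
        apex = float(spectrum.intensity[i])
        if apex <= 0:
            continue
        sigma = spectrum.mz[i] / 2000.0  # linear-mode width model
        noise = _local_noise(spectrum, i, sigma)
        snr = np.inf if noise == 0 else apex / noise
        if snr >= params.snr_threshold:
            out.append((float(spectrum.mz[i]), apex, float(snr)))
    return out


def integrate_feature(spectrum: Spectrum, mz_center: float, halfwidth: float | None = None) -> float:
    """Trapezoidal area of the (baseline-corrected) signal in a closed window.

    The window is ``[mz_center - halfwidth, mz_center + halfwidth]`` on the
    grid; negative trapezoid sums (possible after smoothing overshoot) are
    clipped to zero.
    """
    if halfwidth is None:
        halfwidth = default_halfwidth(mz_center)
    lo, hi = mz_center - halfwidth, mz_center + halfwidth
    if lo < spectrum.mz[0] or hi > spectrum.mz[-1]:
        raise ParameterError(
            f"integration window [{lo}, {hi}] outside spectrum range "
            f"[{spectrum.mz[0]}, {spectrum.mz[-1]}]"
        )
    sel = (spectrum.mz >= lo) & (spectrum.mz <= hi)
    area = float(np.trapezoid(spectrum.intensity[sel], spectrum.mz[sel]))
    return max(area, 0.0)


def bin_spectrum(
    spectrum: Spectrum,
    bin_width: float = 5.0,
    mass_range: tuple[float, float] = (2000.0, 20000.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Sum intensities into half-open bins and normalize to unit total.

    Returns ``(bin_centers, vector)`` where ``vector`` sums to 1 (TIC
    normalization), making the fingerprint invariant to overall intensity
    scale.
    """
    low, high = mass_range
    if not high > low:
        raise ParameterError("empty mass range")
    edges = np.arange(low, high + bin_width / 2, bin_width)
    if edges[-1] < high:
        edges = np.append(edges, edges[-1] + bin_width)
    sel = (spectrum.mz >= low) & (spectrum.mz < high)  # half-open bins
    sums, _ = np.histogram(spectrum.mz[sel], bins=edges, weights=spectrum.intensity[sel])
    total = sums.sum()
    if total <= 0:
        raise ParameterError("zero total ion current; cannot normalize binned vector")
    centers = edges[:-1] + bin_width / 2
    return centers, sums / total


def preprocess(spectrum: Spectrum, params: ProcessingParams | None = None) -> Spectrum:
    """Full chain: resample -> top-hat baseline -> Savitzky-Golay smoothing."""
    params = params or ProcessingParams()
    spec = resample(spectrum, params.grid_spacing)
    corrected, _ = tophat_baseline(spec, params.tophat_window)
    return savgol_smooth(corrected, params.savgol_window, params.savgol_order)
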