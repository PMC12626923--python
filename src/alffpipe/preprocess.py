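"""Temporal/spatial preprocessing of already-registered 4D BOLD data.

Stages: initial-volume discard, isotropic Gaussian smoothing, band-pass
filtering (ideal DFT boxcar by default, Butterworth optional) and per-voxel
linear detrending.  Default stage order follows the source protocol
(smooth -> bandpass -> detrend); callers may reorder.
"""

from __future__ import annotations

from typing import Sequence, Union

import numpy as np
from scipy import ndimage, signal

from .core import BoldSeries, SpectrumBand, VoxelMap

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

DEFAULT_ORDER = ("smooth", "bandpass", "detrend")


def discard_initial(series: BoldSeries, n_discard: int) -> BoldSeries:
    """Drop the first `n_discard` volumes."""
    if n_discard < 0:
        raise ValueError("n_discard must be >= 0")
    if n_discard >= series.n_timepoints:
        raise ValueError(
            f"cannot discard {n_discard} of {series.n_timepoints} timepoints"
        )
    if n_discard == 0:
        return series
    return series.with_values(series.values[..., n_discard:])


def _smooth_volume(vol: np.ndarray, sigma_vox: Sequence[float]) -> np.ndarray:
    # nearest-edge padding: biases boundary smoothness estimates but keeps
    # constants exactly constant
    return ndimage.gaussian_filter(vol, sigma=sigma_vox, mode="nearest")


def smooth_gaussian(
    obj: Union[BoldSeries, VoxelMap], fwhm_mm: float
) -> Union[BoldSeries, VoxelMap]:
    """Convolve each volume with an isotropic Gaussian of the given FWHM (mm)."""
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return obj
    sigma_vox = [fwhm_mm / (vs * FWHM_TO_SIGMA) for vs in obj.voxel_size_mm]
    if isinstance(obj, BoldSeries):
        out = np.empty_like(obj.values)
        for t in range(obj.n_timepoints):
            out[..., t] = _smooth_volume(obj.values[..., t], sigma_vox)
        return obj.with_values(out)
    return obj.with_values(_smooth_volume(obj.values, sigma_vox))


def _ideal_bandpass_matrix(x: np.ndarray, tr_s: float, band: SpectrumBand) -> np.ndarray:
    """DFT-boxcar band-pass of the last axis; closed band edges, DC always removed."""
    n = x.shape[-1]
    freqs = np.fft.rfftfreq(n, d=tr_s)
    keep = (freqs >= band.f_low_hz) & (freqs <= band.f_high_hz)
    keep[0] = False
    spec = np.fft.rfft(x, axis=-1)
    spec[..., ~keep] = 0.0
    return np.fft.irfft(spec, n=n, axis=-1)


def _butter_bandpass_matrix(x: np.ndarray, tr_s: float, band: SpectrumBand, order: int = 4) -> np.ndarray:
    nyq = 1.0 / (2.0 * tr_s)
    sos = signal.butter(
        order, [band.f_low_hz / nyq, band.f_high_hz / nyq], btype="band", output="sos"
    )
    return signal.sosfiltfilt(sos, x - x.mean(axis=-1, keepdims=True), axis=-1)


def bandpass(
    series: BoldSeries, band: SpectrumBand, method: str = "ideal"
) -> BoldSeries:
    """Band-pass filter every voxel time series.

    `method="ideal"` zeroes all DFT bins outside the closed band (the same
    frequency-domain convention the ALFF computation uses); `"butter"` applies
    a zero-phase 4th-order Butterworth filter.
    """
    band.validate_for_tr(series.tr_s)
    if method == "ideal":
        out = _ideal_bandpass_matrix(series.values, series.tr_s, band)
    elif method == "butter":
        out = _butter_bandpass_matrix(series.values, series.tr_s, band)
    else:
        raise ValueError(f"unknown bandpass method {method!r}")
    return series.with_values(out)


def detrend_linear(series: BoldSeries) -> BoldSeries:
    """Subtract the per-voxel least-squares line (intercept + slope)."""
    if series.n_timepoints < 3:
        raise ValueError("detrend needs at least 3 timepoints")
    out = detrend_array(series.values)
    return series.with_values(out)


def detrend_array(x: np.ndarray) -> np.ndarray:
    """Least-squares linear detrend along the last axis."""
    n = x.shape[-1]
    t = np.arange(n, dtype=np.float64)
    t_c = t - t.mean()
    denom = (t_c**2).sum()
    mean = x.mean(axis=-1, keepdims=True)
    slope = (x * t_c).sum(axis=-1, keepdims=True) / denom
    return x - mean - slope * t_c


def preprocess_series(
    series: BoldSeries,
    n_discard: int = 10,
    fwhm_mm: float = 6.0,
    band: SpectrumBand | None = None,
    order: Sequence[str] = DEFAULT_ORDER,
    bandpass_method: str = "ideal",
) -> BoldSeries:
    """Run the full temporal preprocessing chain in the configured order."""
    band = band or SpectrumBand()
    out = discard_initial(series, n_discard)
    steps = {
        "smooth": lambda s: smooth_gaussian(s, fwhm_mm),
        "bandpass": lambda s: bandpass(s, band, method=bandpass_method),
        "detrend": lambda s: detrend_linear(s),
    }
    for name in order:
        if name not in steps:
            raise ValueError(f"unknown preprocessing stage {name!r}")
        out = steps[name](out)
    return out
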