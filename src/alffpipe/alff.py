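"""Static ALFF: band-limited amplitude spectrum means, per voxel.

The amplitude spectrum is the one-sided DFT magnitude scaled so that a pure
unit-amplitude sinusoid at an exact bin reads 1 at that bin.  ALFF is the mean
amplitude over the frequency bins falling inside the closed analysis band;
mALFF divides by the global in-mask mean.
"""

from __future__ import annotations

import numpy as np

from .core import BoldSeries, SpectrumBand, VoxelMap


def amplitude_spectrum(signal: np.ndarray, tr_s: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided amplitude spectrum of a 1D series.

    Bin k carries (2/N)|X_k| for 0 < k < N/2; the DC and (even-N) Nyquist bins
    are scaled 1/N so they report the actual mean / alternating amplitude.
    """
    x = np.asarray(signal, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("signal must be 1D")
    if x.size < 4:
        raise ValueError("signal too short (need >= 4 samples)")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in signal")
    n = x.size
    freqs = np.fft.rfftfreq(n, d=tr_s)
    amps = np.abs(np.fft.rfft(x)) * (2.0 / n)
    amps[0] /= 2.0
    if n % 2 == 0:
        amps[-1] /= 2.0
    return freqs, amps


def band_bin_indices(n: int, tr_s: float, band: SpectrumBand) -> np.ndarray:
    """Indices of one-sided DFT bins with f_low <= f <= f_high (DC excluded)."""
    freqs = np.fft.rfftfreq(n, d=tr_s)
    idx = np.nonzero((freqs >= band.f_low_hz) & (freqs <= band.f_high_hz) & (freqs > 0))[0]
    return idx


def alff(
    signal: np.ndarray,
    tr_s: float,
    band: SpectrumBand,
    denominator: str = "bin_count",
) -> float:
    """Band-mean amplitude of one voxel time series.

    denominator="bin_count" averages over the number of in-band bins;
    "printed" uses N2-N1 (index difference), kept for compatibility with the
    typeset formula.
    """
    _, amps = amplitude_spectrum(signal, tr_s)
    idx = band_bin_indices(len(signal), tr_s, band)
    if idx.size == 0:
        raise ValueError(
            f"band ({band.f_low_hz}, {band.f_high_hz}) Hz contains no bins for "
            f"N={len(signal)}, TR={tr_s}s"
        )
    total = amps[idx].sum()
    if denominator == "bin_count":
        return float(total / idx.size)
    if denominator == "printed":
        if idx[-1] == idx[0]:
            raise ValueError("printed denominator N2-N1 is zero (single bin)")
        return float(total / (idx[-1] - idx[0]))
    raise ValueError(f"unknown denominator convention {denominator!r}")


def _alff_matrix(ts: np.ndarray, tr_s: float, band: SpectrumBand,
                 denominator: str = "bin_count") -> np.ndarray:
    """Vectorized ALFF over rows of a (n_voxels, t) matrix."""
    n = ts.shape[-1]
    idx = band_bin_indices(n, tr_s, band)
    if idx.size == 0:
        raise ValueError("band contains no bins at this length/TR")
    amps = np.abs(np.fft.rfft(ts, axis=-1)) * (2.0 / n)
    total = amps[..., idx].sum(axis=-1)
    if denominator == "bin_count":
        return total / idx.size
    return total / (idx[-1] - idx[0])


def alff_map(
    series: BoldSeries,
    band: SpectrumBand,
    denominator: str = "bin_count",
) -> VoxelMap:
    """Per-voxel ALFF over the series mask; out-of-mask voxels are 0."""
    if not series.mask.any():
        raise ValueError("empty mask")
    band.validate_for_tr(series.tr_s)
    vals = np.zeros(series.mask.shape, dtype=np.float64)
    vals[series.mask] = _alff_matrix(
        series.in_mask_timeseries(), series.tr_s, band, denominator
    )
    return VoxelMap(
        values=vals,
        mask=series.mask,
        kind="alff",
        voxel_size_mm=series.voxel_size_mm,
        affine=series.affine,
        meta={"band": (band.f_low_hz, band.f_high_hz), "denominator": denominator},
    )


def falff_map(series: BoldSeries, band: SpectrumBand) -> VoxelMap:
    """Canonical fractional ALFF: band amplitude sum / full-spectrum amplitude sum.

    Extension beyond the source protocol (which uses global-mean normalization);
    provided under its literature meaning and clearly labeled.
    """
    if not series.mask.any():
        raise ValueError("empty mask")
    band.validate_for_tr(series.tr_s)
    ts = series.in_mask_timeseries()
    n = ts.shape[-1]
    amps = np.abs(np.fft.rfft(ts, axis=-1)) * (2.0 / n)
    idx = band_bin_indices(n, series.tr_s, band)
    full = amps[..., 1:].sum(axis=-1)  # exclude DC
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(full > 0, amps[..., idx].sum(axis=-1) / full, 0.0)
    vals = np.zeros(series.mask.shape, dtype=np.float64)
    vals[series.mask] = frac
    return VoxelMap(
        values=vals, mask=series.mask, kind="falff",
        voxel_size_mm=series.voxel_size_mm, affine=series.affine,
        meta={"band": (band.f_low_hz, band.f_high_hz)},
    )


def normalize_by_global_mean(vmap: VoxelMap) -> VoxelMap:
    """Divide by the in-mask mean so the returned map has in-mask mean exactly 1."""
    mean = vmap.in_mask().mean()
    if not (mean > 0):
        raise ValueError(f"in-mask mean must be positive, got {mean}")
    out = np.zeros_like(vmap.values)
    out[vmap.mask] = vmap.values[vmap.mask] / mean
    res = vmap.with_values(out, kind="malff")
    res.meta = dict(vmap.meta, global_mean=float(mean))
    return res
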