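"""Dynamic ALFF: sliding-window ALFF and its across-window variance.

Windows are rectangular (no taper) by default; each window is linearly
detrended before its FFT because short windows are drift-dominated.  The
across-window variance is the population variance (divide by the number of
windows) and the z-scored map uses the population SD, both in-mask.
"""

from __future__ import annotations

import numpy as np

from .alff import _alff_matrix
from .core import BoldSeries, SpectrumBand, VoxelMap, WindowScheme
from .preprocess import detrend_array


def window_starts(n_timepoints: int, scheme: WindowScheme) -> list[int]:
    """Start indices 0, S, 2S, ... while start + L <= n; remainder dropped."""
    if n_timepoints < scheme.length_tr:
        raise ValueError(
            f"series length {n_timepoints} < window length {scheme.length_tr}"
        )
    n_windows = (n_timepoints - scheme.length_tr) // scheme.step_tr + 1
    return [i * scheme.step_tr for i in range(n_windows)]


def windowed_alff(
    series: BoldSeries,
    band: SpectrumBand,
    scheme: WindowScheme,
    detrend_windows: bool = True,
    taper: str = "rect",
) -> np.ndarray:
    """(n_windows, n_mask_voxels) per-window ALFF values."""
    starts = window_starts(series.n_timepoints, scheme)
    ts = series.in_mask_timeseries()
    L = scheme.length_tr
    out = np.empty((len(starts), ts.shape[0]), dtype=np.float64)
    if taper == "hann":
        w = np.hanning(L)
    elif taper == "rect":
        w = None
    else:
        raise ValueError(f"unknown taper {taper!r}")
    for i, s in enumerate(starts):
        seg = ts[:, s : s + L]
        if detrend_windows:
            seg = detrend_array(seg)
        if w is not None:
            seg = seg * w
        out[i] = _alff_matrix(seg, series.tr_s, band)
    return out


def dalff_map(
    series: BoldSeries,
    band: SpectrumBand,
    scheme: WindowScheme,
    detrend_windows: bool = True,
    taper: str = "rect",
) -> VoxelMap:
    """Across-window population variance of windowed ALFF, per voxel."""
    if not series.mask.any():
        raise ValueError("empty mask")
    per_window = windowed_alff(series, band, scheme, detrend_windows, taper)
    var = per_window.var(axis=0)  # population variance (ddof=0)
    vals = np.zeros(series.mask.shape, dtype=np.float64)
    vals[series.mask] = var
    return VoxelMap(
        values=vals,
        mask=series.mask,
        kind="dalff_var",
        voxel_size_mm=series.voxel_size_mm,
        affine=series.affine,
        meta={
            "band": (band.f_low_hz, band.f_high_hz),
            "window_length_tr": scheme.length_tr,
            "window_step_tr": scheme.step_tr,
            "n_windows": per_window.shape[0],
        },
    )


def zscore_map(vmap: VoxelMap) -> VoxelMap:
    """In-mask z-scoring (population SD); result has mean 0 and SD 1 exactly."""
    inm = vmap.in_mask()
    sd = inm.std()  # ddof=0
    if sd <= 0:
        raise ValueError("in-mask SD is zero; cannot z-score a constant map")
    out = np.zeros_like(vmap.values)
    out[vmap.mask] = (inm - inm.mean()) / sd
    res = vmap.with_values(out, kind="dalff_z")
    res.meta = dict(vmap.meta, zscore_mean=float(inm.mean()), zscore_sd=float(sd))
    return res
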