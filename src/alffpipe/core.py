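"""Core data structures shared across the pipeline.

All spatial data live on a common voxel grid.  A :class:`BoldSeries` is one
subject-session 4D acquisition; a :class:`VoxelMap` is a single 3D statistic
image defined over the same mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

VALID_MAP_KINDS = frozenset(
    {"alff", "malff", "falff", "dalff_var", "dalff_z", "tstat", "zstat", "residual", "other"}
)


def default_affine(voxel_size_mm: float | tuple[float, float, float]) -> np.ndarray:
    """Axis-aligned affine with the given voxel size, origin at the grid corner."""
    if np.isscalar(voxel_size_mm):
        vs = (float(voxel_size_mm),) * 3
    else:
        vs = tuple(float(v) for v in voxel_size_mm)
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = vs
    return aff


@dataclass
class BoldSeries:
    """A 4D BOLD lattice (x, y, z, t) with geometry, TR and brain mask."""

    values: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    tr_s: float
    mask: np.ndarray
    subject_id: str = ""
    session: str = "single"
    affine: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 4:
            raise ValueError(f"BoldSeries values must be 4D, got ndim={self.values.ndim}")
        if self.mask.shape != self.values.shape[:3]:
            raise ValueError(
                f"mask shape {self.mask.shape} != spatial dims {self.values.shape[:3]}"
            )
        if self.values.shape[3] < 2:
            raise ValueError("BoldSeries needs at least 2 timepoints")
        if np.isscalar(self.voxel_size_mm):
            self.voxel_size_mm = (float(self.voxel_size_mm),) * 3
        else:
            self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if self.affine is None:
            self.affine = default_affine(self.voxel_size_mm)
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("non-finite values inside mask")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[3]

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.values.shape

    def with_values(self, values: np.ndarray) -> "BoldSeries":
        return replace(self, values=np.asarray(values, dtype=np.float64))

    def in_mask_timeseries(self) -> np.ndarray:
        """(n_mask_voxels, t) view of the in-mask time series."""
        return self.values[self.mask]


@dataclass
class VoxelMap:
    """A 3D per-voxel statistic image restricted to a mask."""

    values: np.ndarray
    mask: np.ndarray
    kind: str = "other"
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    affine: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 3:
            raise ValueError(f"VoxelMap values must be 3D, got ndim={self.values.ndim}")
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape mismatch")
        if self.kind not in VALID_MAP_KINDS:
            raise ValueError(f"unknown map kind {self.kind!r}")
        if np.isscalar(self.voxel_size_mm):
            self.voxel_size_mm = (float(self.voxel_size_mm),) * 3
        else:
            self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if self.affine is None:
            self.affine = default_affine(self.voxel_size_mm)
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("non-finite values inside mask")

    def in_mask(self) -> np.ndarray:
        return self.values[self.mask]

    def with_values(self, values: np.ndarray, kind: Optional[str] = None) -> "VoxelMap":
        return replace(
            self, values=np.asarray(values, dtype=np.float64), kind=kind or self.kind
        )


@dataclass(frozen=True)
class SpectrumBand:
    """Closed frequency interval [f_low_hz, f_high_hz] used for ALFF."""

    f_low_hz: float = 0.01
    f_high_hz: float = 0.08

    def __post_init__(self) -> None:
        if not (0.0 < self.f_low_hz < self.f_high_hz):
            raise ValueError(
                f"need 0 < f_low < f_high, got ({self.f_low_hz}, {self.f_high_hz})"
            )

    def validate_for_tr(self, tr_s: float) -> None:
        nyquist = 1.0 / (2.0 * tr_s)
        if self.f_high_hz >= nyquist:
            raise ValueError(
                f"band upper edge {self.f_high_hz} Hz >= Nyquist {nyquist:.4f} Hz "
                f"for TR {tr_s}s"
            )


@dataclass(frozen=True)
class WindowScheme:
    """Sliding-window segmentation: window length and step, both in TRs."""

    length_tr: int = 50
    step_tr: int = 20

    def __post_init__(self) -> None:
        if not (1 <= self.step_tr <= self.length_tr):
            raise ValueError(
                f"need 1 <= step ({self.step_tr}) <= length ({self.length_tr})"
            )


@dataclass
class SmoothnessEstimate:
    """Per-axis FWHM (mm) of the residual field and RESEL counts of the mask."""

    fwhm_mm: tuple[float, float, float]
    resels: tuple[float, float, float, float]  # R0..R3
    voxel_size_mm: tuple[float, float, float]

    @property
    def fwhm_vox(self) -> np.ndarray:
        return np.asarray(self.fwhm_mm) / np.asarray(self.voxel_size_mm)


@dataclass
class ClusterRecord:
    """One suprathreshold cluster: a row of the cluster report table."""

    cluster_id: int
    size_voxels: int
    peak_coord_mm: tuple[float, float, float]
    peak_grid_index: tuple[int, int, int]
    peak_stat: float
    cluster_p_corrected: float
    sign: str  # "+" or "-"
    atlas_label: str = "unlabeled"
    voxel_indices: Optional[np.ndarray] = None  # (k, 3) grid indices

    def __post_init__(self) -> None:
        if self.sign not in ("+", "-"):
            raise ValueError("sign must be '+' or '-'")
        if self.size_voxels < 1:
            raise ValueError("cluster size must be >= 1")
        if not (0.0 < self.cluster_p_corrected <= 1.0):
            raise ValueError("corrected p must lie in (0, 1]")


@dataclass
class TStatResult:
    """Voxelwise t contrast with the residual maps needed for smoothness estimation."""

    t_map: VoxelMap
    df: int
    residual_maps: list[VoxelMap]
    contrast: str = ""

    def __post_init__(self) -> None:
        if self.df <= 0:
            raise ValueError("df must be positive")
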