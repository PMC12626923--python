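"""Longitudinal delta analysis and clinical scoring utilities.

ROI means are extracted from per-subject maps, post - pre differences are
correlated (Pearson) with changes in clinical indices, and p-values are
Bonferroni-adjusted over the configured test family.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special

from .core import VoxelMap

CLINICAL_DELTA_INDICES = (
    "nct_a_s",
    "dst_score",
    "prothrombin_time_s",
    "albumin_mg_dl",
    "total_bilirubin_mg_dl",
    "ammonia_umol_l",
)


def extract_roi_mean(vmap: VoxelMap, roi_mask: np.ndarray) -> float:
    """Arithmetic mean of map values over the ROI voxels."""
    roi = np.asarray(roi_mask, dtype=bool)
    if roi.shape != vmap.values.shape:
        raise ValueError("ROI shape does not match map")
    if not roi.any():
        raise ValueError("empty ROI")
    return float(vmap.values[roi].mean())


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson r and the two-sided p from t = r sqrt((n-2)/(1-r^2))."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc * xc).sum())
    sy = np.sqrt((yc * yc).sum())
    if sx == 0 or sy == 0:
        raise ValueError("constant input; correlation undefined")
    r = float(np.clip((xc * yc).sum() / (sx * sy), -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * special.stdtr(n - 2, -abs(t)))
    return r, p


def bonferroni(p_values: Sequence[float], m: int) -> np.ndarray:
    """Adjusted p = min(1, m * p)."""
    p = np.asarray(p_values, dtype=np.float64)
    if m < len(p):
        raise ValueError(f"m ({m}) must be >= number of tests ({len(p)})")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, m * p)


def child_pugh_class(points: int) -> str:
    """Liver-function class from the 5-15 point score: A 5-6, B 7-9, C 10-15."""
    if not (5 <= points <= 15):
        raise ValueError(f"Child-Pugh points must be in 5..15, got {points}")
    if points <= 6:
        return "A"
    if points <= 9:
        return "B"
    return "C"


@dataclass(frozen=True)
class CognitiveNorms:
    """Healthy-control normative mean and SD for one neuropsychological test."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("norm SD must be positive")


def flag_mhe(
    nct_a_s: float, dst_score: float, nct_norms: CognitiveNorms, dst_norms: CognitiveNorms
) -> bool:
    """2-SD rule, one-sided toward impairment: NCT-A slow OR DST low."""
    if nct_a_s is None or dst_score is None or not np.isfinite([nct_a_s, dst_score]).all():
        raise ValueError("missing test values")
    return bool(
        nct_a_s > nct_norms.mean + 2 * nct_norms.sd
        or dst_score < dst_norms.mean - 2 * dst_norms.sd
    )


def compute_clinical_deltas(
    subjects_pre: pd.DataFrame,
    subjects_post: pd.DataFrame,
    indices: Sequence[str] = CLINICAL_DELTA_INDICES,
) -> pd.DataFrame:
    """Post - pre clinical deltas, matched on subject id."""
    pre = subjects_pre.set_index("id")
    post = subjects_post.set_index("id")
    if set(pre.index) != set(post.index):
        raise ValueError("pre/post subject ids do not match")
    post = post.loc[pre.index]
    out = pd.DataFrame(index=pre.index)
    for col in indices:
        out["d_" + col] = post[col].astype(float) - pre[col].astype(float)
    return out.reset_index()


def run_delta_analysis(
    pre_maps: Sequence[VoxelMap],
    post_maps: Sequence[VoxelMap],
    cluster_rois: Mapping[str, np.ndarray],
    subjects_pre: pd.DataFrame,
    subjects_post: pd.DataFrame,
    m_tests: Optional[int] = None,
    alpha: float = 0.05,
    indices: Sequence[str] = CLINICAL_DELTA_INDICES,
) -> pd.DataFrame:
    """Full cross of ROIs x clinical delta indices with Bonferroni correction.

    `cluster_rois` maps a region label to its boolean mask (the exact
    suprathreshold cluster from the paired contrast, not a sphere).  The
    Bonferroni family defaults to the number of ROIs, applied per clinical
    index; pass m_tests=len(rois)*len(indices) for the stricter family.
    Degenerate (constant) inputs yield NaN r/p for that pair rather than
    aborting the whole table.
    """
    if len(pre_maps) != len(post_maps):
        raise ValueError("pre/post map lists differ in length")
    deltas_clin = compute_clinical_deltas(subjects_pre, subjects_post, indices)
    n = len(pre_maps)
    if len(deltas_clin) != n:
        raise ValueError("subject table rows do not match number of map pairs")
    if m_tests is None:
        m_tests = len(cluster_rois)

    roi_deltas: dict[str, np.ndarray] = {}
    for name, roi in cluster_rois.items():
        d = np.array(
            [extract_roi_mean(post_maps[i], roi) - extract_roi_mean(pre_maps[i], roi)
             for i in range(n)]
        )
        roi_deltas[name] = d

    rows = []
    for roi_name, d_roi in roi_deltas.items():
        for index in indices:
            d_clin = deltas_clin["d_" + index].to_numpy()
            try:
                r, p = pearson_r(d_roi, d_clin)
            except ValueError as exc:
                rows.append(
                    {"roi": roi_name, "index": index, "r": np.nan, "p": np.nan,
                     "p_adjusted": np.nan, "significant": False, "note": str(exc)}
                )
                continue
            p_adj = float(bonferroni([p], m_tests)[0])
            rows.append(
                {"roi": roi_name, "index": index, "r": r, "p": p,
                 "p_adjusted": p_adj, "significant": bool(p_adj < alpha), "note": ""}
            )
    return pd.DataFrame(rows)
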