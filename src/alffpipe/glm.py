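"""Voxelwise covariate-adjusted group contrasts.

Two-sample contrasts are ordinary-least-squares fits of
value ~ intercept + group + centered covariates, with the t statistic on the
group column.  Paired contrasts are one-sample t tests on per-subject
(post - pre) difference maps.  Residual maps are retained for random-field
smoothness estimation.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special

from .core import BoldSeries, TStatResult, VoxelMap

# |t| assigned at voxels whose difference has zero variance but nonzero mean
CENSORED_T = 1e6


def _stack_maps(maps: Sequence[VoxelMap], mask: np.ndarray) -> np.ndarray:
    return np.stack([m.values[mask] for m in maps], axis=0)


def _common_mask(maps: Sequence[VoxelMap]) -> np.ndarray:
    mask = maps[0].mask
    for m in maps[1:]:
        if m.mask.shape != mask.shape or not np.array_equal(m.mask, mask):
            raise ValueError("input maps have mismatched masks")
    return mask


def build_design(
    group_indicator: np.ndarray, covariates: Optional[pd.DataFrame]
) -> tuple[np.ndarray, list[str]]:
    """Design matrix [intercept, group, centered covariates]; checks rank."""
    n = len(group_indicator)
    cols = [np.ones(n), np.asarray(group_indicator, dtype=np.float64)]
    names = ["intercept", "group"]
    if covariates is not None:
        if len(covariates) != n:
            raise ValueError("covariate rows do not align with maps")
        for name in covariates.columns:
            c = covariates[name].to_numpy(dtype=np.float64)
            cols.append(c - c.mean())  # centered: contrast holds at covariate means
            names.append(name)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return X, names


def _ols_t(Y: np.ndarray, X: np.ndarray, contrast_col: int) -> tuple[np.ndarray, np.ndarray, int]:
    """OLS per column of Y; returns (t, residuals, df) for the given column's beta."""
    n, p = X.shape
    df = n - p
    if df <= 0:
        raise ValueError(f"non-positive degrees of freedom (n={n}, p={p})")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ Y)
    resid = Y - X @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    sigma2 = rss / df
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[contrast_col, contrast_col], 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(se > 0, beta[contrast_col] / se, 0.0)
    return t, resid, df


def two_sample_t(
    maps_a: Sequence[VoxelMap],
    maps_b: Sequence[VoxelMap],
    covariates: Optional[pd.DataFrame] = None,
    contrast: str = "A>B",
) -> TStatResult:
    """Voxelwise two-sample contrast; positive t means group A > group B.

    Covariate rows must be ordered maps_a then maps_b.  Voxels with zero
    variance across all subjects are dropped from the analysis mask.
    """
    if len(maps_a) < 2 or len(maps_b) < 2:
        raise ValueError("need at least 2 maps per group")
    all_maps = list(maps_a) + list(maps_b)
    mask = _common_mask(all_maps)
    Y = _stack_maps(all_maps, mask)

    analysis_mask = mask.copy()
    var_ok = Y.var(axis=0) > 0
    if not var_ok.all():
        analysis_mask[mask] = var_ok
        Y = Y[:, var_ok]

    group = np.concatenate([np.ones(len(maps_a)), np.zeros(len(maps_b))])
    X, names = build_design(group, covariates)
    t, resid, df = _ols_t(Y, X, contrast_col=1)

    ref = all_maps[0]
    t_vals = np.zeros(mask.shape)
    t_vals[analysis_mask] = t
    t_map = VoxelMap(
        values=t_vals, mask=analysis_mask, kind="tstat",
        voxel_size_mm=ref.voxel_size_mm, affine=ref.affine,
        meta={"df": df, "design_columns": names,
              "n_zero_variance_voxels": int((~var_ok).sum())},
    )
    residual_maps = []
    for i in range(resid.shape[0]):
        rv = np.zeros(mask.shape)
        rv[analysis_mask] = resid[i]
        residual_maps.append(
            VoxelMap(values=rv, mask=analysis_mask, kind="residual",
                     voxel_size_mm=ref.voxel_size_mm, affine=ref.affine)
        )
    return TStatResult(t_map=t_map, df=df, residual_maps=residual_maps, contrast=contrast)


def paired_t(
    maps_pre: Sequence[VoxelMap],
    maps_post: Sequence[VoxelMap],
    covariates: Optional[pd.DataFrame] = None,
    contrast: str = "post>pre",
) -> TStatResult:
    """One-sample t on (post - pre) differences; positive t means post > pre.

    Covariates default to none (demographics are constant within subject over
    the follow-up interval); pass a table to include them anyway.
    """
    if len(maps_pre) != len(maps_post):
        raise ValueError("pre/post lists have different lengths")
    if len(maps_pre) < 2:
        raise ValueError("need at least 2 pairs")
    mask = _common_mask(list(maps_pre) + list(maps_post))
    D = _stack_maps(maps_post, mask) - _stack_maps(maps_pre, mask)

    n = D.shape[0]
    cols = [np.ones(n)]
    names = ["mean"]
    if covariates is not None:
        if len(covariates) != n:
            raise ValueError("covariate rows do not align with pairs")
        for name in covariates.columns:
            c = covariates[name].to_numpy(dtype=np.float64)
            cols.append(c - c.mean())
            names.append(name)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    p = X.shape[1]
    df = n - p
    if df <= 0:
        raise ValueError("non-positive degrees of freedom")

    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ D)
    resid = D - X @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    se = np.sqrt(np.maximum(rss / df * xtx_inv[0, 0], 0.0))
    mean = beta[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(se > 0, mean / se, np.sign(mean) * CENSORED_T)
    # zero-variance shifts blow up t (exactly or to float noise); censor them
    t = np.clip(t, -CENSORED_T, CENSORED_T)
    n_censored = int((np.abs(t) >= CENSORED_T).sum())

    ref = maps_pre[0]
    t_vals = np.zeros(mask.shape)
    t_vals[mask] = t
    t_map = VoxelMap(
        values=t_vals, mask=mask, kind="tstat",
        voxel_size_mm=ref.voxel_size_mm, affine=ref.affine,
        meta={"df": df, "design_columns": names, "n_censored_voxels": n_censored},
    )
    residual_maps = []
    for i in range(n):
        rv = np.zeros(mask.shape)
        rv[mask] = resid[i]
        residual_maps.append(
            VoxelMap(values=rv, mask=mask, kind="residual",
                     voxel_size_mm=ref.voxel_size_mm, affine=ref.affine)
        )
    return TStatResult(t_map=t_map, df=df, residual_maps=residual_maps, contrast=contrast)


def t_to_z(t_result: TStatResult) -> VoxelMap:
    """Gaussianize a t map: z = Phi^-1(F_t(t; df)), sign-symmetric.

    Computed through the upper tail for numerical stability at large |t|.
    """
    df = t_result.df
    if df < 1:
        raise ValueError("df must be >= 1")
    t = t_result.t_map.in_mask()
    p_upper = special.stdtr(df, -np.abs(t))  # P(T > |t|)
    p_upper = np.clip(p_upper, 1e-300, 1.0)
    z_abs = -special.ndtri(p_upper)
    z = np.sign(t) * z_abs
    vals = np.zeros_like(t_result.t_map.values)
    vals[t_result.t_map.mask] = z
    out = t_result.t_map.with_values(vals, kind="zstat")
    out.meta = dict(t_result.t_map.meta, df=df)
    return out
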