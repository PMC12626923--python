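"""Synthetic BOLD cohorts with known ground truth.

Generates 4D series with planted band-limited oscillations in chosen regions,
temporally AR(1) and spatially smoothed Gaussian noise, plus a subjects table
whose clinical scores follow configurable group means/SDs, with optional
planted correlations between regional amplitude changes and clinical changes.

Noise is built white -> AR(1)-filtered in time -> Gaussian-smoothed in space,
so the true spatial smoothness of the field is known exactly and random-field
inference can be validated against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, signal as sp_signal

from .core import BoldSeries
from .preprocess import FWHM_TO_SIGMA

AR_BURN_IN = 50

#: Cohort/clinical defaults: group means and SDs for the generated scores.
#: Spread for median(IQR)-style quantities uses IQR/1.35 as the SD surrogate.
DEFAULT_CLINICAL = {
    "hc": {
        "age": (45.8, 8.5), "education_years": (9.5, 2.0), "p_male": 25 / 32,
        "nct_a_s": (43.7, 8.3), "dst_score": (47.7, 7.9),
    },
    "pre": {
        "age": (46.9, 9.1), "education_years": (9.8, 2.0), "p_male": 21 / 27,
        "nct_a_s": (76.6, 10.6), "dst_score": (33.4, 8.3),
        "prothrombin_time_s": (14.8, 4.7), "albumin_mg_dl": (33.3, 7.2),
        "total_bilirubin_mg_dl": (55.0, 40.0), "ammonia_umol_l": (145.6, 32.3),
    },
    "post": {
        "nct_a_s": (51.1, 5.0), "dst_score": (43.3, 5.5),
        "prothrombin_time_s": (12.4, 2.1), "albumin_mg_dl": (38.9, 4.2),
        "total_bilirubin_mg_dl": (16.0, 8.9), "ammonia_umol_l": (46.2, 10.4),
    },
    # Child-Pugh class frequencies A/B/C among patients
    "child_pugh_probs": (2 / 27, 5 / 27, 20 / 27),
}

LAB_COLUMNS = (
    "prothrombin_time_s", "albumin_mg_dl", "total_bilirubin_mg_dl", "ammonia_umol_l",
)


def roi_mask_from_spec(spec: dict, grid_dims: Sequence[int]) -> np.ndarray:
    """Boolean ROI mask from a spec dict.

    Supported forms: {"center": [x,y,z], "radius": r} (ball, voxel units) and
    {"box": [[x0,x1],[y0,y1],[z0,z1]]} (half-open index ranges).
    """
    dims = tuple(int(d) for d in grid_dims)
    mask = np.zeros(dims, dtype=bool)
    if "box" in spec:
        (x0, x1), (y0, y1), (z0, z1) = spec["box"]
        mask[x0:x1, y0:y1, z0:z1] = True
    elif "center" in spec and "radius" in spec:
        cx, cy, cz = spec["center"]
        r = float(spec["radius"])
        gx, gy, gz = np.ogrid[: dims[0], : dims[1], : dims[2]]
        mask[(gx - cx) ** 2 + (gy - cy) ** 2 + (gz - cz) ** 2 <= r * r] = True
    else:
        raise ValueError(f"unrecognized roi_mask_spec: {spec!r}")
    if not mask.any():
        raise ValueError(f"roi_mask_spec selects no voxels: {spec!r}")
    return mask


def ellipsoid_mask(grid_dims: Sequence[int], fill: float = 0.9) -> np.ndarray:
    """Brain-like ellipsoidal mask inscribed in the grid."""
    dims = np.asarray(grid_dims, dtype=float)
    semi = dims / 2.0
    c = (dims - 1) / 2.0
    gx, gy, gz = np.ogrid[: grid_dims[0], : grid_dims[1], : grid_dims[2]]
    r = (
        ((gx - c[0]) / (fill * semi[0])) ** 2
        + ((gy - c[1]) / (fill * semi[1])) ** 2
        + ((gz - c[2]) / (fill * semi[2])) ** 2
    )
    return r <= 1.0


@dataclass
class PlantedSignal:
    """A band-limited oscillation planted in one region."""

    roi_mask_spec: dict
    frequency_hz: float
    amplitude: float
    amplitude_post: Optional[float] = None  # patients' post-session amplitude
    amplitude_post_sd: float = 0.0  # per-patient jitter of the post amplitude
    group_scope: str = "all"  # all | hc | patients

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("invariant violated: amplitude must be >= 0")
        if self.amplitude_post is not None and self.amplitude_post < 0:
            raise ValueError("invariant violated: amplitude_post must be >= 0")
        if self.amplitude_post_sd < 0:
            raise ValueError("invariant violated: amplitude_post_sd must be >= 0")
        if self.group_scope not in ("all", "hc", "patients"):
            raise ValueError(f"invalid group_scope {self.group_scope!r}")


@dataclass
class DeltaLink:
    """Planted correlation between a region's amplitude change and a clinical delta."""

    signal_index: int
    clinical_index: str
    target_r: float

    def __post_init__(self) -> None:
        if not (-1.0 <= self.target_r <= 1.0):
            raise ValueError("invariant violated: target_r must lie in [-1, 1]")


@dataclass
class SimulationConfig:
    grid_dims: tuple[int, int, int] = (24, 24, 16)
    voxel_size_mm: float = 3.0
    tr_s: float = 2.17
    n_volumes: int = 186
    ar1_coef: float = 0.3
    sigma: float = 1.0
    baseline: float = 100.0
    planted_signals: list[PlantedSignal] = field(default_factory=list)
    smooth_fwhm_mm: float = 6.0
    n_hc: int = 32
    n_patients: int = 27
    clinical: dict = field(default_factory=lambda: DEFAULT_CLINICAL)
    delta_links: list[DeltaLink] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        nyquist = 1.0 / (2.0 * self.tr_s)
        for i, sig in enumerate(self.planted_signals):
            if not (0.0 < sig.frequency_hz < nyquist):
                raise ValueError(
                    f"invariant violated: planted frequency {sig.frequency_hz} Hz of "
                    f"signal {i} must lie strictly inside (0, {nyquist:.4f}) Hz"
                )
        if self.n_volumes < 2:
            raise ValueError("invariant violated: n_volumes must be >= 2")
        if not (0.0 <= self.ar1_coef < 1.0):
            raise ValueError("invariant violated: ar1_coef must lie in [0, 1)")
        if self.sigma < 0:
            raise ValueError("invariant violated: sigma must be >= 0")
        if self.smooth_fwhm_mm < 0:
            raise ValueError("invariant violated: smooth_fwhm_mm must be >= 0")
        if self.n_hc < 0 or self.n_patients < 0:
            raise ValueError("invariant violated: cohort sizes must be >= 0")
        for link in self.delta_links:
            if not (0 <= link.signal_index < len(self.planted_signals)):
                raise ValueError(
                    f"invariant violated: delta link references signal "
                    f"{link.signal_index} but only {len(self.planted_signals)} exist"
                )


def ar1_noise(
    rng: np.random.Generator,
    shape_spatial: tuple[int, ...],
    n_t: int,
    ar1_coef: float,
    sigma: float,
) -> np.ndarray:
    """Stationary AR(1) noise along the last axis with marginal SD `sigma`."""
    if sigma == 0:
        return np.zeros(shape_spatial + (n_t,))
    innov_sd = sigma * np.sqrt(1.0 - ar1_coef**2)
    w = rng.standard_normal(shape_spatial + (n_t + AR_BURN_IN,)) * innov_sd
    out = sp_signal.lfilter([1.0], [1.0, -ar1_coef], w, axis=-1)
    return out[..., AR_BURN_IN:]


def _smooth_noise(noise: np.ndarray, fwhm_mm: float, voxel_size_mm: float) -> np.ndarray:
    if fwhm_mm == 0:
        return noise
    sigma_vox = fwhm_mm / (voxel_size_mm * FWHM_TO_SIGMA)
    # smoothing shrinks the marginal variance; rescale to preserve sigma
    ref = np.std(
        ndimage.gaussian_filter(
            np.random.default_rng(0).standard_normal(noise.shape[:3]),
            sigma=sigma_vox, mode="wrap",
        )
    )
    out = np.empty_like(noise)
    for t in range(noise.shape[-1]):
        out[..., t] = ndimage.gaussian_filter(noise[..., t], sigma=sigma_vox, mode="nearest")
    return out / max(ref, 1e-12)


def plant_delta_correlation(
    roi_deltas: Sequence[float],
    target_r: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Standardized deltas whose sample correlation with `roi_deltas` is target_r.

    Construction: standardized signal + noise orthogonalized against it (and
    the constant), mixed as r*z + sqrt(1-r^2)*e.  Scale/locate the result to
    the desired clinical units downstream.
    """
    x = np.asarray(roi_deltas, dtype=np.float64)
    if x.size < 3:
        raise ValueError("need at least 3 values")
    if not (-1.0 <= target_r <= 1.0):
        raise ValueError("|target_r| must be <= 1")
    xc = x - x.mean()
    sx = xc.std()
    if sx == 0:
        raise ValueError("roi_deltas have zero variance")
    z = xc / sx
    e = rng.standard_normal(x.size)
    e = e - e.mean()
    e = e - (e @ z) / (z @ z) * z
    se = e.std()
    if se == 0:  # pathological draw; retry deterministically
        e = np.arange(x.size, dtype=np.float64)
        e = e - e.mean()
        e = e - (e @ z) / (z @ z) * z
        se = e.std()
        if se == 0:
            raise ValueError("cannot construct orthogonal noise for these deltas")
    e = e / se
    y = target_r * z + np.sqrt(1.0 - target_r**2) * e
    return y


def _truncate_positive(x: np.ndarray, lo: float = 0.5) -> np.ndarray:
    return np.maximum(x, lo)


def _draw_clinical(
    rng: np.random.Generator, params: dict, n: int, cols: Sequence[str]
) -> dict[str, np.ndarray]:
    out = {}
    for col in cols:
        mean, sd = params[col]
        out[col] = _truncate_positive(rng.normal(mean, sd, size=n))
    return out


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[BoldSeries], pd.DataFrame, dict]:
    """Generate one BoldSeries per subject-session plus subjects table.

    HC subjects get a single session; patients get `pre` and `post`.  Returns
    (series_list, subjects_table, ground_truth) where ground_truth records the
    planted ROI masks, per-patient amplitude deltas and delta links for
    recovery testing.
    """
    rng = np.random.default_rng(config.seed)
    dims = config.grid_dims
    mask = ellipsoid_mask(dims)
    t_sec = np.arange(config.n_volumes) * config.tr_s
    clin = config.clinical

    roi_masks = [roi_mask_from_spec(s.roi_mask_spec, dims) for s in config.planted_signals]

    # per-patient post amplitudes (ground truth for delta-correlation planting)
    post_amps: list[np.ndarray] = []
    for sig in config.planted_signals:
        if sig.amplitude_post is None:
            post_amps.append(np.full(config.n_patients, sig.amplitude))
        else:
            a = rng.normal(sig.amplitude_post, sig.amplitude_post_sd, config.n_patients)
            post_amps.append(np.maximum(a, 0.0))
    amp_deltas = [pa - sig.amplitude for pa, sig in zip(post_amps, config.planted_signals)]

    def build_series(subject_id: str, session: str, group: str,
                     patient_idx: Optional[int]) -> BoldSeries:
        vals = np.full(dims + (config.n_volumes,), config.baseline, dtype=np.float64)
        for k, sig in enumerate(config.planted_signals):
            if sig.group_scope == "hc" and group != "HC":
                continue
            if sig.group_scope == "patients" and group == "HC":
                continue
            if group == "HC" or session == "pre" or sig.amplitude_post is None:
                amp = sig.amplitude
            else:
                amp = float(post_amps[k][patient_idx])
            if amp == 0:
                continue
            phase = rng.uniform(0, 2 * np.pi)
            vals[roi_masks[k]] += amp * np.sin(
                2 * np.pi * sig.frequency_hz * t_sec + phase
            )
        if config.sigma > 0:
            noise = ar1_noise(rng, dims, config.n_volumes, config.ar1_coef, config.sigma)
            vals += _smooth_noise(noise, config.smooth_fwhm_mm, config.voxel_size_mm)
        return BoldSeries(
            values=vals, voxel_size_mm=config.voxel_size_mm, tr_s=config.tr_s,
            mask=mask, subject_id=subject_id, session=session,
        )

    series: list[BoldSeries] = []
    rows: list[dict] = []

    hc = _draw_clinical(rng, clin["hc"], config.n_hc, ["age", "education_years", "nct_a_s", "dst_score"])
    hc_sex = (rng.uniform(size=config.n_hc) < clin["hc"]["p_male"]).astype(int)
    for i in range(config.n_hc):
        sid = f"hc{i:03d}"
        series.append(build_series(sid, "single", "HC", None))
        rows.append({
            "id": sid, "group": "HC", "session": "single",
            "age": hc["age"][i], "sex": int(hc_sex[i]),
            "education_years": hc["education_years"][i],
            "nct_a_s": hc["nct_a_s"][i], "dst_score": hc["dst_score"][i],
            **{c: np.nan for c in LAB_COLUMNS}, "child_pugh_points": np.nan,
        })

    n_p = config.n_patients
    pre = _draw_clinical(
        rng, clin["pre"], n_p,
        ["age", "education_years", "nct_a_s", "dst_score", *LAB_COLUMNS],
    )
    p_sex = (rng.uniform(size=n_p) < clin["pre"]["p_male"]).astype(int)
    cls = rng.choice(3, size=n_p, p=clin["child_pugh_probs"])
    cp_lo, cp_hi = np.array([5, 7, 10]), np.array([6, 9, 15])
    cp_points = rng.integers(cp_lo[cls], cp_hi[cls] + 1)

    # clinical deltas: planted links get exact-sample-correlation construction,
    # everything else is drawn independently of the imaging ground truth
    clinical_cols = ["nct_a_s", "dst_score", *LAB_COLUMNS]
    deltas: dict[str, np.ndarray] = {}
    linked = {link.clinical_index: link for link in config.delta_links}
    for col in clinical_cols:
        mu_post, sd_post = clin["post"][col]
        mu_pre, sd_pre = clin["pre"][col]
        d_mean = mu_post - mu_pre
        d_sd = float(np.sqrt(sd_post**2 + sd_pre**2))
        if col in linked and n_p >= 3:
            link = linked[col]
            x = amp_deltas[link.signal_index]
            y = plant_delta_correlation(x, link.target_r, rng)
            deltas[col] = d_mean + d_sd * y
        else:
            deltas[col] = rng.normal(d_mean, d_sd, size=n_p)

    for i in range(n_p):
        sid = f"pat{i:03d}"
        base = {
            "id": sid, "group": "MHE", "age": pre["age"][i], "sex": int(p_sex[i]),
            "education_years": pre["education_years"][i],
            "child_pugh_points": int(cp_points[i]),
        }
        pre_vals = {c: pre[c][i] for c in clinical_cols}
        post_vals = {
            c: max(pre_vals[c] + deltas[c][i], 0.5) for c in clinical_cols
        }
        series.append(build_series(sid, "pre", "MHE", i))
        rows.append({**base, "session": "pre", **pre_vals})
        series.append(build_series(sid, "post", "MHE", i))
        rows.append({**base, "session": "post", **post_vals})

    subjects = pd.DataFrame(rows)
    ground_truth = {
        "mask_n_voxels": int(mask.sum()),
        "planted_signals": [
            {
                "roi_mask_spec": sig.roi_mask_spec,
                "roi_voxel_indices": np.argwhere(roi_masks[k]).tolist(),
                "frequency_hz": sig.frequency_hz,
                "amplitude": sig.amplitude,
                "amplitude_post": sig.amplitude_post,
                "group_scope": sig.group_scope,
                "patient_amplitude_deltas": amp_deltas[k].tolist(),
            }
            for k, sig in enumerate(config.planted_signals)
        ],
        "delta_links": [
            {"signal_index": l.signal_index, "clinical_index": l.clinical_index,
             "target_r": l.target_r}
            for l in config.delta_links
        ],
        "seed": config.seed,
    }
    return series, subjects, ground_truth
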