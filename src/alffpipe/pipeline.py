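"""End-to-end pipeline: simulate -> preprocess -> ALFF/dALFF -> contrasts ->
GRF cluster tables -> delta correlations.

The driver mirrors the study design: two-sample contrasts of patients (pre and
post) against controls with age/sex/education covariates, a paired post-vs-pre
contrast, and Pearson correlations of post-pre regional changes against
clinical changes, Bonferroni-corrected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .alff import alff_map, band_bin_indices, normalize_by_global_mean
from .core import BoldSeries, SpectrumBand, VoxelMap, WindowScheme
from .dalff import dalff_map, window_starts, zscore_map
from .deltas import run_delta_analysis
from .glm import paired_t, two_sample_t
from .grf import estimate_smoothness, make_cluster_table
from .io import cluster_records_to_frame, config_hash, write_provenance, write_tsv
from .preprocess import preprocess_series
from .synthetic import DeltaLink, PlantedSignal, SimulationConfig, simulate_cohort

logger = logging.getLogger(__name__)

COVARIATE_COLUMNS = ("age", "sex", "education_years")

_SECTION_KEYS = {
    "simulation": {
        "grid_dims", "voxel_size_mm", "tr_s", "n_volumes", "ar1_coef", "sigma",
        "baseline", "planted_signals", "smooth_fwhm_mm", "n_hc", "n_patients",
        "clinical", "delta_links", "seed",
    },
    "preprocess": {"n_discard", "fwhm_mm", "band", "order", "bandpass_method"},
    "window": {"length_tr", "step_tr"},
    "stats": {"voxel_p", "cluster_p", "connectivity", "two_sided"},
    "delta": {"m_tests", "alpha"},
}


@dataclass
class PipelineConfig:
    """Validated pipeline parameters; unknown config keys are rejected."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    n_discard: int = 10
    fwhm_mm: float = 6.0
    band: SpectrumBand = field(default_factory=SpectrumBand)
    order: tuple[str, ...] = ("smooth", "bandpass", "detrend")
    bandpass_method: str = "ideal"
    window: WindowScheme = field(default_factory=WindowScheme)
    voxel_p: float = 0.05
    cluster_p: float = 0.05
    connectivity: int = 26
    two_sided: bool = True
    m_tests: Optional[int] = None
    alpha: float = 0.05
    schema_version: str = "1"

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        raw.pop("schema_version", None)
        unknown_sections = set(raw) - set(_SECTION_KEYS)
        if unknown_sections:
            raise ValueError(f"unknown config sections: {sorted(unknown_sections)}")
        kwargs: dict = {}
        for section, allowed in _SECTION_KEYS.items():
            sub = dict(raw.get(section, {}))
            unknown = set(sub) - allowed
            if unknown:
                raise ValueError(f"unknown keys in [{section}]: {sorted(unknown)}")
            if section == "simulation":
                if "planted_signals" in sub:
                    sub["planted_signals"] = [
                        PlantedSignal(**s) for s in sub["planted_signals"]
                    ]
                if "delta_links" in sub:
                    sub["delta_links"] = [DeltaLink(**d) for d in sub["delta_links"]]
                if "grid_dims" in sub:
                    sub["grid_dims"] = tuple(sub["grid_dims"])
                kwargs["simulation"] = SimulationConfig(**sub)
            elif section == "preprocess":
                if "band" in sub:
                    sub["band"] = SpectrumBand(*sub["band"])
                if "order" in sub:
                    sub["order"] = tuple(sub["order"])
                kwargs.update(sub)
            elif section == "window":
                if sub:
                    kwargs["window"] = WindowScheme(**sub)
            else:
                kwargs.update(sub)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        sim = self.simulation
        return {
            "schema_version": self.schema_version,
            "simulation": {
                "grid_dims": list(sim.grid_dims), "voxel_size_mm": sim.voxel_size_mm,
                "tr_s": sim.tr_s, "n_volumes": sim.n_volumes, "ar1_coef": sim.ar1_coef,
                "sigma": sim.sigma, "baseline": sim.baseline,
                "smooth_fwhm_mm": sim.smooth_fwhm_mm, "n_hc": sim.n_hc,
                "n_patients": sim.n_patients, "seed": sim.seed,
                "planted_signals": [vars(s) for s in sim.planted_signals],
                "delta_links": [vars(d) for d in sim.delta_links],
            },
            "preprocess": {
                "n_discard": self.n_discard, "fwhm_mm": self.fwhm_mm,
                "band": [self.band.f_low_hz, self.band.f_high_hz],
                "order": list(self.order), "bandpass_method": self.bandpass_method,
            },
            "window": {"length_tr": self.window.length_tr, "step_tr": self.window.step_tr},
            "stats": {"voxel_p": self.voxel_p, "cluster_p": self.cluster_p,
                      "connectivity": self.connectivity, "two_sided": self.two_sided},
            "delta": {"m_tests": self.m_tests, "alpha": self.alpha},
        }


@dataclass
class PipelineResult:
    cluster_tables: dict[str, pd.DataFrame]  # pre_vs_hc, post_vs_hc, post_vs_pre
    correlation_table: pd.DataFrame
    subjects: pd.DataFrame
    ground_truth: dict
    cluster_records: dict[str, dict[str, list]]  # contrast -> metric -> records
    provenance: dict


def _metric_maps(series: BoldSeries, cfg: PipelineConfig) -> tuple[VoxelMap, VoxelMap]:
    """(mALFF, z-scored dALFF) maps for one preprocessed series."""
    malff = normalize_by_global_mean(alff_map(series, cfg.band))
    dz = zscore_map(dalff_map(series, cfg.band, cfg.window))
    return malff, dz


def run_pipeline(cfg: PipelineConfig, out_dir: Optional[Path] = None) -> PipelineResult:
    """Execute every stage on a simulated cohort; optionally write the bundle.

    Emits one cluster table per contrast (rows from both metrics) and one
    correlation table over the paired-contrast ROIs.
    """
    sim = cfg.simulation
    series_list, subjects, ground_truth = simulate_cohort(sim)

    n_after = sim.n_volumes - cfg.n_discard
    n_windows = len(window_starts(n_after, cfg.window))
    n_bins = band_bin_indices(n_after, sim.tr_s, cfg.band).size
    logger.info(
        "pipeline: %d series; %d timepoints after discard; %d in-band bins; "
        "%d sliding windows", len(series_list), n_after, n_bins, n_windows,
    )

    maps: dict[tuple[str, str], dict[str, VoxelMap]] = {}
    for s in series_list:
        pp = preprocess_series(
            s, n_discard=cfg.n_discard, fwhm_mm=cfg.fwhm_mm, band=cfg.band,
            order=cfg.order, bandpass_method=cfg.bandpass_method,
        )
        malff, dz = _metric_maps(pp, cfg)
        maps[(s.subject_id, s.session)] = {"alff": malff, "dalff": dz}

    hc_ids = subjects.loc[subjects.group == "HC", "id"].unique().tolist()
    pat_ids = subjects.loc[subjects.group == "MHE", "id"].unique().tolist()
    sub_hc = subjects[subjects.group == "HC"].set_index("id").loc[hc_ids]
    sub_pre = subjects[(subjects.group == "MHE") & (subjects.session == "pre")].set_index("id").loc[pat_ids]
    sub_post = subjects[(subjects.group == "MHE") & (subjects.session == "post")].set_index("id").loc[pat_ids]

    contrasts = {
        "pre_vs_hc": ("two_sample", "pre", sub_pre),
        "post_vs_hc": ("two_sample", "post", sub_post),
        "post_vs_pre": ("paired", None, None),
    }

    cluster_tables: dict[str, pd.DataFrame] = {}
    cluster_records: dict[str, dict[str, list]] = {}
    paired_rois: dict[str, np.ndarray] = {}

    for cname, (kind, psession, psub) in contrasts.items():
        frames = []
        cluster_records[cname] = {}
        for metric in ("alff", "dalff"):
            if kind == "two_sample":
                maps_a = [maps[(pid, psession)][metric] for pid in pat_ids]
                maps_b = [maps[(hid, "single")][metric] for hid in hc_ids]
                cov = pd.concat(
                    [psub[list(COVARIATE_COLUMNS)], sub_hc[list(COVARIATE_COLUMNS)]]
                ).reset_index(drop=True)
                res = two_sample_t(maps_a, maps_b, covariates=cov, contrast=cname)
            else:
                maps_pre = [maps[(pid, "pre")][metric] for pid in pat_ids]
                maps_post = [maps[(pid, "post")][metric] for pid in pat_ids]
                res = paired_t(maps_pre, maps_post, contrast=cname)
            smooth = estimate_smoothness(res.residual_maps, df=res.df)
            logger.info(
                "%s/%s: df=%d, estimated FWHM=%s mm", cname, metric, res.df,
                np.round(smooth.fwhm_mm, 2),
            )
            records = make_cluster_table(
                res, smooth, voxel_p=cfg.voxel_p, cluster_p=cfg.cluster_p,
                connectivity=cfg.connectivity, two_sided=cfg.two_sided,
            )
            cluster_records[cname][metric] = records
            frame = cluster_records_to_frame(records)
            frame.insert(0, "metric", metric)
            frames.append(frame)
            if cname == "post_vs_pre":
                for r in records:
                    roi = np.zeros(res.t_map.mask.shape, dtype=bool)
                    roi[tuple(r.voxel_indices.T)] = True
                    paired_rois[f"{metric}_c{r.cluster_id}_{r.sign}"] = roi
        non_empty = [f for f in frames if len(f)]
        cluster_tables[cname] = (
            pd.concat(non_empty, ignore_index=True) if non_empty else frames[0]
        )

    if paired_rois:
        # delta correlations use the metric each ROI came from
        corr_frames = []
        for metric in ("alff", "dalff"):
            rois = {k: v for k, v in paired_rois.items() if k.startswith(metric + "_")}
            if not rois:
                continue
            tab = run_delta_analysis(
                [maps[(pid, "pre")][metric] for pid in pat_ids],
                [maps[(pid, "post")][metric] for pid in pat_ids],
                rois,
                sub_pre.reset_index(),
                sub_post.reset_index(),
                m_tests=cfg.m_tests if cfg.m_tests is not None else len(paired_rois),
                alpha=cfg.alpha,
            )
            tab.insert(0, "metric", metric)
            corr_frames.append(tab)
        correlation_table = pd.concat(corr_frames, ignore_index=True)
    else:
        correlation_table = pd.DataFrame(
            columns=["metric", "roi", "index", "r", "p", "p_adjusted", "significant", "note"]
        )

    cfg_dict = cfg.to_dict()
    provenance = {
        "package_version": __version__,
        "config": cfg_dict,
        "config_hash": config_hash(cfg_dict),
        "seed": sim.seed,
        "n_series": len(series_list),
        "n_timepoints_after_discard": n_after,
        "n_band_bins": n_bins,
        "n_windows": n_windows,
    }

    result = PipelineResult(
        cluster_tables=cluster_tables,
        correlation_table=correlation_table,
        subjects=subjects,
        ground_truth=ground_truth,
        cluster_records=cluster_records,
        provenance=provenance,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for cname, frame in cluster_tables.items():
            write_tsv(frame, out_dir / f"clusters_{cname}.tsv")
        write_tsv(correlation_table, out_dir / "delta_correlations.tsv")
        write_tsv(subjects, out_dir / "subjects.tsv")
        write_provenance(out_dir / "provenance.json", provenance)
        gt = dict(ground_truth)
        write_provenance(out_dir / "ground_truth.json", gt)
    return result
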