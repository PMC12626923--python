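"""NIfTI and table I/O plus provenance sidecars."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence, Union

import nibabel as nib
import numpy as np
import pandas as pd

from .core import BoldSeries, ClusterRecord, VoxelMap

PathLike = Union[str, Path]


def _voxel_sizes_from_affine(affine: np.ndarray) -> tuple[float, float, float]:
    return tuple(float(np.linalg.norm(affine[:3, i])) for i in range(3))


def write_nifti(obj: Union[BoldSeries, VoxelMap], path: PathLike) -> None:
    """Write a BoldSeries (4D) or VoxelMap (3D) as NIfTI-1."""
    img = nib.Nifti1Image(np.asarray(obj.values, dtype=np.float64), obj.affine)
    if isinstance(obj, BoldSeries):
        zooms = (*obj.voxel_size_mm, obj.tr_s)
        img.header.set_zooms(zooms)
        img.header.set_xyzt_units("mm", "sec")
    else:
        img.header.set_zooms(obj.voxel_size_mm)
        img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def write_mask(mask: np.ndarray, affine: np.ndarray, path: PathLike) -> None:
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(path))


def read_mask(path: PathLike) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"mask must be 3D, got {data.ndim}D: {path}")
    return data > 0, img.affine


def read_bold(
    path: PathLike,
    mask: Optional[np.ndarray] = None,
    subject_id: str = "",
    session: str = "single",
) -> BoldSeries:
    """Load a 4D NIfTI as a BoldSeries; TR is taken from the header."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise ValueError(f"expected a 4D BOLD image, got {data.ndim}D: {path}")
    zooms = img.header.get_zooms()
    tr_s = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    return BoldSeries(
        values=data,
        voxel_size_mm=_voxel_sizes_from_affine(img.affine),
        tr_s=tr_s,
        mask=mask,
        subject_id=subject_id,
        session=session,
        affine=img.affine,
    )


def read_map(path: PathLike, mask: Optional[np.ndarray] = None, kind: str = "other") -> VoxelMap:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D map, got {data.ndim}D: {path}")
    if mask is None:
        mask = np.isfinite(data)
    return VoxelMap(
        values=np.nan_to_num(data), mask=mask, kind=kind,
        voxel_size_mm=_voxel_sizes_from_affine(img.affine), affine=img.affine,
    )


def cluster_records_to_frame(records: Sequence[ClusterRecord]) -> pd.DataFrame:
    """Cluster table with the report columns (one row per cluster)."""
    return pd.DataFrame(
        [
            {
                "region_label": r.atlas_label,
                "mni_x": r.peak_coord_mm[0],
                "mni_y": r.peak_coord_mm[1],
                "mni_z": r.peak_coord_mm[2],
                "n_voxels": r.size_voxels,
                "peak_t": r.peak_stat,
                "p_corrected": r.cluster_p_corrected,
                "sign": r.sign,
            }
            for r in records
        ],
        columns=["region_label", "mni_x", "mni_y", "mni_z", "n_voxels",
                 "peak_t", "p_corrected", "sign"],
    )


def write_tsv(frame: pd.DataFrame, path: PathLike) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_subjects_table(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_atlas_labels(path: PathLike) -> dict[int, str]:
    """TSV with columns `code` and `name` mapping atlas integers to labels."""
    df = pd.read_csv(path, sep="\t")
    return {int(row["code"]): str(row["name"]) for _, row in df.iterrows()}


def config_hash(config_dict: dict) -> str:
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_provenance(path: PathLike, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
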