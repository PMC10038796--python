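"""NIfTI / TSV readers and writers tying volumes to flat voxel vectors.

All statistics operate on flat ``(subjects, voxels, timepoints)`` arrays;
this module maps between those vectors and 3-D volumes through a mask,
using one documented ordering: ascending linear (C-order ravel) index of
the mask grid.  Maps are written unthresholded together with companion p
and mask volumes so thresholds can be revised without recomputation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .isc import BoldGroup, IscMap, GroupComparison
from .mediation import FeatureModel, MediationResult
from .simulate import GroundTruth


@dataclass
class VolumeGeometry:
    """Mask grid + affine defining the flat voxel ordering of all maps."""

    mask: np.ndarray                   # 3-D boolean
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3-D")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def flatten(self, volume: np.ndarray) -> np.ndarray:
        """Voxel vector(s) in ascending linear mask order; time stays last."""
        return np.asarray(volume)[self.mask]

    def unflatten(self, values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        """3-D volume from a flat voxel vector."""
        values = np.asarray(values)
        if values.shape[0] != self.n_voxels:
            raise ValueError(f"{values.shape[0]} values for {self.n_voxels} mask voxels")
        out = np.full(self.mask.shape + values.shape[1:], fill, dtype=float)
        out[self.mask] = values
        return out

    def write_map(self, values: np.ndarray, path: str | Path) -> None:
        vol = self.unflatten(values)
        nib.save(nib.Nifti1Image(vol.astype(np.float32), self.affine), str(path))

    def write_mask(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(self.mask.astype(np.uint8), self.affine), str(path))


def geometry_for_grid(grid_shape: tuple[int, int, int], n_voxels: int,
                      voxel_size_mm: float = 3.0) -> VolumeGeometry:
    """Geometry of a synthetic dataset: the first n_voxels of a small grid."""
    mask = np.zeros(grid_shape, dtype=bool)
    mask.ravel()[:n_voxels] = True
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    return VolumeGeometry(mask=mask, affine=affine)


# ---------------------------------------------------------------------------
# BOLD groups
# ---------------------------------------------------------------------------

def read_bold_group(
    paths: Sequence[str | Path],
    mask_path: str | Path,
    tr_seconds: float,
    run_lengths: Sequence[int],
    condition: str = "AV",
    population: str = "TD",
) -> tuple[BoldGroup, VolumeGeometry]:
    """Load per-subject 4-D NIfTI volumes inside a 3-D mask.

    All subject images must share the mask's grid and affine; the offending
    file is named otherwise.
    """
    mask_img = nib.load(str(mask_path))
    mask = np.asarray(mask_img.dataobj) > 0
    geometry = VolumeGeometry(mask=mask, affine=mask_img.affine)
    data = []
    ids = []
    for p in paths:
        img = nib.load(str(p))
        if img.shape[:3] != mask.shape or not np.allclose(img.affine, mask_img.affine):
            raise ValueError(
                f"{p}: grid/affine mismatch with mask "
                f"(data {img.shape[:3]} vs mask {mask.shape})"
            )
        vol = np.asarray(img.dataobj, dtype=float)
        data.append(vol[mask])                      # (n_voxels, T)
        ids.append(Path(p).stem.replace(".nii", ""))
    group = BoldGroup(
        subject_ids=ids,
        data=np.stack(data),
        tr_seconds=tr_seconds,
        run_lengths=run_lengths,
        condition=condition,
        population=population,
    )
    return group, geometry


def write_bold_group(group: BoldGroup, geometry: VolumeGeometry,
                     out_dir: str | Path) -> list[Path]:
    """Write each subject as a 4-D NIfTI; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, sid in enumerate(group.subject_ids):
        vol = geometry.unflatten(group.data[i], fill=0.0)
        path = out_dir / f"sub-{sid}_bold.nii.gz"
        nib.save(nib.Nifti1Image(vol.astype(np.float32), geometry.affine), str(path))
        paths.append(path)
    return paths


def write_ground_truth(truth: GroundTruth, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame({
        "voxel": np.arange(truth.shared_voxel_mask.size),
        "shared": truth.shared_voxel_mask.astype(int),
        "timescale_s": truth.voxel_timescale_s,
    })
    df.to_csv(out_dir / "ground_truth.tsv", sep="\t", index=False)
    meta = {
        "grid_shape": list(truth.grid_shape),
        "n_model_features": int(truth.model_weights.shape[1]),
    }
    (out_dir / "ground_truth.json").write_text(json.dumps(meta, indent=2))
    if truth.model_weights.size:
        pd.DataFrame(truth.model_weights).to_csv(
            out_dir / "model_weights.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# feature models
# ---------------------------------------------------------------------------

def write_feature_model(model: FeatureModel, path: str | Path) -> None:
    """TSV with ``time_s`` as the first column, one column per feature."""
    cols = {"time_s": model.times_s}
    for j in range(model.n_features):
        cols[f"{model.name}_{j}"] = model.matrix[:, j]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_feature_model(path: str | Path, level: str,
                       name: str | None = None) -> FeatureModel:
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "time_s":
        raise ValueError(f"{path}: first column must be time_s")
    times = df["time_s"].to_numpy(dtype=float)
    rate = 1.0 / float(np.median(np.diff(times)))
    return FeatureModel(
        name=name or Path(path).stem,
        level=level,
        times_s=times,
        matrix=df.iloc[:, 1:].to_numpy(dtype=float),
        native_rate_hz=rate,
    )


# ---------------------------------------------------------------------------
# result tables and volumes
# ---------------------------------------------------------------------------

def write_isc_map(m: IscMap, geometry: VolumeGeometry, out_dir: str | Path,
                  prefix: str) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    geometry.write_map(m.mean_r, out_dir / f"{prefix}_mean_r.nii.gz")
    geometry.write_map(m.t_stat, out_dir / f"{prefix}_tstat.nii.gz")
    if m.p is not None:
        geometry.write_map(m.p, out_dir / f"{prefix}_p.nii.gz")
    if m.significant_mask is not None:
        geometry.write_map(m.significant_mask.astype(float),
                           out_dir / f"{prefix}_sigmask.nii.gz")
    summary = {
        "n_pairs": m.n_pairs,
        "mean_r_max": float(np.nanmax(m.mean_r)),
        "mean_r_mean": float(np.nanmean(m.mean_r)),
        "fwe_threshold": None if m.fwe_threshold is None else float(m.fwe_threshold),
        "n_significant": None if m.significant_mask is None
        else int(np.sum(m.significant_mask)),
    }
    pd.DataFrame([summary]).to_csv(out_dir / f"{prefix}_summary.tsv",
                                   sep="\t", index=False)


def write_mediation_result(res: MediationResult, geometry: VolumeGeometry,
                           out_dir: str | Path, prefix: str) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    geometry.write_map(res.isc_original, out_dir / f"{prefix}_isc_original.nii.gz")
    geometry.write_map(res.isc_mediated, out_dir / f"{prefix}_isc_mediated.nii.gz")
    geometry.write_map(res.drop, out_dir / f"{prefix}_drop.nii.gz")
    if res.p_drop is not None:
        geometry.write_map(res.p_drop, out_dir / f"{prefix}_p.nii.gz")
    peak = int(np.nanargmax(res.drop))
    table = {
        "drop_peak": float(res.drop[peak]),
        "peak_voxel": peak,
        "isc_original_at_peak": float(res.isc_original[peak]),
        "isc_mediated_at_peak": float(res.isc_mediated[peak]),
        "fwe_threshold": None if res.fwe_threshold is None else float(res.fwe_threshold),
    }
    pd.DataFrame([table]).to_csv(out_dir / f"{prefix}_peak.tsv", sep="\t", index=False)


def write_group_comparisons(rows: Sequence[GroupComparison],
                            path: str | Path) -> None:
    pd.DataFrame([vars(r) for r in rows]).to_csv(path, sep="\t", index=False)
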