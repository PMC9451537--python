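"""File interchange: NIfTI volumes/masks, β arrays, DSM tables."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .rsa import DSM
from .synth import BetaArray
from .univariate import ROIMask


def save_mask_nifti(mask3d: np.ndarray, path: str | Path, affine: np.ndarray | None = None) -> None:
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(mask3d, dtype=np.uint8), affine), str(path))


def load_mask_nifti(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata()) > 0


def save_map_nifti(vol: np.ndarray, path: str | Path, affine: np.ndarray | None = None) -> None:
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(vol, dtype=np.float32), affine), str(path))


def save_beta_array(betas: BetaArray, path: str | Path) -> None:
    """β array as .npz with a JSON sidecar naming subjects/conditions."""
    path = Path(path)
    np.savez_compressed(path, values=betas.values)
    sidecar = {
        "roi": betas.roi,
        "subject_ids": betas.subject_ids,
        "condition_labels": betas.condition_labels,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_beta_array(path: str | Path) -> BetaArray:
    path = Path(path)
    values = np.load(path)["values"]
    meta = json.loads(path.with_suffix(".json").read_text())
    return BetaArray(
        values=values,
        subject_ids=meta["subject_ids"],
        roi=meta["roi"],
        condition_labels=meta["condition_labels"],
    )


def dsm_to_frame(dsm: DSM) -> pd.DataFrame:
    return pd.DataFrame(dsm.values, index=dsm.labels, columns=dsm.labels)


def save_dsm_csv(dsm: DSM, path: str | Path) -> None:
    dsm_to_frame(dsm).to_csv(path)


def load_dsm_csv(path: str | Path) -> DSM:
    df = pd.read_csv(path, index_col=0)
    return DSM(df.to_numpy(dtype=float), list(df.columns))


def save_roi_json(roi: ROIMask, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "name": roi.name,
                "defining_contrast": roi.defining_contrast,
                "excluded_subject_id": roi.excluded_subject_id,
                "n_voxels_total": roi.n_voxels_total,
                "voxel_indices": [int(i) for i in roi.voxel_indices],
            },
            indent=1,
        )
    )


def load_roi_json(path: str | Path) -> ROIMask:
    d = json.loads(Path(path).read_text())
    return ROIMask(
        voxel_indices=np.asarray(d["voxel_indices"], dtype=int),
        name=d["name"],
        defining_contrast=d.get("defining_contrast", ""),
        excluded_subject_id=d.get("excluded_subject_id"),
        n_voxels_total=d.get("n_voxels_total"),
    )
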