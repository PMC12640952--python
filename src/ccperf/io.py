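"""NIfTI / CSV / JSON persistence.

Volumes are stored in conventional NIfTI (x, y, z[, t]) order with the voxel
spacing on the affine diagonal; in memory the package uses (t, z, y, x).
Studies get a JSON sidecar with frame times, spacing and (when present) the
JSON-serializable part of the truth payload.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import DynamicStudy
from .preprocess import HeartMasks


def _affine(spacing_zyx):
    dz, dy, dx = spacing_zyx
    return np.diag([dx, dy, dz, 1.0])


def save_masks(masks: HeartMasks, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.transpose(masks.labels, (2, 1, 0)).astype(np.int16),
                          _affine(masks.spacing_mm))
    nib.save(img, str(path))
    return path


def load_masks(path) -> HeartMasks:
    img = nib.load(str(path))
    dx, dy, dz = img.header.get_zooms()[:3]
    labels = np.transpose(np.asarray(img.dataobj), (2, 1, 0)).astype(np.int16)
    return HeartMasks(labels, (float(dz), float(dy), float(dx)))


def save_study(study: DynamicStudy, stem) -> Path:
    """Write <stem>.nii.gz (4-D), <stem>.json (sidecar) and, if truth masks
    are present, <stem>_masks.nii.gz."""
    stem = Path(stem)
    data = np.transpose(study.frames, (3, 2, 1, 0))  # (x, y, z, t)
    nib.save(nib.Nifti1Image(data.astype(np.float32),
                             _affine(study.spacing_mm)),
             str(stem.with_suffix(".nii.gz")))
    side = dict(frame_times_s=list(map(float, study.frame_times_s)),
                spacing_mm=list(map(float, study.spacing_mm)))
    if study.truth is not None:
        t = study.truth
        side["truth"] = dict(
            seed=t.get("seed"),
            bh_coeffs=list(t.get("bh_coeffs", ())),
            shifts_vox=np.asarray(t.get("shifts_vox", [])).tolist(),
            septal_angle_deg=t.get("septal_angle_deg"),
            rv_stub_angles_deg=t.get("rv_stub_angles_deg"),
            sectors=[s if isinstance(s, dict) else dataclasses.asdict(s)
                     for s in t.get("sectors", ())],
        )
        if "masks" in t:
            save_masks(t["masks"], stem.parent / (stem.name + "_masks.nii.gz"))
    stem.with_suffix(".json").write_text(json.dumps(side, indent=2))
    return stem.with_suffix(".nii.gz")


def load_study(stem) -> DynamicStudy:
    stem = Path(stem)
    img = nib.load(str(stem.with_suffix(".nii.gz")))
    side = json.loads(stem.with_suffix(".json").read_text())
    frames = np.transpose(np.asarray(img.dataobj, dtype=np.float64), (3, 2, 1, 0))
    truth = None
    mask_path = stem.parent / (stem.name + "_masks.nii.gz")
    if mask_path.exists():
        truth = dict(side.get("truth", {}))
        truth["masks"] = load_masks(mask_path)
    return DynamicStudy(frames, np.asarray(side["frame_times_s"]),
                        tuple(side["spacing_mm"]), truth)


def save_perfusion_map(pm, stem) -> Path:
    stem = Path(stem)
    nib.save(nib.Nifti1Image(np.transpose(pm.data, (2, 1, 0)).astype(np.float32),
                             _affine(pm.spacing_mm)),
             str(stem.with_suffix(".nii.gz")))
    pm.table.to_csv(stem.with_suffix(".csv"), index=False)
    return stem.with_suffix(".nii.gz")


def save_cohort(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def load_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path)
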