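"""NIfTI and CSV input/output for cohorts, feature tables, and databanks.

Phantoms are stored as paired files ``<id>_image.nii.gz`` / ``<id>_mask.nii.gz``
(arrays written in x,y,z order with the spacing encoded in the affine),
outcomes as ``outcomes.csv`` with columns ``id,time,event``, and all tabular
results as plain CSV.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .volume import VolumeWithMask

__all__ = [
    "write_volume_pair",
    "read_volume_pair",
    "write_cohort",
    "read_cohort",
    "write_features",
    "read_features",
    "write_databank",
    "read_databank",
]


def _affine(vm: VolumeWithMask) -> np.ndarray:
    sz, sy, sx = vm.spacing_mm
    oz, oy, ox = vm.origin_mm
    aff = np.diag([sx, sy, sz, 1.0])
    aff[:3, 3] = (ox, oy, oz)
    return aff


def write_volume_pair(vm: VolumeWithMask, out_dir: str | Path, patient_id: str | None = None) -> tuple[Path, Path]:
    """Write ``<id>_image.nii.gz`` and ``<id>_mask.nii.gz``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pid = patient_id or vm.patient_id or "volume"
    aff = _affine(vm)
    img_path = out_dir / f"{pid}_image.nii.gz"
    msk_path = out_dir / f"{pid}_mask.nii.gz"
    nib.save(nib.Nifti1Image(np.transpose(vm.image, (2, 1, 0)).astype(np.float32), aff), img_path)
    nib.save(nib.Nifti1Image(np.transpose(vm.mask, (2, 1, 0)).astype(np.uint8), aff), msk_path)
    return img_path, msk_path


def _load(path: Path) -> tuple[np.ndarray, tuple, tuple]:
    img = nib.load(str(path))
    data = np.transpose(np.asarray(img.dataobj), (2, 1, 0))
    aff = img.affine
    spacing = (float(aff[2, 2]), float(aff[1, 1]), float(aff[0, 0]))
    origin = (float(aff[2, 3]), float(aff[1, 3]), float(aff[0, 3]))
    return data, spacing, origin


def read_volume_pair(image_path: str | Path, mask_path: str | Path, patient_id: str = "") -> VolumeWithMask:
    image, spacing, origin = _load(Path(image_path))
    mask, m_spacing, m_origin = _load(Path(mask_path))
    if image.shape != mask.shape or not np.allclose(spacing, m_spacing) or not np.allclose(origin, m_origin):
        raise ValueError(
            f"image/mask grid mismatch for {patient_id or image_path}: "
            f"{image.shape}@{spacing} vs {mask.shape}@{m_spacing}"
        )
    return VolumeWithMask(
        image=image.astype(np.float64), mask=mask > 0, spacing_mm=spacing,
        origin_mm=origin, patient_id=patient_id,
    )


def write_cohort(cohort: list[VolumeWithMask], out_dir: str | Path) -> None:
    for vm in cohort:
        write_volume_pair(vm, out_dir)


def read_cohort(in_dir: str | Path) -> list[VolumeWithMask]:
    """Discover ``*_image.nii.gz`` / ``*_mask.nii.gz`` pairs in a directory."""
    in_dir = Path(in_dir)
    images = sorted(in_dir.glob("*_image.nii.gz"))
    if not images:
        raise FileNotFoundError(f"no *_image.nii.gz files in {in_dir}")
    cohort = []
    for img_path in images:
        pid = img_path.name[: -len("_image.nii.gz")]
        msk_path = in_dir / f"{pid}_mask.nii.gz"
        if not msk_path.exists():
            raise FileNotFoundError(f"missing mask file for patient {pid}")
        cohort.append(read_volume_pair(img_path, msk_path, patient_id=pid))
    return cohort


def write_features(table: pd.DataFrame, path: str | Path) -> None:
    """Measurement/feature table to CSV (MultiIndex preserved)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path)


def read_features(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if {"patient", "measurement"} <= set(df.columns):
        df = df.set_index(["patient", "measurement"])
    else:
        df = df.set_index(df.columns[0])
        df.index.name = "patient"
    return df


def write_databank(databank: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    databank.to_csv(path)


def read_databank(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="feature_name")


def write_outcomes(outcomes: pd.DataFrame, path: str | Path) -> None:
    out = outcomes.copy()
    out.index.name = "id"
    out.to_csv(path)


def read_outcomes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="id")
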