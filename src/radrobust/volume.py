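"""Core in-memory container for a CT volume with an aligned binary tumor mask.

Arrays are indexed ``(z, y, x)``; ``spacing_mm`` follows the same axis order.
All physical quantities are millimetres and Hounsfield units (HU).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: HU value used to fill voxels that fall outside the grid after resampling.
AIR_HU = -1000.0


@dataclass
class VolumeWithMask:
    """A 3D HU image plus an aligned binary mask on the same grid.

    Parameters
    ----------
    image : ndarray, shape (nz, ny, nx)
        Voxel intensities in HU.
    mask : ndarray of bool, same shape
        Tumor (region-of-interest) indicator.
    spacing_mm : tuple of float
        Voxel size per axis ``(z, y, x)`` in mm.
    origin_mm : tuple of float
        Physical coordinate of voxel ``(0, 0, 0)``.
    """

    image: np.ndarray
    mask: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    patient_id: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=np.float64)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.image.ndim != 3:
            raise ValueError("image must be 3D")
        if self.image.shape != self.mask.shape:
            raise ValueError(
                f"image shape {self.image.shape} != mask shape {self.mask.shape}"
            )
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("all spacings must be positive")
        self.origin_mm = tuple(float(o) for o in self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.image.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def copy(self) -> "VolumeWithMask":
        return replace(self, image=self.image.copy(), mask=self.mask.copy())

    def mask_centroid_vox(self) -> np.ndarray:
        """Centroid of the mask in (fractional) voxel coordinates."""
        if not self.mask.any():
            raise ValueError("mask is empty; no centroid")
        return np.mean(np.argwhere(self.mask), axis=0)

    def crop_to_mask(self, margin_vox: int | tuple[int, int, int] = 10) -> "VolumeWithMask":
        """Return the sub-volume covering the mask bounding box plus a margin.

        The margin (scalar or per-axis) keeps enough context for interpolation
        and filtering near the tumor; the origin is shifted so physical
        coordinates are preserved.
        """
        if not self.mask.any():
            raise ValueError("mask is empty; nothing to crop to")
        margin = np.broadcast_to(np.asarray(margin_vox, dtype=int), (3,))
        idx = np.argwhere(self.mask)
        lo = np.maximum(idx.min(axis=0) - margin, 0)
        hi = np.minimum(idx.max(axis=0) + margin + 1, self.shape)
        sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
        origin = tuple(
            o + s * int(a)
            for o, s, a in zip(self.origin_mm, self.spacing_mm, lo)
        )
        return VolumeWithMask(
            image=self.image[sl].copy(),
            mask=self.mask[sl].copy(),
            spacing_mm=self.spacing_mm,
            origin_mm=origin,
            patient_id=self.patient_id,
        )


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap coefficient between two binary masks on the same grid."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)
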