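"""IBSI-aligned radiomic feature extraction.

The extraction pipeline is: resample image+mask to isotropic spacing,
resegment the intensity mask to a HU window, then compute

* 14 shape features from the morphological mask,
* 93 first-order + texture features (18 first-order, 24 GLCM, 16 GLRLM,
  16 GLSZM, 14 GLDM, 5 NGTDM) from each image type: the unfiltered image,
  six Laplacian-of-Gaussian responses (sigma 1..6 mm), and eight single-level
  undecimated Coiflet-1 wavelet subbands — 15 image types, 1395 intensity
  features, 1409 in total.

Gray levels are discretized to a fixed bin count (default 30) between the
ROI minimum and maximum of each image type.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy import ndimage
from sklearn.base import BaseEstimator, TransformerMixin

from ..volume import VolumeWithMask
from ._firstorder import FIRSTORDER_FEATURE_NAMES, firstorder_features
from ._shape import SHAPE_FEATURE_NAMES, shape_features
from ._texture import (
    GLCM_FEATURE_NAMES,
    GLDM_FEATURE_NAMES,
    GLRLM_FEATURE_NAMES,
    GLSZM_FEATURE_NAMES,
    NGTDM_FEATURE_NAMES,
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)

__all__ = [
    "ExtractionConfig",
    "PreprocessedVolume",
    "RadiomicsExtractor",
    "preprocess",
    "discretize",
    "log_filter",
    "wavelet_decompose",
    "shape_features",
    "intensity_texture_features",
    "extract_all",
    "feature_names",
]

ALL_INTENSITY_CLASSES = ("firstorder", "glcm", "glrlm", "glszm", "gldm", "ngtdm")
_CLASS_NAMES = {
    "firstorder": FIRSTORDER_FEATURE_NAMES,
    "glcm": GLCM_FEATURE_NAMES,
    "glrlm": GLRLM_FEATURE_NAMES,
    "glszm": GLSZM_FEATURE_NAMES,
    "gldm": GLDM_FEATURE_NAMES,
    "ngtdm": NGTDM_FEATURE_NAMES,
}
_CLASS_FUNCS = {
    "glcm": glcm_features,
    "glrlm": glrlm_features,
    "glszm": glszm_features,
    "gldm": gldm_features,
    "ngtdm": ngtdm_features,
}


@dataclass
class ExtractionConfig:
    """Extraction settings (defaults match the study protocol)."""

    target_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    resegment_window_hu: tuple[float, float] = (-150.0, 180.0)
    bin_count: int = 30
    log_sigmas_mm: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0)
    wavelet: str = "coif1"
    enabled_classes: tuple[str, ...] = ("shape",) + ALL_INTENSITY_CLASSES
    image_types: tuple[str, ...] = ("original", "log", "wavelet")

    def validate(self) -> None:
        if self.bin_count < 2:
            raise ValueError("bin_count must be >= 2")
        lo, hi = self.resegment_window_hu
        if not lo < hi:
            raise ValueError("resegment window lower bound must be < upper")
        if any(s <= 0 for s in self.log_sigmas_mm):
            raise ValueError("log sigmas must be positive")
        unknown = set(self.enabled_classes) - ({"shape"} | set(ALL_INTENSITY_CLASSES))
        if unknown:
            raise ValueError(f"unknown feature classes: {sorted(unknown)}")

    @property
    def intensity_classes(self) -> tuple[str, ...]:
        return tuple(c for c in ALL_INTENSITY_CLASSES if c in self.enabled_classes)


@dataclass
class PreprocessedVolume:
    """Resampled image with the morphological and resegmented intensity masks."""

    image: np.ndarray
    morph_mask: np.ndarray
    intensity_mask: np.ndarray
    spacing_mm: tuple[float, float, float]


def preprocess(vm: VolumeWithMask, cfg: ExtractionConfig) -> PreprocessedVolume:
    """Resample to the target spacing and resegment the intensity mask.

    The image is linearly interpolated; the mask is linearly interpolated and
    re-binarized at 0.5. Voxels whose resampled HU falls outside the
    resegmentation window are removed from the intensity mask only — shape
    features keep the full morphological mask.
    """
    cfg.validate()
    factors = tuple(s / t for s, t in zip(vm.spacing_mm, cfg.target_spacing_mm))
    if all(abs(f - 1.0) < 1e-9 for f in factors):
        image = vm.image.copy()
        mask = vm.mask.copy()
    else:
        image = ndimage.zoom(vm.image, factors, order=1, mode="nearest")
        mask = ndimage.zoom(
            vm.mask.astype(np.float32), factors, order=1, mode="nearest"
        ) >= 0.5
    lo, hi = cfg.resegment_window_hu
    intensity_mask = mask & (image >= lo) & (image <= hi)
    if not intensity_mask.any():
        raise ValueError(
            f"resegmentation window [{lo}, {hi}] HU removed every ROI voxel"
        )
    return PreprocessedVolume(
        image=image, morph_mask=mask, intensity_mask=intensity_mask,
        spacing_mm=tuple(cfg.target_spacing_mm),
    )


def discretize(image: np.ndarray, mask: np.ndarray, bin_count: int) -> np.ndarray:
    """Fixed-bin-count discretization of ROI intensities.

    Maps ROI values to gray levels 1..``bin_count`` over equal-width bins
    spanning [min, max] of the ROI; the maximum maps to ``bin_count``. Voxels
    outside the mask get label 0. A constant ROI collapses to a single
    occupied bin (level 1), the documented degenerate case.
    """
    if bin_count < 2:
        raise ValueError("bin_count must be >= 2")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty intensity mask")
    vals = image[mask]
    lo, hi = float(vals.min()), float(vals.max())
    labels = np.zeros(image.shape, dtype=np.int64)
    if hi == lo:
        labels[mask] = 1
        return labels
    width = (hi - lo) / bin_count
    labels[mask] = np.clip(
        np.floor((image[mask] - lo) / width).astype(np.int64) + 1, 1, bin_count
    )
    return labels


def log_filter(
    image: np.ndarray, sigma_mm: float, spacing_mm: tuple[float, float, float]
) -> np.ndarray:
    """Laplacian-of-Gaussian response with a physical-units sigma."""
    sigma_vox = tuple(float(sigma_mm) / s for s in spacing_mm)
    if any(sv < 1.0 for sv in sigma_vox):
        warnings.warn(
            f"LoG sigma {sigma_mm} mm is below the voxel size; response is "
            "dominated by discretization",
            stacklevel=2,
        )
    # truncate=8: the default 4-sigma support leaves a DC leak of ~3e-4
    # relative, visible as a spurious response on flat regions
    return ndimage.gaussian_laplace(image, sigma=sigma_vox, mode="nearest", truncate=8.0)


def wavelet_decompose(image: np.ndarray, wavelet: str = "coif1") -> dict[str, np.ndarray]:
    """Single-level undecimated 3D separable wavelet transform.

    Returns the 8 subbands on the input grid, keyed ``wavelet-XYZ`` where the
    three letters are the per-axis low/high-pass labels for the x, y and z
    axes in that order (arrays are indexed z, y, x). Uses the energy-
    preserving (``norm=True``) stationary-transform dialect, so for periodic
    signals the subband energies sum to the input energy.
    """
    pads = tuple((0, n % 2) for n in image.shape)  # swt needs even extents
    padded = np.pad(image, pads, mode="edge")
    coeffs = pywt.swtn(padded, wavelet, level=1, norm=True, trim_approx=False)[0]
    crop = tuple(slice(0, n) for n in image.shape)
    out = {}
    for key, band in coeffs.items():
        label = "".join("L" if ch == "a" else "H" for ch in reversed(key))
        out[f"wavelet-{label}"] = band[crop]
    return dict(sorted(out.items()))


def intensity_texture_features(
    image: np.ndarray,
    intensity_mask: np.ndarray,
    bin_count: int = 30,
    voxel_volume_mm3: float = 1.0,
    classes: tuple[str, ...] = ALL_INTENSITY_CLASSES,
) -> dict[str, float]:
    """First-order + texture features of one image type (93 when all classes on).

    Texture matrices are computed on the fixed-bin-count discretized volume,
    cropped to the ROI bounding box; first-order features use the raw
    intensities except Entropy/Uniformity, which are histogram statistics.
    """
    mask = np.asarray(intensity_mask, dtype=bool)
    labels_full = discretize(image, mask, bin_count)

    idx = np.argwhere(mask)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    L = labels_full[sl]

    out: dict[str, float] = {}
    if "firstorder" in classes:
        fo = firstorder_features(image[mask], labels_full[mask], voxel_volume_mm3)
        out.update({f"firstorder_{k}": v for k, v in fo.items()})
    for cls in classes:
        if cls == "firstorder":
            continue
        vals = _CLASS_FUNCS[cls](L)
        out.update({f"{cls}_{k}": v for k, v in vals.items()})
    return out


def _image_type_names(cfg: ExtractionConfig) -> list[str]:
    names = []
    if "original" in cfg.image_types:
        names.append("original")
    if "log" in cfg.image_types:
        names += [f"log-sigma-{s:g}-mm-3D" for s in cfg.log_sigmas_mm]
    if "wavelet" in cfg.image_types:
        names += [
            f"wavelet-{l}"
            for l in ("HHH", "HHL", "HLH", "HLL", "LHH", "LHL", "LLH", "LLL")
        ]
    return names


def feature_names(cfg: ExtractionConfig | None = None) -> list[str]:
    """The ordered feature names a given configuration emits."""
    cfg = cfg or ExtractionConfig()
    cfg.validate()
    names = []
    if "shape" in cfg.enabled_classes:
        names += [f"original_shape_{n}" for n in SHAPE_FEATURE_NAMES]
    for img_type in _image_type_names(cfg):
        for cls in cfg.intensity_classes:
            names += [
                f"{img_type}_{cls}_{n}_{cfg.bin_count}_binCount"
                for n in _CLASS_NAMES[cls]
            ]
    return names


def _crop_margins_vox(vm: VolumeWithMask, cfg: ExtractionConfig) -> tuple[int, ...]:
    # Enough native-resolution context for resampling plus the widest filter
    # support (4 sigma for the largest LoG scale; wavelet stencils are narrow).
    margin_mm = 6.0
    if "log" in cfg.image_types and cfg.log_sigmas_mm:
        margin_mm = max(margin_mm, 4.0 * max(cfg.log_sigmas_mm) + 4.0)
    if "wavelet" in cfg.image_types:
        margin_mm = max(margin_mm, 12.0)
    return tuple(int(np.ceil(margin_mm / s)) for s in vm.spacing_mm)


def extract_all(vm: VolumeWithMask, cfg: ExtractionConfig | None = None) -> pd.Series:
    """Full feature vector for one volume: preprocess, filter, extract.

    Returns a Series whose index follows the ``<imagetype>_<class>_<feature>_
    <bins>_binCount`` naming convention (shape features as
    ``original_shape_<feature>``). The volume is first cropped to the mask
    bounding box plus a filter-support margin; features depend only on
    geometry and ROI content, so this is value-preserving.
    """
    cfg = cfg or ExtractionConfig()
    cfg.validate()
    margins = _crop_margins_vox(vm, cfg)
    vmc = vm.crop_to_mask(margin_vox=margins)
    pv = preprocess(vmc, cfg)
    voxvol = float(np.prod(pv.spacing_mm))

    out: dict[str, float] = {}
    if "shape" in cfg.enabled_classes:
        sf = shape_features(pv.morph_mask, pv.spacing_mm)
        out.update({f"original_shape_{k}": v for k, v in sf.items()})

    classes = cfg.intensity_classes
    if classes:
        images: dict[str, np.ndarray] = {}
        if "original" in cfg.image_types:
            images["original"] = pv.image
        if "log" in cfg.image_types:
            for s in cfg.log_sigmas_mm:
                images[f"log-sigma-{s:g}-mm-3D"] = log_filter(
                    pv.image, s, pv.spacing_mm
                )
        if "wavelet" in cfg.image_types:
            images.update(wavelet_decompose(pv.image, cfg.wavelet))
        for img_type in _image_type_names(cfg):
            vals = intensity_texture_features(
                images[img_type], pv.intensity_mask, cfg.bin_count, voxvol, classes
            )
            out.update(
                {
                    f"{img_type}_{k}_{cfg.bin_count}_binCount": v
                    for k, v in vals.items()
                }
            )
    return pd.Series(out, name=vm.patient_id or None)


class RadiomicsExtractor(TransformerMixin, BaseEstimator):
    """Stateless transformer turning volumes into a radiomic feature table.

    Parameters mirror :class:`ExtractionConfig`; ``transform`` accepts a list
    of :class:`VolumeWithMask` and returns a DataFrame (rows = patients,
    columns = feature names in the stable configuration order).
    """

    def __init__(
        self,
        target_spacing_mm=(1.0, 1.0, 1.0),
        resegment_window_hu=(-150.0, 180.0),
        bin_count=30,
        log_sigmas_mm=(1.0, 2.0, 3.0, 4.0, 5.0, 6.0),
        wavelet="coif1",
        enabled_classes=("shape",) + ALL_INTENSITY_CLASSES,
        image_types=("original", "log", "wavelet"),
    ):
        self.target_spacing_mm = target_spacing_mm
        self.resegment_window_hu = resegment_window_hu
        self.bin_count = bin_count
        self.log_sigmas_mm = log_sigmas_mm
        self.wavelet = wavelet
        self.enabled_classes = enabled_classes
        self.image_types = image_types

    def _config(self) -> ExtractionConfig:
        return ExtractionConfig(
            target_spacing_mm=tuple(self.target_spacing_mm),
            resegment_window_hu=tuple(self.resegment_window_hu),
            bin_count=int(self.bin_count),
            log_sigmas_mm=tuple(self.log_sigmas_mm),
            wavelet=self.wavelet,
            enabled_classes=tuple(self.enabled_classes),
            image_types=tuple(self.image_types),
        )

    def fit(self, X=None, y=None):
        cfg = self._config()
        cfg.validate()
        self.feature_names_ = feature_names(cfg)
        self.n_features_out_ = len(self.feature_names_)
        return self

    def transform(self, X) -> pd.DataFrame:
        cfg = self._config()
        rows = [extract_all(vm, cfg) for vm in X]
        df = pd.DataFrame(rows)
        df.index = [
            vm.patient_id or str(i) for i, vm in enumerate(X)
        ]
        return df

    def get_feature_names_out(self, input_features=None):
        return np.asarray(feature_names(self._config()), dtype=object)
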