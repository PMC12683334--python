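"""Image/mask perturbations that mimic rescanning and recontouring variability.

Four modes are composed per realization, in a fixed order:

1. in-plane rigid transform (sub-voxel translation + rotation about the mask
   centroid) of image and mask,
2. additive Gaussian noise at a multiple of the image's own estimated noise
   level (image only),
3. randomized contour deformation of the mask by a smoothed, RMS-normalized
   random displacement field (mask only).

A realization is one random combination of parameters from the perturbation
grid; sixty realizations per patient is the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import AIR_HU, VolumeWithMask

__all__ = [
    "PerturbationGrid",
    "PerturbationRealization",
    "sample_realizations",
    "rigid_transform",
    "estimate_noise",
    "add_noise",
    "randomize_contour",
    "apply_realization",
]

# Noise gain of the 3D discrete Laplacian (center -6, six neighbors +1):
# sqrt(36 + 6) = sqrt(42). Divides the filtered residual's scale back to
# the white-noise standard deviation.
_LAPLACE_NOISE_GAIN = math.sqrt(42.0)
_MAD_TO_SIGMA = 1.4826022185056018  # 1 / Phi^-1(3/4)


@dataclass
class PerturbationGrid:
    """Parameter sets the realization sampler draws from."""

    translations_px: tuple[float, ...] = (0.0, 0.4, 0.8)
    rotations_deg: tuple[float, ...] = (-20.0, 0.0, 20.0)
    noise_multipliers: tuple[float, ...] = (0.0, 1.0, 2.0, 5.0)
    contour_smooth_sigma_vox: float = 10.0
    contour_amplitude_vox: float = 1.0
    n_realizations: int = 60

    def validate(self) -> None:
        for name in ("translations_px", "rotations_deg", "noise_multipliers"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"{name} must be non-empty")
        if self.contour_smooth_sigma_vox <= 0:
            raise ValueError("contour_smooth_sigma_vox must be positive")
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be >= 1")


@dataclass(frozen=True)
class PerturbationRealization:
    """One sampled combination of the four perturbation modes."""

    tx_px: float
    ty_px: float
    angle_deg: float
    noise_multiplier: float
    contour_seed: int
    contour_amplitude_vox: float = 1.0
    contour_smooth_sigma_vox: float = 10.0

    @property
    def is_identity(self) -> bool:
        return (
            self.tx_px == 0.0
            and self.ty_px == 0.0
            and self.angle_deg == 0.0
            and self.noise_multiplier == 0.0
            and self.contour_amplitude_vox == 0.0
        )


def sample_realizations(
    grid: PerturbationGrid, seed: int = 0
) -> list[PerturbationRealization]:
    """Draw ``grid.n_realizations`` random parameter combinations.

    Each parameter is sampled independently and uniformly from its set, with
    replacement across realizations; the contour displacement field gets a
    fresh seed per realization. Deterministic given ``seed``.
    """
    grid.validate()
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(grid.n_realizations):
        out.append(
            PerturbationRealization(
                tx_px=float(rng.choice(grid.translations_px)),
                ty_px=float(rng.choice(grid.translations_px)),
                angle_deg=float(rng.choice(grid.rotations_deg)),
                noise_multiplier=float(rng.choice(grid.noise_multipliers)),
                contour_seed=int(rng.integers(0, 2**31)),
                contour_amplitude_vox=float(grid.contour_amplitude_vox),
                contour_smooth_sigma_vox=float(grid.contour_smooth_sigma_vox),
            )
        )
    return out


def rigid_transform(
    vm: VolumeWithMask,
    tx_px: float,
    ty_px: float,
    angle_deg: float,
    fill_hu: float = AIR_HU,
    mask_only: bool = False,
) -> VolumeWithMask:
    """In-plane rotation about the mask centroid followed by translation.

    Rotation is about the z axis (axial plane); z is never perturbed, matching
    thick-slice CT where setup error is dominated by in-plane shifts and roll.
    The image is interpolated linearly with out-of-grid voxels set to
    ``fill_hu``; the mask is interpolated linearly and re-binarized at 0.5.

    ``mask_only=True`` skips the image interpolation (image passed through
    unchanged) — used when only mask-derived (shape) features are needed.
    """
    if not vm.mask.any():
        raise ValueError("empty mask: rotation center undefined")
    if abs(angle_deg) > 180:
        raise ValueError("|angle_deg| must be <= 180")
    if tx_px == 0.0 and ty_px == 0.0 and angle_deg == 0.0:
        return vm.copy()

    theta = math.radians(angle_deg)
    c, s = math.cos(theta), math.sin(theta)
    # Backward map on (z, y, x) voxel indices: rotate (y, x) about the mask
    # centroid, then shift by (ty, tx).  input = R^-1 (output - center - t) + center
    rot_inv = np.array([[1.0, 0.0, 0.0], [0.0, c, s], [0.0, -s, c]])
    center = vm.mask_centroid_vox()
    shift = np.array([0.0, float(ty_px), float(tx_px)])
    offset = center - rot_inv @ (center + shift)

    if mask_only:
        image = vm.image.copy()
    else:
        image = ndimage.affine_transform(
            vm.image, rot_inv, offset=offset, order=1, mode="constant",
            cval=float(fill_hu),
        )
    mask_f = ndimage.affine_transform(
        vm.mask.astype(np.float32), rot_inv, offset=offset, order=1,
        mode="constant", cval=0.0,
    )
    return VolumeWithMask(
        image=image, mask=mask_f >= 0.5, spacing_mm=vm.spacing_mm,
        origin_mm=vm.origin_mm, patient_id=vm.patient_id,
    )


def estimate_noise(
    vm: VolumeWithMask, body_threshold_hu: float = -300.0, min_body_voxels: int = 1000
) -> float:
    """Robust estimate of the additive Gaussian noise level, in HU.

    Applies a discrete Laplacian (a high-pass filter whose response to smooth
    anatomy is small), takes the median absolute deviation of the residual
    over body voxels (HU above ``body_threshold_hu``, eroded to avoid
    boundaries), and rescales by the filter's white-noise gain sqrt(42).
    """
    body = vm.image > body_threshold_hu
    body = ndimage.binary_erosion(body, iterations=2)
    n_body = int(body.sum())
    if n_body < min_body_voxels:
        raise ValueError(
            f"only {n_body} body voxels above {body_threshold_hu} HU; "
            f"need >= {min_body_voxels}"
        )
    residual = ndimage.laplace(vm.image)
    mad = float(np.median(np.abs(residual[body])))
    return mad * _MAD_TO_SIGMA / _LAPLACE_NOISE_GAIN


def add_noise(
    vm: VolumeWithMask, multiplier: float, sigma_hu: float, seed: int = 0
) -> VolumeWithMask:
    """Add i.i.d. Gaussian noise with std ``multiplier * sigma_hu`` to the image.

    A multiplier of zero returns the input unchanged; the mask is never
    touched.
    """
    if multiplier < 0 or sigma_hu < 0:
        raise ValueError("multiplier and sigma_hu must be >= 0")
    if multiplier == 0.0 or sigma_hu == 0.0:
        return vm.copy()
    rng = np.random.default_rng(seed)
    noisy = vm.image + rng.normal(0.0, multiplier * sigma_hu, size=vm.shape)
    return VolumeWithMask(
        image=noisy, mask=vm.mask.copy(), spacing_mm=vm.spacing_mm,
        origin_mm=vm.origin_mm, patient_id=vm.patient_id,
    )


def _raw_uniform_field(
    shape: tuple[int, int, int], rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-voxel U(-1,1) displacement components; the z component is shared by
    all voxels of a slice, mimicking slice-by-slice contouring."""
    nz = shape[0]
    uz = np.broadcast_to(
        rng.uniform(-1.0, 1.0, size=(nz, 1, 1)), shape
    ).copy()
    uy = rng.uniform(-1.0, 1.0, size=shape)
    ux = rng.uniform(-1.0, 1.0, size=shape)
    return uz, uy, ux


def make_displacement_field(
    shape: tuple[int, int, int],
    smooth_sigma_vox: float,
    amplitude_vox: float,
    seed: int,
    literal_order: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Smoothed, RMS-normalized random displacement field, in voxel units.

    Default pipeline: smooth each raw U(-1,1) component with a Gaussian of
    ``smooth_sigma_vox``, then normalize so the root-mean-square *magnitude*
    of the 3-vector field equals ``amplitude_vox`` — i.e. amplitude 1 means a
    typical displacement of one voxel. With ``literal_order=True`` each
    component is instead RMS-normalized before the smoothing (which leaves
    displacements far below ``amplitude_vox`` because smoothing averages away
    an uncorrelated field).
    """
    rng = np.random.default_rng(seed)
    components = list(_raw_uniform_field(shape, rng))
    out = []
    for comp in components:
        if literal_order:
            rms = np.sqrt(np.mean(comp**2))
            comp = comp / rms if rms > 0 else comp
            comp = ndimage.gaussian_filter(comp, sigma=smooth_sigma_vox, mode="reflect")
            comp = comp * amplitude_vox
        else:
            comp = ndimage.gaussian_filter(comp, sigma=smooth_sigma_vox, mode="reflect")
        out.append(comp)
    if not literal_order:
        total_rms = np.sqrt(np.mean(out[0] ** 2 + out[1] ** 2 + out[2] ** 2))
        if total_rms > 0:
            out = [c * (amplitude_vox / total_rms) for c in out]
    return tuple(out)


def randomize_contour(
    vm: VolumeWithMask,
    smooth_sigma_vox: float = 10.0,
    amplitude_vox: float = 1.0,
    seed: int = 0,
    literal_order: bool = False,
    margin_vox: int = 8,
) -> VolumeWithMask:
    """Deform the mask by a random displacement field; the image is untouched.

    The field lives on the mask's bounding box plus ``margin_vox``; the mask is
    backward-warped with linear interpolation and re-binarized at 0.5.
    """
    if not vm.mask.any():
        raise ValueError("empty mask: nothing to deform")
    if amplitude_vox == 0.0:
        return vm.copy()

    idx = np.argwhere(vm.mask)
    lo = np.maximum(idx.min(axis=0) - margin_vox, 0)
    hi = np.minimum(idx.max(axis=0) + margin_vox + 1, vm.shape)
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    sub = vm.mask[sl].astype(np.float32)

    dz, dy, dx = make_displacement_field(
        sub.shape, smooth_sigma_vox, amplitude_vox, seed, literal_order
    )
    grid = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in sub.shape], indexing="ij")
    coords = [grid[0] + dz, grid[1] + dy, grid[2] + dx]
    warped = ndimage.map_coordinates(sub, coords, order=1, mode="constant", cval=0.0)

    new_mask = np.zeros(vm.shape, dtype=bool)
    new_mask[sl] = warped >= 0.5
    if not new_mask.any():
        raise ValueError(
            f"contour randomization (seed={seed}, amplitude={amplitude_vox}) "
            "emptied the mask"
        )
    return VolumeWithMask(
        image=vm.image.copy(), mask=new_mask, spacing_mm=vm.spacing_mm,
        origin_mm=vm.origin_mm, patient_id=vm.patient_id,
    )


def apply_realization(
    vm: VolumeWithMask,
    r: PerturbationRealization,
    sigma_hu: float,
    fill_hu: float = AIR_HU,
    mask_only: bool = False,
) -> VolumeWithMask:
    """Compose rigid transform -> noise -> contour randomization, in that order.

    The identity realization returns the input unchanged (bit-exact).
    ``mask_only=True`` propagates to the rigid step and skips the noise step
    entirely (noise never changes the mask).
    """
    if r.is_identity:
        return vm.copy()
    out = rigid_transform(
        vm, r.tx_px, r.ty_px, r.angle_deg, fill_hu=fill_hu, mask_only=mask_only
    )
    if not mask_only and r.noise_multiplier > 0:
        out = add_noise(out, r.noise_multiplier, sigma_hu, seed=r.contour_seed)
    if r.contour_amplitude_vox > 0:
        out = randomize_contour(
            out,
            smooth_sigma_vox=r.contour_smooth_sigma_vox,
            amplitude_vox=r.contour_amplitude_vox,
            seed=r.contour_seed,
        )
    return out
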