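"""Synthetic CT phantom cohorts with textured ellipsoid tumors and survival outcomes.

The generator emulates the kind of input the robustness pipeline sees in
practice: a soft-tissue background, an ellipsoidal tumor whose interior is a
smoothed Gaussian random field (so gray-level texture matrices are
non-degenerate), additive white Gaussian acquisition noise with a known and
recoverable level, and anisotropic voxel spacing. Survival outcomes follow an
exponential proportional-hazards model with independent exponential censoring,
so known coefficients can be recovered by a Cox fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import VolumeWithMask

__all__ = [
    "PhantomSpec",
    "CohortDistribution",
    "generate_phantom",
    "generate_cohort",
    "simulate_survival",
]


@dataclass
class PhantomSpec:
    """Configuration of a single synthetic CT phantom.

    Defaults give a 64x96x96 grid at (3, 1, 1) mm spacing — thick-slice,
    in-plane-fine CT geometry — with a soft-tissue background and a mildly
    hyperdense textured tumor.
    """

    grid_shape: tuple[int, int, int] = (64, 96, 96)
    spacing_mm: tuple[float, float, float] = (3.0, 1.0, 1.0)
    tumor_axes_mm: tuple[float, float, float] = (15.0, 15.0, 15.0)
    tumor_center_mm: tuple[float, float, float] | None = None
    background_hu: float = 40.0
    tumor_mean_hu: float = 60.0
    texture_scale_mm: float = 4.0
    texture_amplitude_hu: float = 25.0
    noise_sigma_hu: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if any(int(n) < 8 for n in self.grid_shape):
            raise ValueError("grid_shape axes must be >= 8 voxels")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be positive")
        if any(a <= 0 for a in self.tumor_axes_mm):
            raise ValueError("tumor_axes_mm must be positive")
        if self.noise_sigma_hu < 0:
            raise ValueError("noise_sigma_hu must be >= 0")
        if self.texture_amplitude_hu < 0:
            raise ValueError("texture_amplitude_hu must be >= 0")
        center = self._center_mm()
        for ax in range(3):
            extent_vox = self.tumor_axes_mm[ax] / self.spacing_mm[ax]
            c_vox = center[ax] / self.spacing_mm[ax]
            if c_vox - extent_vox < 5 or c_vox + extent_vox > self.grid_shape[ax] - 5:
                raise ValueError(
                    "tumor does not fit inside the grid with a 5-voxel margin "
                    f"(axis {ax})"
                )

    def _center_mm(self) -> tuple[float, float, float]:
        if self.tumor_center_mm is not None:
            return tuple(float(c) for c in self.tumor_center_mm)
        return tuple(
            n * s / 2.0 for n, s in zip(self.grid_shape, self.spacing_mm)
        )


def generate_phantom(spec: PhantomSpec) -> VolumeWithMask:
    """Build one phantom volume+mask from a :class:`PhantomSpec`.

    The mask is the exact voxelized ellipsoid indicator. The image is
    ``background_hu`` outside the tumor and, inside,
    ``tumor_mean_hu + texture + noise`` where the texture is white Gaussian
    noise smoothed at ``texture_scale_mm`` and rescaled to
    ``texture_amplitude_hu`` standard deviation. Deterministic given
    ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(n) for n in spec.grid_shape)
    spacing = np.asarray(spec.spacing_mm)
    center = np.asarray(spec._center_mm())
    axes = np.asarray(spec.tumor_axes_mm)

    coords = [
        (np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)
    ]  # voxel-center physical coordinates
    zz, yy, xx = np.meshgrid(*coords, indexing="ij")
    r2 = (
        ((zz - center[0]) / axes[0]) ** 2
        + ((yy - center[1]) / axes[1]) ** 2
        + ((xx - center[2]) / axes[2]) ** 2
    )
    mask = r2 <= 1.0

    image = np.full(shape, float(spec.background_hu))
    image[mask] = float(spec.tumor_mean_hu)

    if spec.texture_amplitude_hu > 0:
        white = rng.standard_normal(shape)
        sigma_vox = np.asarray(spec.texture_scale_mm) / spacing
        texture = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="reflect")
        std = texture.std()
        if std > 0:
            texture *= spec.texture_amplitude_hu / std
        image[mask] += texture[mask]

    if spec.noise_sigma_hu > 0:
        image += rng.normal(0.0, spec.noise_sigma_hu, size=shape)

    return VolumeWithMask(
        image=image, mask=mask, spacing_mm=spec.spacing_mm,
        patient_id=f"phantom-{spec.seed}",
    )


@dataclass
class CohortDistribution:
    """Uniform ranges over per-patient :class:`PhantomSpec` fields.

    Each patient's tumor size, density, texture, and noise level is drawn
    independently from these closed intervals; everything else is copied from
    ``base``.
    """

    tumor_axes_mm: tuple[float, float] = (8.0, 20.0)
    tumor_mean_hu: tuple[float, float] = (40.0, 80.0)
    texture_amplitude_hu: tuple[float, float] = (15.0, 35.0)
    noise_sigma_hu: tuple[float, float] = (10.0, 20.0)
    base: PhantomSpec = field(default_factory=PhantomSpec)

    def validate(self) -> None:
        for name in (
            "tumor_axes_mm",
            "tumor_mean_hu",
            "texture_amplitude_hu",
            "noise_sigma_hu",
        ):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"empty range for {name}: ({lo}, {hi})")


def _child_seed(master_seed: int, *key: int) -> int:
    """Derive a stable child seed; adding later patients never shifts earlier streams."""
    ss = np.random.SeedSequence(int(master_seed), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1)[0] % (2**31))


def generate_cohort(
    n: int,
    spec_distribution: CohortDistribution | None = None,
    seed: int = 0,
) -> list[VolumeWithMask]:
    """Generate ``n`` phantoms with per-patient varied size/intensity/texture.

    Per-patient seeds are derived hierarchically from the master ``seed``.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    dist = spec_distribution or CohortDistribution()
    dist.validate()
    cohort = []
    for i in range(n):
        patient_seed = _child_seed(seed, i)
        draw = np.random.default_rng(patient_seed)
        # Tumor semi-axes drawn independently per axis within the range so
        # shapes (elongation/flatness) vary across patients too.
        axes = tuple(draw.uniform(*dist.tumor_axes_mm) for _ in range(3))
        spec = PhantomSpec(
            grid_shape=dist.base.grid_shape,
            spacing_mm=dist.base.spacing_mm,
            tumor_axes_mm=axes,
            tumor_center_mm=dist.base.tumor_center_mm,
            background_hu=dist.base.background_hu,
            tumor_mean_hu=float(draw.uniform(*dist.tumor_mean_hu)),
            texture_scale_mm=dist.base.texture_scale_mm,
            texture_amplitude_hu=float(draw.uniform(*dist.texture_amplitude_hu)),
            noise_sigma_hu=float(draw.uniform(*dist.noise_sigma_hu)),
            seed=patient_seed,
        )
        vm = generate_phantom(spec)
        vm.patient_id = f"P{i:04d}"
        cohort.append(vm)
    return cohort


def simulate_survival(
    features: pd.DataFrame,
    beta: dict[str, float],
    baseline_hazard: float = 0.1,
    censor_rate: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate (time, event) outcomes under an exponential proportional-hazards model.

    Features named in ``beta`` are z-scored across the table before the linear
    predictor is formed; event times are exponential with rate
    ``baseline_hazard * exp(beta^T z)`` and censoring is an independent
    exponential with rate ``censor_rate``.

    Returns a DataFrame indexed like ``features`` with columns ``time`` and
    ``event`` (1 = event observed, 0 = censored).
    """
    unknown = set(beta) - set(features.columns)
    if unknown:
        raise KeyError(f"unknown feature name(s) in beta: {sorted(unknown)}")
    if baseline_hazard <= 0:
        raise ValueError("baseline_hazard must be positive")
    if censor_rate < 0:
        raise ValueError("censor_rate must be >= 0")
    rng = np.random.default_rng(seed)
    n = len(features)
    lp = np.zeros(n)
    for name, b in beta.items():
        col = features[name].to_numpy(dtype=float)
        sd = col.std()
        z = (col - col.mean()) / sd if sd > 0 else np.zeros(n)
        lp += float(b) * z
    rate = baseline_hazard * np.exp(lp)
    event_time = rng.exponential(1.0 / rate)
    if censor_rate > 0:
        censor_time = rng.exponential(1.0 / censor_rate, size=n)
    else:
        censor_time = np.full(n, np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    return pd.DataFrame({"time": time, "event": event}, index=features.index)
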