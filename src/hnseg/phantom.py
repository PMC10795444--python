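"""Synthetic CT-like phantoms with exact organ masks.

Generates ellipsoidal "organs" embedded in noisy background so the
whole pipeline — preprocessing, training, uncertainty scoring,
selection, evaluation — runs with no external data.  Geometry mimics a
head-and-neck protocol scaled down for desk-size tests: the default is
a 64x64 grid at 1 mm in-plane spacing and 3 mm slice thickness; full
512x512 volumes are supported by the same code path.

A "domain shift" (HU offset, extra noise, organ rescaling) produces a
labeled external pool that is systematically different from the local
pool, mirroring the local-hospital vs public-dataset situation that
motivates localized fine-tuning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .io_preprocess import (
    BinaryMask,
    CTVolume,
    SOFT_TISSUE_WINDOW,
    WindowSpec,
    apply_window,
    pad_or_crop,
    resample_in_plane,
    resample_mask_in_plane,
)

__all__ = [
    "PhantomSpec",
    "CorruptionSpec",
    "generate_phantom_pool",
    "corrupt_mask_to_probability",
    "preprocess_case",
    "pool_to_dataset",
    "pool_to_cases",
]


@dataclass
class PhantomSpec:
    """Geometry and intensity parameters of the phantom generator.

    Semi-axis ranges are in voxels: `organ_axes_inplane` for rows/cols
    and `organ_axes_slices` along the scan axis.  The domain shift is
    (HU offset, extra noise SD, organ scale factor).
    """

    image_size: int = 64
    n_slices: int = 8
    spacing: tuple[float, float, float] = (3.0, 1.0, 1.0)
    organ_axes_inplane: tuple[float, float] = (8.0, 16.0)
    organ_axes_slices: tuple[float, float] = (2.5, 4.0)
    organ_hu: float = 60.0
    background_hu: float = -20.0
    noise_sd: float = 20.0
    domain_shift: tuple[float, float, float] = (80.0, 10.0, 1.25)
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.organ_axes_inplane[1] * max(1.0, self.domain_shift[2]) \
                >= self.image_size / 2:
            raise ValueError("organ semi-axes do not fit within the grid")


@dataclass
class CorruptionSpec:
    """Controls for degrading a perfect mask into a probability map."""

    boundary_blur_sd: float = 0.0   # pixels
    flip_fraction: float = 0.0      # fraction of pixels pushed toward 0.5
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.flip_fraction <= 1):
            raise ValueError("flip_fraction must lie in [0, 1]")
        if self.boundary_blur_sd < 0:
            raise ValueError("boundary_blur_sd must be non-negative")


def _ellipsoid_mask(shape, center, semi_axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    dist2 = sum(((g - c) / a) ** 2
                for g, c, a in zip(grids, center, semi_axes))
    return (dist2 <= 1.0).astype(np.uint8)


def _generate_case(spec: PhantomSpec, rng: np.random.Generator,
                   case_id: str, shifted: bool):
    shape = (spec.n_slices, spec.image_size, spec.image_size)
    offset_hu, extra_sd, scale = spec.domain_shift if shifted else (0.0, 0.0, 1.0)

    a_sl = rng.uniform(*spec.organ_axes_slices)
    a_r = rng.uniform(*spec.organ_axes_inplane) * scale
    a_c = rng.uniform(*spec.organ_axes_inplane) * scale
    jitter = spec.image_size / 8.0
    center = (spec.n_slices / 2.0 + rng.uniform(-0.5, 0.5),
              spec.image_size / 2.0 + rng.uniform(-jitter, jitter),
              spec.image_size / 2.0 + rng.uniform(-jitter, jitter))
    mask = _ellipsoid_mask(shape, center, (a_sl, a_r, a_c))

    sd = spec.noise_sd + extra_sd
    hu = rng.normal(spec.background_hu + offset_hu, sd, size=shape)
    organ = rng.normal(spec.organ_hu + offset_hu, sd, size=shape)
    hu[mask == 1] = organ[mask == 1]
    return (CTVolume(voxels=hu, spacing=spec.spacing, case_id=case_id),
            BinaryMask(voxels=mask, spacing=spec.spacing,
                       organ="phantom", case_id=case_id))


def generate_phantom_pool(spec: PhantomSpec, n_cases: int,
                          seed: int | None = None, shifted: bool = False,
                          id_prefix: str = "case"):
    """Generate `n_cases` (CTVolume, BinaryMask) pairs, seed-deterministic.

    `shifted=True` applies the spec's domain shift, emulating an
    external public pool with different intensity, noise and organ
    scale than the local pool.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    return [_generate_case(spec, rng, f"{id_prefix}{i:03d}", shifted)
            for i in range(n_cases)]


def corrupt_mask_to_probability(mask: BinaryMask | np.ndarray,
                                corruption: CorruptionSpec) -> np.ndarray:
    """Degrade a perfect mask into a plausible network probability map.

    Gaussian blur widens the boundary transition (boundary uncertainty);
    a random `flip_fraction` of pixels is pushed 80% of the way toward
    0.5 (scattered low confidence).  Both degradations lower the Dice
    of the 0.5-thresholded map against the original mask and raise the
    mean pixel uncertainty, giving a controllable quality gradient.
    """
    voxels = mask.voxels if isinstance(mask, BinaryMask) else np.asarray(mask)
    voxels = voxels.astype(np.float64)
    stack = voxels[None] if voxels.ndim == 2 else voxels
    rng = np.random.default_rng(corruption.seed)
    out = np.empty_like(stack)
    for i, sl in enumerate(stack):
        p = gaussian_filter(sl, corruption.boundary_blur_sd) \
            if corruption.boundary_blur_sd > 0 else sl.copy()
        if corruption.flip_fraction > 0:
            flip = rng.random(p.shape) < corruption.flip_fraction
            p[flip] += 0.8 * (0.5 - p[flip])
        out[i] = np.clip(p, 0.0, 1.0)
    return out[0] if voxels.ndim == 2 else out


def preprocess_case(volume: CTVolume, mask: BinaryMask,
                    window: WindowSpec = SOFT_TISSUE_WINDOW,
                    target_spacing_mm: float | None = None,
                    target_size: int | None = None):
    """Full preprocessing chain for one case: resample, pad/crop, window.

    Returns (slices (S, H, W) in [0, 1], masks (S, H, W) in {0, 1}).
    Resampling/padding are skipped when targets are None (phantoms are
    generated on the target grid already).
    """
    if target_spacing_mm is not None:
        volume = resample_in_plane(volume, target_spacing_mm)
        mask = resample_mask_in_plane(mask, target_spacing_mm)
    vox, mvox = volume.voxels, mask.voxels
    if target_size is not None:
        vox = np.stack([pad_or_crop(sl, target_size) for sl in vox])
        mvox = np.stack([pad_or_crop(sl, target_size) for sl in mvox])
    return apply_window(vox, window), mvox.astype(np.uint8)


def pool_to_dataset(pool, window: WindowSpec = SOFT_TISSUE_WINDOW):
    """Flatten a phantom pool into [(slice, mask)] training pairs."""
    dataset = []
    for vol, mask in pool:
        slices, masks = preprocess_case(vol, mask, window=window)
        dataset.extend(zip(slices, masks))
    return dataset


def pool_to_cases(pool, window: WindowSpec = SOFT_TISSUE_WINDOW) -> dict:
    """Index a phantom pool by case id: {case_id: (slices, masks)}."""
    return {vol.case_id: preprocess_case(vol, mask, window=window)
            for vol, mask in pool}
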