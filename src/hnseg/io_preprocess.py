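"""Volume I/O and geometric/intensity preprocessing for CT slices.

The pipeline harmonizes heterogeneous scans before they reach the
network: in-plane bilinear resampling to a common pixel spacing
(default 1 mm), symmetric zero-padding or center-cropping to a fixed
slice size (default 512), then HU windowing with linear rescaling to
[0, 1].  Masks travel through the same geometry with nearest-neighbour
interpolation so labels stay binary.  Resampling is purely in-plane:
the model is 2-D slice-based, so slice thickness is left untouched.

Order of operations: resample -> pad/crop -> window.  Interpolation is
therefore performed in HU space; since windowing is a monotone affine
clip, interpolating before or after it differs only where the window
clips, and doing it in HU space avoids committing to a window early.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml
from scipy.ndimage import map_coordinates

__all__ = [
    "CTVolume",
    "BinaryMask",
    "WindowSpec",
    "SOFT_TISSUE_WINDOW",
    "SKELETAL_WINDOW",
    "load_window_presets",
    "window_for_organ",
    "resample_in_plane",
    "pad_or_crop",
    "apply_window",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
]


@dataclass
class CTVolume:
    """A CT scan: HU voxels (slices, rows, cols) with physical spacing (mm)."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]   # (slice_mm, row_mm, col_mm)
    case_id: str = ""

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValueError("voxels must be a non-empty 3-D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be strictly positive")
        if not np.isfinite(self.voxels).all():
            raise ValueError("HU values must be finite")


@dataclass
class BinaryMask:
    """A per-organ binary label volume sharing its CT's geometry."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    organ: str = ""
    case_id: str = ""

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        vals = np.unique(self.voxels)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask values must be 0 or 1")
        self.voxels = self.voxels.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be strictly positive")


@dataclass(frozen=True)
class WindowSpec:
    lower: float
    upper: float
    name: str = ""

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValueError("window requires lower < upper")


SOFT_TISSUE_WINDOW = WindowSpec(-140.0, 210.0, "soft_tissue")
SKELETAL_WINDOW = WindowSpec(-350.0, 1250.0, "skeletal")


def load_window_presets(path: str | Path | None = None) -> dict:
    """Load window presets; defaults to the packaged YAML."""
    if path is None:
        text = resources.files("hnseg").joinpath("data/windows.yaml") \
            .read_text()
    else:
        text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    windows = {name: WindowSpec(w["lower"], w["upper"], name)
               for name, w in cfg["windows"].items()}
    return {"windows": windows, "organs": cfg["organs"]}


def window_for_organ(organ: str, presets: dict | None = None) -> WindowSpec:
    presets = presets or load_window_presets()
    try:
        return presets["windows"][presets["organs"][organ]]
    except KeyError:
        raise KeyError(f"no window preset for organ '{organ}'") from None


# -- geometry -------------------------------------------------------------

def _resample_plane_size(n: int, old_mm: float, target_mm: float) -> int:
    # round-half-up keeps the physical field of view as close as possible
    return int(np.floor(n * old_mm / target_mm + 0.5))


def _resample_stack(voxels: np.ndarray, spacing, target_mm: float,
                    order: int) -> np.ndarray:
    _, rows, cols = voxels.shape
    new_rows = _resample_plane_size(rows, spacing[1], target_mm)
    new_cols = _resample_plane_size(cols, spacing[2], target_mm)
    # pixel-center convention: output pixel j sits at physical (j+0.5)*target
    rr = (np.arange(new_rows) + 0.5) * target_mm / spacing[1] - 0.5
    cc = (np.arange(new_cols) + 0.5) * target_mm / spacing[2] - 0.5
    grid = np.meshgrid(rr, cc, indexing="ij")
    out = np.empty((voxels.shape[0], new_rows, new_cols), dtype=np.float64)
    for k, sl in enumerate(voxels):
        out[k] = map_coordinates(sl.astype(np.float64), grid, order=order,
                                 mode="nearest")
    return out


def resample_in_plane(volume: CTVolume, target_spacing_mm: float = 1.0
                      ) -> CTVolume:
    """Bilinearly resample each slice to the target in-plane spacing.

    The new in-plane size is round(old_size * old_spacing / target) per
    axis; the slice axis is untouched.
    """
    if target_spacing_mm <= 0:
        raise ValueError("target spacing must be positive")
    out = _resample_stack(volume.voxels, volume.spacing, target_spacing_mm,
                          order=1)
    return CTVolume(voxels=out,
                    spacing=(volume.spacing[0], target_spacing_mm,
                             target_spacing_mm),
                    case_id=volume.case_id)


def resample_mask_in_plane(mask: BinaryMask, target_spacing_mm: float = 1.0
                           ) -> BinaryMask:
    """Nearest-neighbour counterpart for label volumes (stays binary)."""
    if target_spacing_mm <= 0:
        raise ValueError("target spacing must be positive")
    out = _resample_stack(mask.voxels, mask.spacing, target_spacing_mm,
                          order=0)
    return BinaryMask(voxels=out.astype(np.uint8),
                      spacing=(mask.spacing[0], target_spacing_mm,
                               target_spacing_mm),
                      organ=mask.organ, case_id=mask.case_id)


def pad_or_crop(slice_image: np.ndarray, target_size: int = 512) -> np.ndarray:
    """Zero-pad or center-crop a slice to target_size x target_size.

    Padding and cropping are symmetric; when the margin is odd the
    extra pixel goes to (or comes off) the high-index side.  Content is
    never rescaled.
    """
    if target_size < 1:
        raise ValueError("target_size must be >= 1")
    out = np.asarray(slice_image)
    for axis in (0, 1):
        n = out.shape[axis]
        if n < target_size:
            lo = (target_size - n) // 2
            hi = target_size - n - lo
            pad = [(0, 0), (0, 0)]
            pad[axis] = (lo, hi)
            out = np.pad(out, pad)
        elif n > target_size:
            start = (n - target_size) // 2
            sl = [slice(None), slice(None)]
            sl[axis] = slice(start, start + target_size)
            out = out[tuple(sl)]
    return out


def apply_window(volume: CTVolume | np.ndarray,
                 window: WindowSpec) -> np.ndarray:
    """Clip HU to [lower, upper] and rescale linearly to [0, 1]."""
    voxels = volume.voxels if isinstance(volume, CTVolume) else \
        np.asarray(volume, dtype=np.float64)
    clipped = np.clip(voxels, window.lower, window.upper)
    return (clipped - window.lower) / (window.upper - window.lower)


# -- NIfTI I/O ------------------------------------------------------------
# On disk the array axes follow the usual NIfTI (x=col, y=row, z=slice)
# order; in memory volumes are (slice, row, col).

def _affine(spacing) -> np.ndarray:
    return np.diag([spacing[2], spacing[1], spacing[0], 1.0])


def _load(path: str | Path):
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        zooms = img.header.get_zooms()[:3]
    except Exception as exc:  # malformed header etc.
        raise IOError(f"failed to read NIfTI file {path}: {exc}") from exc
    voxels = np.ascontiguousarray(data.transpose(2, 1, 0))
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return voxels, spacing


def read_volume(path: str | Path, case_id: str = "") -> CTVolume:
    voxels, spacing = _load(path)
    return CTVolume(voxels=voxels.astype(np.float64), spacing=spacing,
                    case_id=case_id or Path(path).stem.split(".")[0])


def write_volume(volume: CTVolume, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(volume.voxels.transpose(2, 1, 0),
                          _affine(volume.spacing))
    img.header.set_zooms((volume.spacing[2], volume.spacing[1],
                          volume.spacing[0]))
    nib.save(img, str(path))
    return path


def read_mask(path: str | Path, organ: str = "", case_id: str = "") -> BinaryMask:
    voxels, spacing = _load(path)
    return BinaryMask(voxels=(voxels > 0.5).astype(np.uint8),
                      spacing=spacing, organ=organ,
                      case_id=case_id or Path(path).stem.split(".")[0])


def write_mask(mask: BinaryMask, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8).transpose(2, 1, 0),
                          _affine(mask.spacing))
    img.header.set_zooms((mask.spacing[2], mask.spacing[1],
                          mask.spacing[0]))
    nib.save(img, str(path))
    return path
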