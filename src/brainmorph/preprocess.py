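"""Minimal MRI preprocessing: mask, conform, rescale, center.

The network consumes volumes on a canonical grid: 256³ voxels at 1 mm
isotropic spacing.  Preprocessing is deliberately minimal — no registration,
no bias-field correction — matching the design goal of regressing morphometry
from near-raw T1-weighted images:

1. ``skull_strip``     — zero everything outside a supplied binary brain mask
2. ``conform``         — trilinear resample to 1 mm, center crop/pad to 256³
3. ``rescale_intensity`` — linear min–max map onto [0, 4095]
4. ``center_foreground`` — integer shift of the foreground center of mass to
   the grid center (cheap, interpolation-free, so later augmentation shifts
   stay within bounds)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "VolumeGrid",
    "CANONICAL_EDGE",
    "INTENSITY_MAX",
    "skull_strip",
    "conform",
    "rescale_intensity",
    "center_foreground",
    "preprocess_volume",
    "load_nifti",
    "save_nifti",
]

CANONICAL_EDGE = 256
INTENSITY_MAX = 4095.0


@dataclass
class VolumeGrid:
    """A 3-D intensity grid with isotropic-or-not voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D grid, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def is_canonical(self) -> bool:
        return self.shape == (CANONICAL_EDGE,) * 3 and self.spacing == (1.0, 1.0, 1.0)


def skull_strip(volume: VolumeGrid, mask: np.ndarray) -> VolumeGrid:
    """Zero all voxels outside the binary brain mask."""
    mask = np.asarray(mask)
    if mask.shape != volume.shape:
        raise ValueError(f"mask shape {mask.shape} != volume shape {volume.shape}")
    return VolumeGrid(volume.data * (mask > 0), volume.spacing)


def _center_crop_pad(data: np.ndarray, edge: int) -> np.ndarray:
    """Symmetric crop or zero-pad each axis to length ``edge``."""
    out = data
    for ax in range(3):
        n = out.shape[ax]
        if n > edge:
            lo = (n - edge) // 2
            sl = [slice(None)] * 3
            sl[ax] = slice(lo, lo + edge)
            out = out[tuple(sl)]
        elif n < edge:
            lo = (edge - n) // 2
            pad = [(0, 0)] * 3
            pad[ax] = (lo, edge - n - lo)
            out = np.pad(out, pad)
    return out


def conform(volume: VolumeGrid, edge: int = CANONICAL_EDGE, order: int = 1) -> VolumeGrid:
    """Resample to 1 mm isotropic spacing and center crop/pad to ``edge``³.

    Trilinear interpolation for intensities (``order=1``); pass ``order=0``
    for masks.  Already-canonical inputs pass through unchanged.
    """
    if volume.shape == (edge,) * 3 and volume.spacing == (1.0, 1.0, 1.0):
        return VolumeGrid(volume.data.copy(), (1.0, 1.0, 1.0))
    data = volume.data
    if volume.spacing != (1.0, 1.0, 1.0):
        data = ndimage.zoom(data, zoom=volume.spacing, order=order, grid_mode=True, mode="grid-constant")
    return VolumeGrid(_center_crop_pad(data, edge), (1.0, 1.0, 1.0))


def rescale_intensity(volume: VolumeGrid, top: float = INTENSITY_MAX) -> VolumeGrid:
    """Linearly map the intensity range onto [0, ``top``].

    A constant volume carries no signal and maps to all zeros.
    """
    lo = float(volume.data.min())
    hi = float(volume.data.max())
    if hi == lo:
        return VolumeGrid(np.zeros_like(volume.data), volume.spacing)
    out = (volume.data.astype(np.float64) - lo) * (top / (hi - lo))
    return VolumeGrid(out, volume.spacing)


def center_foreground(volume: VolumeGrid) -> VolumeGrid:
    """Shift so the intensity-weighted foreground center of mass sits at the
    grid center (index ``edge//2`` per axis).

    The shift is rounded to whole voxels (no resampling); voxels shifted out
    of the grid are discarded and vacated voxels are zero-filled.
    """
    data = volume.data
    fg = data > 0
    if not fg.any():
        raise ValueError("cannot center a volume with empty foreground")
    idx = np.nonzero(fg)
    w = data[idx].astype(np.float64)
    com = np.array([np.average(ix, weights=w) for ix in idx])
    target = np.array([n // 2 for n in data.shape], dtype=float)
    shift = np.rint(target - com).astype(int)
    if not shift.any():
        return VolumeGrid(data.copy(), volume.spacing)
    out = np.zeros_like(data)
    src = [slice(max(0, -s), min(n, n - s)) for s, n in zip(shift, data.shape)]
    dst = [slice(max(0, s), min(n, n + s)) for s, n in zip(shift, data.shape)]
    out[tuple(dst)] = data[tuple(src)]
    return VolumeGrid(out, volume.spacing)


def preprocess_volume(
    volume: VolumeGrid, mask: np.ndarray, edge: int = CANONICAL_EDGE
) -> VolumeGrid:
    """Full pipeline: skull-strip → conform → rescale → center."""
    stripped = skull_strip(volume, mask)
    conformed = conform(stripped, edge=edge)
    rescaled = rescale_intensity(conformed)
    return center_foreground(rescaled)


def load_nifti(path) -> VolumeGrid:
    import nibabel as nib

    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeGrid(np.asanyarray(img.dataobj).astype(np.float32), spacing)


def save_nifti(volume: VolumeGrid, path) -> None:
    import nibabel as nib

    affine = np.diag(list(volume.spacing) + [1.0])
    nib.save(nib.Nifti1Image(volume.data.astype(np.float32), affine), str(path))
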