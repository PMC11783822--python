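"""CT preprocessing: HU windowing, axial MIP slabs and the test-time
augmentation grid.

The detector consumes bone-windowed 8-bit maximum-intensity projections: HU
values are clipped to [-10, 1000] (soft tissue floor to dense cortical bone)
and rescaled to [0, 255]; axial slices are collapsed into 8 mm slabs by a
per-pixel maximum.  Self-ensembling inference perturbs the windowed volume
with a small grid of intensity shifts and contrast factors chosen so every
fracture's visual pattern is preserved.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

HU_WINDOW = (-10.0, 1000.0)
DEFAULT_SLAB_MM = 8.0
DEFAULT_SHIFTS = (-2, -1, 0, 1, 2)
DEFAULT_CONTRASTS = (0.8, 0.9, 1.0, 1.1, 1.2)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    # np.round rounds half to even; the pipeline is specified bit-exact
    # with half-up rounding.
    return np.floor(np.asarray(x, dtype=float) + 0.5)


@dataclass(frozen=True)
class AugmentationParams:
    """One cell of the test-time augmentation grid.

    intensity_shift is in uint8 intensity units; contrast_factor scales
    about mid-gray.  The identity cell is (0, 1.0).
    """

    intensity_shift: int
    contrast_factor: float

    def __post_init__(self) -> None:
        if self.contrast_factor <= 0:
            raise ValueError("contrast_factor must be > 0")

    @property
    def is_identity(self) -> bool:
        return self.intensity_shift == 0 and self.contrast_factor == 1.0


@dataclass(frozen=True)
class CTVolume:
    """A 3D CT grid with voxel spacing in mm.

    ``intensities`` holds HU reals before windowing and integers in
    [0, 255] after; ``axial_axis`` indexes the slice axis.
    """

    intensities: np.ndarray
    voxel_spacing: tuple[float, float, float]  # (x, y, z) mm
    axial_axis: int = 2

    def __post_init__(self) -> None:
        if self.intensities.ndim != 3:
            raise ValueError("CTVolume requires a 3D intensity grid")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacings must all be > 0")
        if not 0 <= self.axial_axis <= 2:
            raise ValueError("axial_axis must be 0, 1 or 2")

    @property
    def axial_spacing_mm(self) -> float:
        return self.voxel_spacing[self.axial_axis]

    @property
    def n_axial_slices(self) -> int:
        return self.intensities.shape[self.axial_axis]


@dataclass(frozen=True)
class MIPStack:
    """Axial maximum-intensity-projection slabs of a windowed volume."""

    slices: tuple[np.ndarray, ...]
    slab_thickness_mm: float
    source_spacing: tuple[float, float, float]


def clip_rescale_hu(volume: CTVolume) -> CTVolume:
    """Window HU intensities to [-10, 1000] and rescale to uint8 [0, 255].

    v -> round_half_up((clip(v, -10, 1000) + 10) / 1010 * 255).
    """
    if volume.intensities.size == 0:
        raise ValueError("cannot window an empty volume")
    lo, hi = HU_WINDOW
    clipped = np.clip(volume.intensities.astype(float), lo, hi)
    scaled = _round_half_up((clipped - lo) / (hi - lo) * 255.0).astype(np.uint8)
    return CTVolume(scaled, volume.voxel_spacing, volume.axial_axis)


def axial_mip(
    volume: CTVolume,
    thickness_mm: float = DEFAULT_SLAB_MM,
    slice_range: Optional[tuple[int, int]] = None,
) -> MIPStack:
    """Collapse axial slices into non-overlapping MIP slabs.

    Slab size is ceil(thickness_mm / z-spacing) source slices; the trailing
    partial slab is kept so no slice is lost.  ``slice_range`` optionally
    restricts to a half-open axial range first (manual pelvic crop).
    """
    dz = volume.axial_spacing_mm
    if thickness_mm < dz:
        raise ValueError(f"slab thickness {thickness_mm} mm < axial spacing {dz} mm")
    data = np.moveaxis(volume.intensities, volume.axial_axis, 0)
    if slice_range is not None:
        start, stop = slice_range
        data = data[start:stop]
    if data.shape[0] == 0:
        raise ValueError("no axial slices to project")
    slab = int(np.ceil(thickness_mm / dz))
    slices = tuple(
        data[i : i + slab].max(axis=0) for i in range(0, data.shape[0], slab)
    )
    return MIPStack(slices, float(thickness_mm), volume.voxel_spacing)


def apply_augmentation(volume: CTVolume, params: AugmentationParams) -> CTVolume:
    """Contrast-adjust about mid-gray, shift, then clip back into [0, 255].

    v' = clip(round_half_up(127.5 + c * (v - 127.5)) + s, 0, 255).
    Expects an already-windowed (uint8-valued) volume.
    """
    v = volume.intensities.astype(float)
    contrasted = _round_half_up(127.5 + params.contrast_factor * (v - 127.5))
    shifted = contrasted + params.intensity_shift
    out = np.clip(shifted, 0, 255).astype(np.uint8)
    return CTVolume(out, volume.voxel_spacing, volume.axial_axis)


def augmentation_grid(
    shifts: Sequence[int] = DEFAULT_SHIFTS,
    contrasts: Sequence[float] = DEFAULT_CONTRASTS,
) -> tuple[AugmentationParams, ...]:
    """The Cartesian shift x contrast grid, in fixed lexicographic order.

    The default 5 x 5 grid yields K = 25 augmented scans; the identity cell
    (0, 1.0) serves as the original scan.
    """
    return tuple(
        AugmentationParams(int(s), float(c))
        for s, c in itertools.product(shifts, contrasts)
    )


def load_nifti(path: str | Path) -> CTVolume:
    """Read a NIfTI volume; voxel spacing from the header zooms."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    return CTVolume(data, tuple(float(z) for z in zooms), axial_axis=2)


def save_nifti(volume: CTVolume, path: str | Path) -> None:
    import nibabel as nib

    affine = np.diag(list(volume.voxel_spacing) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume.intensities), affine), str(path))
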