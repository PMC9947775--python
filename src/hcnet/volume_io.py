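"""NIfTI volume I/O, intensity normalization, and cube resampling.

The analysis grid is an isotropic ``size**3`` cube (default 256): one
trilinear resampling of the native volume onto that common grid serves all
three slicing axes, so the three per-axis probability maps live on the same
grid and can be fused voxel-wise.  Masks move between grids by
nearest-neighbour lookup only, so they stay exactly binary.

Axis names used elsewhere in the package (sagittal/coronal/axial) refer to
grid axes 0/1/2 of the resampled cube; no anatomical reorientation is
performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Volume",
    "MaskVolume",
    "read_nifti",
    "read_nifti_mask",
    "write_nifti",
    "normalize_intensity",
    "resample_to_cube",
    "resample_mask_to_cube",
    "resample_mask_to_native",
]


@dataclass
class Volume:
    """A 3D intensity grid with voxel spacing and a voxel-to-world affine."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    source_path: str | None = None

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValueError(f"expected a 3D grid, got shape {self.voxels.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing}")
        if np.isnan(self.voxels).any():
            raise ValueError("volume contains NaN voxels")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class MaskVolume:
    """A binary 3D grid sharing geometry with its paired :class:`Volume`."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    source_path: str | None = None

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D grid, got shape {self.voxels.shape}")
        vals = np.unique(self.voxels)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask voxels must be exactly 0 or 1")
        self.voxels = self.voxels.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


def _load_single_volume(path) -> tuple[np.ndarray, tuple, np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such NIfTI file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4:
        if data.shape[3] != 1:
            raise ValueError(
                f"{path} is not a single 3D volume (4D with {data.shape[3]} frames)"
            )
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path} is not a single 3D volume (ndim={data.ndim})")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing, np.asarray(img.affine, dtype=float)


def read_nifti(path) -> Volume:
    """Load a single-frame NIfTI volume; intensities are cast to float32."""
    data, spacing, affine = _load_single_volume(path)
    data = data.astype(np.float32)
    if np.isnan(data).any():
        raise ValueError(f"{path} contains NaN intensities")
    return Volume(data, spacing, affine, source_path=str(path))


def read_nifti_mask(path) -> MaskVolume:
    """Load a binary NIfTI mask (values must be exactly 0/1)."""
    data, spacing, affine = _load_single_volume(path)
    return MaskVolume(data, spacing, affine, source_path=str(path))


def write_nifti(vol: Volume | MaskVolume, path) -> None:
    """Write a volume (float32) or mask (uint8, values {0,1}) as NIfTI-1."""
    if isinstance(vol, MaskVolume):
        data = vol.voxels.astype(np.uint8)
    else:
        data = vol.voxels.astype(np.float32)
    img = nib.Nifti1Image(data, vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def normalize_intensity(v: Volume) -> Volume:
    """Min-max rescale intensities to [0, 1].

    A constant volume has no dynamic range; it is mapped to all zeros with a
    warning rather than raising, so batch pipelines stay total.
    """
    x = v.voxels.astype(np.float32)
    lo = float(x.min())
    hi = float(x.max())
    if hi == lo:
        warnings.warn("constant-intensity volume: normalizing to all zeros")
        out = np.zeros_like(x)
    else:
        out = (x - lo) / (hi - lo)
    return Volume(out, v.spacing, v.affine, source_path=v.source_path)


def _cube_coords(native_shape, size):
    """Fractional source indices sampled by each cube axis (edge-aligned)."""
    return [
        (np.arange(size) + 0.5) * (n / size) - 0.5 for n in native_shape
    ]


def _cube_affine(native_affine, native_shape, size):
    scale = np.array([n / size for n in native_shape], dtype=float)
    A = native_affine.copy()
    A[:3, :3] = native_affine[:3, :3] * scale[np.newaxis, :]
    shift = (scale - 1.0) / 2.0
    A[:3, 3] = native_affine[:3, :3] @ shift + native_affine[:3, 3]
    return A


def resample_to_cube(v: Volume, size: int = 256) -> Volume:
    """Trilinearly resample a volume onto an isotropic ``size**3`` grid.

    The physical extent of each axis is preserved: output spacing is
    ``native_spacing * native_shape / size`` per axis.  Sample points are
    edge-aligned, so resampling a grid onto itself is the identity.
    """
    size = int(size)
    if size < 8:
        raise ValueError("cube size must be at least 8")
    coords = _cube_coords(v.shape, size)
    grid = np.meshgrid(*coords, indexing="ij")
    out = ndimage.map_coordinates(
        v.voxels.astype(np.float32), np.stack(grid), order=1, mode="nearest"
    )
    spacing = tuple(sp * n / size for sp, n in zip(v.spacing, v.shape))
    return Volume(out.astype(np.float32), spacing,
                  _cube_affine(v.affine, v.shape, size), source_path=v.source_path)


def resample_mask_to_cube(m: MaskVolume, size: int = 256) -> MaskVolume:
    """Nearest-neighbour resampling of a native mask onto the analysis cube."""
    size = int(size)
    if size < 8:
        raise ValueError("cube size must be at least 8")
    idx = [
        np.clip(np.rint(c).astype(int), 0, n - 1)
        for c, n in zip(_cube_coords(m.shape, size), m.shape)
    ]
    gi, gj, gk = np.meshgrid(*idx, indexing="ij")
    out = m.voxels[gi, gj, gk]
    spacing = tuple(sp * n / size for sp, n in zip(m.spacing, m.shape))
    return MaskVolume(out, spacing, _cube_affine(m.affine, m.shape, size),
                      source_path=m.source_path)


def resample_mask_to_native(m: MaskVolume, target: Volume) -> MaskVolume:
    """Nearest-neighbour resampling of a cube-grid mask back to native geometry."""
    cube = m.voxels
    if len({cube.shape[0], cube.shape[1], cube.shape[2]}) != 1:
        raise ValueError("mask is not on a cubic analysis grid")
    size = cube.shape[0]
    out_idx = []
    for n in target.shape:
        # inverse of the edge-aligned forward mapping
        idx = np.rint((np.arange(n) + 0.5) * (size / n) - 0.5).astype(int)
        out_idx.append(np.clip(idx, 0, size - 1))
    gi, gj, gk = np.meshgrid(*out_idx, indexing="ij")
    out = cube[gi, gj, gk]
    return MaskVolume(out, target.spacing, target.affine, source_path=m.source_path)
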