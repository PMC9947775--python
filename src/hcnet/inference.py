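"""Tri-planar inference: slide the network along each grid axis, reassemble
per-axis probability volumes, fuse them, threshold, and map back to native
space.

For one axis with ``N`` slices the ``N - 2`` blocks are evaluated in
batches; the brain-class probability of each block's *middle* output slice
is written to its center slice, so interior slices are covered exactly
once.  The two boundary slices (never block centers) are filled from the
nearest block's outer output slice.  The three per-axis maps are fused
voxel-wise (unweighted mean by default, majority vote optionally) and
thresholded at 0.5 (ties count as brain, matching two-class argmax).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datablock import make_blocks
from .model import HCNet
from .volume_io import MaskVolume, Volume, normalize_intensity, resample_mask_to_native, resample_to_cube

__all__ = [
    "AxisProbabilityVolume",
    "FusedMaskResult",
    "predict_axis",
    "fuse_axes",
    "threshold_mask",
    "extract_brain",
    "skull_strip",
]


@dataclass
class AxisProbabilityVolume:
    """Brain-class probability on the analysis cube, from slicing one axis."""

    probabilities: np.ndarray
    axis: int

    def __post_init__(self):
        p = self.probabilities
        if p.ndim != 3 or len({p.shape[0], p.shape[1], p.shape[2]}) != 1:
            raise ValueError(f"expected a cubic probability grid, got {p.shape}")
        if p.min() < 0 or p.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class FusedMaskResult:
    fused_probabilities: np.ndarray
    mask_cube: MaskVolume
    mask_native: MaskVolume
    threshold: float


def predict_axis(
    model: HCNet, volume_cube: Volume, axis: int, batch_size: int = 20
) -> AxisProbabilityVolume:
    """Per-axis probability volume from middle-slice assembly."""
    cube = volume_cube.voxels
    size = cube.shape[0]
    if len({cube.shape[0], cube.shape[1], cube.shape[2]}) != 1:
        raise ValueError("volume is not on a cubic analysis grid")
    if size != model.config.cube_size:
        raise ValueError(
            f"cube size {size} does not match the checkpoint's {model.config.cube_size}"
        )
    blocks = make_blocks(volume_cube, None, axis)
    out = np.empty((size, size, size), dtype=np.float32)  # axis-first layout
    written = np.zeros(size, dtype=bool)
    for start in range(0, len(blocks), batch_size):
        chunk = blocks[start : start + batch_size]
        x = np.stack([b.planes for b in chunk]).astype(np.float32)[:, None]
        probs = model.forward(x, training=False)  # (B, 2, 3, H, W)
        for b, p in zip(chunk, probs):
            s0 = b.center_index - 1  # 0-based center slice
            out[s0] = p[1, 1]
            written[s0] = True
            if b.center_index == 2:  # first block also covers slice 1 (0-based 0)
                out[0] = p[1, 0]
                written[0] = True
            if b.center_index == size - 1:  # last block covers slice N (0-based N-1)
                out[size - 1] = p[1, 2]
                written[size - 1] = True
    assert written.all(), "internal error: unwritten slices"
    vol = np.moveaxis(out, 0, axis)
    return AxisProbabilityVolume(np.ascontiguousarray(np.clip(vol, 0.0, 1.0)), axis)


def fuse_axes(
    p0: AxisProbabilityVolume,
    p1: AxisProbabilityVolume,
    p2: AxisProbabilityVolume,
    rule: str = "mean",
) -> np.ndarray:
    """Voxel-wise merge of the three per-axis probability maps."""
    maps = [p.probabilities for p in (p0, p1, p2)]
    if maps[0].shape != maps[1].shape or maps[1].shape != maps[2].shape:
        raise ValueError("per-axis probability volumes differ in shape")
    if rule == "mean":
        return (maps[0] + maps[1] + maps[2]) / 3.0
    if rule == "vote":
        votes = sum((m >= 0.5).astype(np.float32) for m in maps)
        return (votes >= 2).astype(np.float32)
    raise ValueError(f"unknown fusion rule: {rule!r}")


def threshold_mask(fused: np.ndarray, tau: float = 0.5) -> np.ndarray:
    """Binarize a probability grid; values equal to the threshold count as brain."""
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {tau}")
    return (np.asarray(fused) >= tau).astype(np.uint8)


def extract_brain(native_volume: Volume, mask_native: MaskVolume) -> Volume:
    """Zero out non-brain voxels of the native volume."""
    if native_volume.shape != mask_native.shape:
        raise ValueError(
            f"volume {native_volume.shape} and mask {mask_native.shape} shapes differ"
        )
    out = native_volume.voxels * mask_native.voxels.astype(native_volume.voxels.dtype)
    return Volume(out, native_volume.spacing, native_volume.affine,
                  source_path=native_volume.source_path)


def skull_strip(
    native_volume: Volume,
    model: HCNet,
    threshold: float = 0.5,
    fusion: str = "mean",
    batch_size: int = 20,
) -> FusedMaskResult:
    """Full pipeline: preprocess, predict three axes, fuse, threshold, map back."""
    cube = normalize_intensity(resample_to_cube(native_volume, model.config.cube_size))
    per_axis = [predict_axis(model, cube, axis, batch_size) for axis in (0, 1, 2)]
    fused = fuse_axes(*per_axis, rule=fusion)
    mask_cube = MaskVolume(threshold_mask(fused, threshold), cube.spacing, cube.affine)
    mask_native = resample_mask_to_native(mask_cube, native_volume)
    return FusedMaskResult(fused, mask_cube, mask_native, threshold)
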