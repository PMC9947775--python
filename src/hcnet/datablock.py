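"""Tri-planar three-slice "data block" construction.

A data block is three consecutive slices of the resampled, normalized cube
along one grid axis, labeled (when a mask is available) by the middle
slice's mask.  With ``N`` slices along an axis and a reading step of 1 the
centers run over ``s = 2 .. N-1`` (1-based), giving ``N - 2`` blocks whose
neighbours overlap by two slices.  Slicing every volume along all three
axes triples the dataset: ``3 * (N - 2)`` blocks per cube.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .volume_io import MaskVolume, Volume

__all__ = ["DataBlock", "make_blocks", "build_dataset", "write_manifest"]


@dataclass
class DataBlock:
    """Three stacked slices plus the middle slice's label.

    ``planes`` has shape (3, H, W); ``center_index`` is the 1-based index
    ``s`` of the middle slice along ``axis``.
    """

    planes: np.ndarray
    axis: int
    center_index: int
    label: np.ndarray | None = None
    volume_id: str | None = None

    def __post_init__(self):
        if self.planes.ndim != 3 or self.planes.shape[0] != 3:
            raise ValueError(f"planes must be (3, H, W), got {self.planes.shape}")
        if self.axis not in (0, 1, 2):
            raise ValueError(f"axis must be 0, 1 or 2, got {self.axis}")
        if self.label is not None and self.label.shape != self.planes.shape[1:]:
            raise ValueError("label shape must match the slice shape")


def make_blocks(
    volume_cube: Volume,
    mask_cube: MaskVolume | None = None,
    axis: int = 0,
    volume_id: str | None = None,
) -> list[DataBlock]:
    """Cut one axis of a preprocessed cube into overlapping depth-3 blocks."""
    if axis not in (0, 1, 2):
        raise ValueError(f"axis must be 0, 1 or 2, got {axis}")
    vox = volume_cube.voxels
    n = vox.shape[axis]
    if n < 3:
        raise ValueError(f"axis {axis} has {n} slices: too short for a data block")
    if mask_cube is not None and mask_cube.shape != vox.shape:
        raise ValueError(
            f"volume {vox.shape} and mask {mask_cube.shape} shapes differ"
        )
    stack = np.moveaxis(vox, axis, 0)
    mstack = np.moveaxis(mask_cube.voxels, axis, 0) if mask_cube is not None else None
    blocks = []
    for s in range(2, n):  # s is 1-based: centers 2 .. N-1 -> 0-based s-1
        planes = stack[s - 2 : s + 1]
        label = mstack[s - 1] if mstack is not None else None
        blocks.append(DataBlock(planes, axis, s, label, volume_id))
    return blocks


def build_dataset(
    pairs: Iterable[tuple[Volume, MaskVolume | None]],
    volume_ids: Sequence[str] | None = None,
) -> list[DataBlock]:
    """Blocks over all three axes for every (volume, mask) pair.

    Order is deterministic: volume-major, then axis 0/1/2, then ascending
    center index.  Shuffling is the trainer's responsibility.
    """
    dataset: list[DataBlock] = []
    for i, (vol, mask) in enumerate(pairs):
        vid = volume_ids[i] if volume_ids is not None else f"vol{i:03d}"
        if mask is not None and mask.shape != vol.shape:
            raise ValueError(f"pair {vid}: volume/mask shape mismatch")
        for axis in (0, 1, 2):
            dataset.extend(make_blocks(vol, mask, axis, vid))
    return dataset


def write_manifest(blocks: Sequence[DataBlock], path) -> None:
    """Plain-text audit log: one ``volume_id axis center_index`` line per block."""
    with open(path, "w") as fh:
        for b in blocks:
            fh.write(f"{b.volume_id or '-'}\t{b.axis}\t{b.center_index}\n")
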