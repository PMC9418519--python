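"""Core voxel-volume containers.

All volumes are plain numpy arrays in (z, y, x) axis order — z is the
slicing/projection axis of a serial-section acquisition — wrapped together
with a :class:`GridSpec` carrying the physical voxel size in nanometres.
Index windows are 0-based and half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "GridSpec",
    "VoxelVolume",
    "BinaryVolume",
    "LabeledVolume",
]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a voxel grid.

    Parameters
    ----------
    shape
        Grid extents ``(nz, ny, nx)`` in voxels.
    voxel_size
        Physical edge length of one (cubic) voxel, in nm.
    origin
        Offset of voxel ``(0, 0, 0)`` from the parent volume it was cropped
        from, in voxels. ``(0, 0, 0)`` for a freshly created volume.
    """

    shape: tuple[int, int, int]
    voxel_size: float
    origin: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"shape must be three extents >= 1, got {self.shape}")
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be > 0, got {self.voxel_size}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "origin", tuple(int(o) for o in self.origin))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in nm^3."""
        return float(self.voxel_size) ** 3

    def physical_extent(self) -> tuple[float, float, float]:
        """Physical edge lengths (z, y, x) in nm."""
        return tuple(s * self.voxel_size for s in self.shape)


@dataclass
class VoxelVolume:
    """A 3D scalar grid with physical metadata.

    ``kind`` records the intensity semantics: raw grayscale data, a
    two-phase pore/solid mask (pore = True, the "black voxel = void"
    convention of segmented tomograms), or integer object labels.
    """

    data: np.ndarray
    grid: GridSpec
    kind: Literal["grayscale", "binary", "labels"] = "grayscale"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got ndim={self.data.ndim}")
        if tuple(self.data.shape) != tuple(self.grid.shape):
            raise ValueError(
                f"data shape {self.data.shape} does not match grid shape {self.grid.shape}"
            )

    @property
    def voxel_size(self) -> float:
        return self.grid.voxel_size

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)

    def crop(self, lower: tuple[int, int, int], extents: tuple[int, int, int]):
        """Extract a half-open subvolume ``[lower, lower + extents)``.

        The returned volume's grid records the accumulated origin offset so
        provenance survives repeated crops.
        """
        lower = tuple(int(v) for v in lower)
        extents = tuple(int(v) for v in extents)
        for lo, ext, n in zip(lower, extents, self.shape):
            if lo < 0 or ext < 1 or lo + ext > n:
                raise ValueError(
                    f"crop window lower={lower} extents={extents} out of bounds for shape {self.shape}"
                )
        sl = tuple(slice(lo, lo + ext) for lo, ext in zip(lower, extents))
        new_origin = tuple(o + lo for o, lo in zip(self.grid.origin, lower))
        new_grid = GridSpec(extents, self.grid.voxel_size, new_origin)
        return type(self)(self.data[sl].copy(), new_grid, **self._extra_kwargs())

    def _extra_kwargs(self) -> dict:
        return {"kind": self.kind}


@dataclass
class BinaryVolume(VoxelVolume):
    """Two-phase volume: ``True`` = pore/void, ``False`` = solid."""

    kind: Literal["binary"] = "binary"

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.data.dtype != bool:
            self.data = self.data.astype(bool)

    @property
    def pore_voxels(self) -> int:
        return int(self.data.sum())

    def _extra_kwargs(self) -> dict:
        return {}


@dataclass
class LabeledVolume(VoxelVolume):
    """Non-negative integer labels: 0 = solid, k >= 1 = pore object k.

    Labels are contiguous ``1..n_labels``; the union of all labels is the
    pore phase of the binary volume the labelling came from.
    """

    n_labels: int = 0
    kind: Literal["labels"] = "labels"

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.data.size and self.data.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def pore_mask(self) -> np.ndarray:
        return self.data > 0

    def _extra_kwargs(self) -> dict:
        return {"n_labels": self.n_labels}


def same_grid(a: VoxelVolume, b: VoxelVolume) -> bool:
    return a.grid.shape == b.grid.shape and a.grid.voxel_size == b.grid.voxel_size
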