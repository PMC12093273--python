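"""Volume containers and the preprocessing stage.

Whole-brain light-microscopy volumes are resampled to an isotropic voxel
grid, partitioned into fixed-size sub-blocks, and reduced to 2D maximum
intensity projections (MIPs) that gate the downstream segmentation.

Coordinate convention (repo-wide): arrays are indexed ``data[x, y, z]`` with
0-based voxel indices, ``(x, y, z) = (width, height, depth)``.  Centroids and
point coordinates are voxel-center floats in the same frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

DEFAULT_BLOCK_SHAPE = (512, 512, 512)  # production sub-block size, voxels
DEFAULT_ISO_VOXEL_UM = 0.35  # standardized isotropic resolution, um/voxel


@dataclass
class Volume3D:
    """A 3D grayscale grid with voxel-size metadata.

    Parameters
    ----------
    data : ndarray, shape (X, Y, Z)
        Intensity grid; float volumes are expected in [0, 1] after
        :func:`normalize_volume`.
    voxel_size : tuple of float
        Physical voxel edge lengths (vx, vy, vz) in micrometers.
    origin : tuple of int
        Voxel offset of this volume inside its parent (0 for a root volume).
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("Volume3D requires a 3D array with all dims >= 1")
        if min(self.voxel_size) <= 0:
            raise ValueError("voxel_size components must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class SubBlock:
    """A cuboid cut from a parent volume on a regular grid."""

    volume: Volume3D
    grid_index: tuple[int, int, int]
    block_shape: tuple[int, int, int]
    pad: tuple[int, int, int] = (0, 0, 0)  # trailing zero-pad per axis

    def __post_init__(self):
        expected = tuple(g * b for g, b in zip(self.grid_index, self.block_shape))
        if tuple(self.volume.origin) != expected:
            raise ValueError("SubBlock origin must equal grid_index * block_shape")


@dataclass
class MIPImage:
    """2D maximum intensity projection of a sub-block."""

    data: np.ndarray
    source_index: tuple[int, int, int]
    projection_axis: str = "z"


_AXIS = {"x": 0, "y": 1, "z": 2}


def normalize_volume(data: np.ndarray) -> np.ndarray:
    """Global min-max normalization to [0, 1] (constant volumes map to 0)."""
    data = np.asarray(data, dtype=np.float32)
    lo, hi = float(data.min()), float(data.max())
    if hi == lo:
        return np.zeros_like(data)
    return (data - lo) / (hi - lo)


def resample_isotropic(v: Volume3D, target_voxel: float) -> Volume3D:
    """Resample to an isotropic grid of `target_voxel` um by cubic interpolation.

    Output dimension along each axis is ``round(dim * voxel / target)``;
    interpolation over/undershoot is clipped back to the input range.
    """
    if target_voxel <= 0:
        raise ValueError("target_voxel must be positive")
    if min(v.shape) < 4:
        raise ValueError("cubic resampling needs every dimension >= 4")
    out_shape = tuple(
        int(round(d * s / target_voxel)) for d, s in zip(v.shape, v.voxel_size)
    )
    zoom = [o / i for o, i in zip(out_shape, v.shape)]
    out = ndimage.zoom(v.data.astype(np.float32), zoom, order=3, grid_mode=True,
                       mode="grid-constant")
    # zoom can slightly miss the requested size on awkward ratios; enforce it
    if out.shape != out_shape:  # pragma: no cover - defensive
        out = out[tuple(slice(0, s) for s in out_shape)]
    out = np.clip(out, float(v.data.min()), float(v.data.max()))
    return Volume3D(out, (target_voxel,) * 3, v.origin)


def partition(v: Volume3D, block_shape: tuple[int, int, int]) -> list[SubBlock]:
    """Tile `v` into non-overlapping blocks, zero-padding edge blocks.

    The number of blocks is ``prod(ceil(dim / block))``; block ``(i, j, k)``
    starts at voxel ``(i, j, k) * block_shape``.
    """
    block_shape = tuple(int(b) for b in block_shape)
    if min(block_shape) < 1:
        raise ValueError("block_shape components must be >= 1")
    counts = tuple(-(-d // b) for d, b in zip(v.shape, block_shape))
    blocks: list[SubBlock] = []
    for i in range(counts[0]):
        for j in range(counts[1]):
            for k in range(counts[2]):
                origin = (i * block_shape[0], j * block_shape[1], k * block_shape[2])
                stop = tuple(min(o + b, d) for o, b, d in zip(origin, block_shape, v.shape))
                chunk = v.data[origin[0]:stop[0], origin[1]:stop[1], origin[2]:stop[2]]
                pad = tuple(b - (s - o) for b, s, o in zip(block_shape, stop, origin))
                if any(pad):
                    chunk = np.pad(chunk, tuple((0, p) for p in pad))
                blocks.append(SubBlock(
                    Volume3D(chunk, v.voxel_size, origin),
                    grid_index=(i, j, k),
                    block_shape=block_shape,
                    pad=pad,
                ))
    return blocks


def reassemble(blocks: list[SubBlock], full_shape: tuple[int, int, int]) -> np.ndarray:
    """Inverse of :func:`partition`: crop pads and place blocks back."""
    out = np.zeros(full_shape, dtype=blocks[0].volume.data.dtype)
    for b in blocks:
        o = b.volume.origin
        stop = tuple(min(oo + bb, d) for oo, bb, d in zip(o, b.block_shape, full_shape))
        size = tuple(s - oo for s, oo in zip(stop, o))
        out[o[0]:stop[0], o[1]:stop[1], o[2]:stop[2]] = \
            b.volume.data[: size[0], : size[1], : size[2]]
    return out


def mip(b: SubBlock, axis: str = "z") -> MIPImage:
    """Maximum intensity projection along `axis` (default depth)."""
    if axis not in _AXIS:
        raise ValueError(f"axis must be one of {sorted(_AXIS)}")
    return MIPImage(
        data=b.volume.data.max(axis=_AXIS[axis]),
        source_index=b.grid_index,
        projection_axis=axis,
    )
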