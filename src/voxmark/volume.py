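"""Volumetric intensity grids.

A :class:`Volume` is a 3D scalar intensity grid with physical voxel spacing,
the in-memory container every other module operates on.  The indexing
convention is fixed once and asserted everywhere: 0-based, voxel-center,
``data[i, j, k]`` with ``x = column (i)``, ``y = row (j)``, ``z = slice (k)``.
World coordinates of voxel ``(i, j, k)`` are ``origin + (i*sx, j*sy, k*sz)``;
a voxel's coordinate refers to its center.
"""

from __future__ import annotations

import zipfile
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = ["Volume", "downsample", "downsampled_dims", "write_fixture", "read_fixture"]


@dataclass
class Volume:
    """A 3D scalar intensity grid with voxel spacing and provenance.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Intensities in stored-value units (monotone in physical density),
        converted to floating point on construction.
    spacing : tuple of float
        Physical units per voxel along (x, y, z); strictly positive.
    origin : tuple of float
        World position of the center of voxel (0, 0, 0).
    downsample_factors : tuple of int
        Averaging factors already applied to this grid (1 = native).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    downsample_factors: tuple[int, int, int] = (1, 1, 1)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        self.downsample_factors = tuple(int(f) for f in self.downsample_factors)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if any(f < 1 for f in self.downsample_factors):
            raise ValueError("downsample factors must be >= 1")

    @property
    def dims(self) -> tuple[int, int, int]:
        """(nx, ny, nz): grid extents along x, y, z."""
        return self.data.shape

    @property
    def bounds_lo(self) -> np.ndarray:
        """World coordinates of the first voxel center."""
        return np.asarray(self.origin, dtype=float)

    @property
    def bounds_hi(self) -> np.ndarray:
        """World coordinates of the last voxel center."""
        return self.bounds_lo + (np.asarray(self.dims) - 1) * np.asarray(self.spacing)

    @property
    def center(self) -> np.ndarray:
        """World center of the voxel-center range."""
        return 0.5 * (self.bounds_lo + self.bounds_hi)

    def index_to_world(self, index) -> np.ndarray:
        """World coordinates of (fractional) voxel index (i, j, k)."""
        return self.bounds_lo + np.asarray(index, dtype=float) * np.asarray(self.spacing)

    def world_to_index(self, point) -> np.ndarray:
        """Fractional voxel index of a world point."""
        return (np.asarray(point, dtype=float) - self.bounds_lo) / np.asarray(self.spacing)

    def sample(self, points: np.ndarray) -> np.ndarray:
        """Trilinearly interpolated intensity at world ``points`` (N, 3).

        Points outside the voxel-center range are clamped to the nearest
        border value (callers clip rays to the volume bounds first).
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        idx = (pts - self.bounds_lo) / np.asarray(self.spacing)
        out = map_coordinates(self.data, idx.T, order=1, mode="nearest")
        return out if np.asarray(points).ndim > 1 else out[0]

    def contains(self, point) -> bool:
        """True if a world point lies within the voxel-center range."""
        p = np.asarray(point, dtype=float)
        return bool(np.all(p >= self.bounds_lo - 1e-12) and np.all(p <= self.bounds_hi + 1e-12))


def downsampled_dims(dims, factors) -> tuple[int, int, int]:
    """Output extents of block-mean down-sampling: floor(dims / factors).

    Trailing voxels that do not fill a complete block are dropped, so every
    output voxel is an equal-weight mean.  Metadata-only: no grid required.
    """
    dims = tuple(int(d) for d in dims)
    factors = tuple(int(f) for f in factors)
    if any(f < 1 for f in factors):
        raise ValueError("downsample factors must be >= 1")
    if any(f > d for f, d in zip(factors, dims)):
        raise ValueError(f"factor {factors} exceeds dims {dims}")
    return tuple(d // f for d, f in zip(dims, factors))


def downsample(v: Volume, factors) -> Volume:
    """Down-sample a volume by arithmetic block averaging.

    Each output voxel is the mean of its ``fx x fy x fz`` input block; spacing
    is multiplied by the factors and the origin is shifted to the center of
    the first block so voxel centers stay physically aligned.  Trailing
    remainder voxels are dropped (see :func:`downsampled_dims`).
    """
    fx, fy, fz = (int(f) for f in factors)
    nx, ny, nz = downsampled_dims(v.dims, (fx, fy, fz))
    block = v.data[: nx * fx, : ny * fy, : nz * fz]
    # reduce each block over one flattened axis, in the block's own C order,
    # so the result is bit-identical to averaging the extracted block
    out = (
        block.reshape(nx, fx, ny, fy, nz, fz)
        .transpose(0, 2, 4, 1, 3, 5)
        .reshape(nx, ny, nz, fx * fy * fz)
        .mean(axis=-1)
    )
    sx, sy, sz = v.spacing
    new_origin = (
        v.origin[0] + (fx - 1) / 2 * sx,
        v.origin[1] + (fy - 1) / 2 * sy,
        v.origin[2] + (fz - 1) / 2 * sz,
    )
    return Volume(
        data=out,
        spacing=(sx * fx, sy * fy, sz * fz),
        origin=new_origin,
        downsample_factors=tuple(
            f0 * f for f0, f in zip(v.downsample_factors, (fx, fy, fz))
        ),
    )


# Portable binary fixture container: a .npz archive with an explicit header
# (dims, spacing, origin, factors, dtype all recoverable losslessly).

def write_fixture(v: Volume, path) -> None:
    """Write a volume to a portable binary fixture file (lossless)."""
    np.savez(
        path,
        data=v.data,
        spacing=np.asarray(v.spacing, dtype=np.float64),
        origin=np.asarray(v.origin, dtype=np.float64),
        downsample_factors=np.asarray(v.downsample_factors, dtype=np.int64),
    )


def read_fixture(path) -> Volume:
    """Read a volume fixture written by :func:`write_fixture`."""
    try:
        with np.load(path) as npz:
            return Volume(
                data=npz["data"],
                spacing=tuple(npz["spacing"]),
                origin=tuple(npz["origin"]),
                downsample_factors=tuple(npz["downsample_factors"]),
            )
    except (zipfile.BadZipFile, OSError, KeyError, ValueError) as exc:
        raise ValueError(f"corrupt or truncated volume fixture {path!r}: {exc}") from exc
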