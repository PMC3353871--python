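"""The synchronized 3D cursor and its orthogonal cross-sections.

One cursor per session indicates the same position in the 3D rendering and
in the three 2D cross-sections; all slicing, picking and marking flows
through it.  Sub-voxel positions are allowed (slices interpolate
trilinearly), which is what makes refinement of extremal points finer than
the grid possible.  Slices are aligned with the volume's major axes, not
with the rotated view.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .volume import Volume

__all__ = ["Cursor3D", "SliceSet", "init_cursor", "move_cursor", "extract_slices", "save_slice_png"]

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass
class Cursor3D:
    """A continuous world position clamped to the volume's voxel-center range."""

    volume: Volume
    position: np.ndarray

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float).copy()
        self._clamp()

    def _clamp(self):
        np.clip(self.position, self.volume.bounds_lo, self.volume.bounds_hi, out=self.position)

    @property
    def voxel_index(self) -> tuple[int, int, int]:
        """Nearest voxel (i, j, k) = round((position - origin) / spacing)."""
        idx = np.rint(self.volume.world_to_index(self.position)).astype(int)
        return tuple(int(i) for i in idx)

    def set_position(self, position) -> "Cursor3D":
        """Move the cursor to a world position (clamped); returns self."""
        self.position = np.asarray(position, dtype=float).copy()
        self._clamp()
        return self


def init_cursor(v: Volume) -> Cursor3D:
    """Cursor at the center of the volume (midpoint of the voxel-center range)."""
    return Cursor3D(volume=v, position=v.center)


def move_cursor(c: Cursor3D, axis: str, delta_voxels: float) -> Cursor3D:
    """Shift the cursor by ``delta_voxels * spacing`` along a volume axis.

    Fractional steps are allowed; the position is clamped to the volume
    bounds.  Mutates and returns the same cursor (one cursor per session).
    """
    ax = _AXES[axis]
    c.position[ax] += float(delta_voxels) * c.volume.spacing[ax]
    c._clamp()
    return c


@dataclass
class SliceSet:
    """The three orthogonal cross-sections through the cursor.

    ``yz[j, k]``, ``xz[i, k]``, ``xy[i, j]`` index the in-plane volume axes;
    ``cursor_index`` is the cursor's fractional voxel index, giving its
    in-plane location in each slice.
    """

    yz: np.ndarray
    xz: np.ndarray
    xy: np.ndarray
    cursor_index: np.ndarray


def extract_slices(v: Volume, c: Cursor3D) -> SliceSet:
    """The three axis-aligned planes through the cursor position.

    Trilinear interpolation handles sub-voxel cursor positions; at integer
    voxel positions each slice equals the raw grid plane.  Deterministic:
    the same cursor position always yields bit-identical slices.
    """
    idx = v.world_to_index(c.position)
    nx, ny, nz = v.dims

    def plane(fixed_axis, n_a, n_b, ax_a, ax_b):
        A, B = np.meshgrid(np.arange(n_a, dtype=float), np.arange(n_b, dtype=float), indexing="ij")
        coords = np.zeros((3, A.size))
        coords[fixed_axis] = idx[fixed_axis]
        coords[ax_a] = A.ravel()
        coords[ax_b] = B.ravel()
        return map_coordinates(v.data, coords, order=1, mode="nearest").reshape(n_a, n_b)

    return SliceSet(
        yz=plane(0, ny, nz, 1, 2),
        xz=plane(1, nx, nz, 0, 2),
        xy=plane(2, nx, ny, 0, 1),
        cursor_index=idx,
    )


def save_slice_png(slice2d, path, cursor_ab=None, crosshair=True):
    """Write a slice as 8-bit grey PNG, optionally burning in a red crosshair.

    ``cursor_ab`` is the cursor's (row-axis, column-axis) in-plane index.
    Intensities are min-max scaled over the slice.
    """
    import imageio.v3 as iio

    arr = np.asarray(slice2d, dtype=float)
    lo, hi = arr.min(), arr.max()
    grey = np.zeros_like(arr) if hi == lo else (arr - lo) / (hi - lo)
    rgb = np.repeat((grey * 255).astype(np.uint8)[:, :, None], 3, axis=2)
    if crosshair and cursor_ab is not None:
        a = int(round(cursor_ab[0]))
        b = int(round(cursor_ab[1]))
        if 0 <= a < rgb.shape[0]:
            rgb[a, :] = [255, 0, 0]
        if 0 <= b < rgb.shape[1]:
            rgb[:, b] = [255, 0, 0]
    iio.imwrite(path, rgb)
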