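"""Reading stacks of single-frame DICOM slice files into a :class:`~voxmark.volume.Volume`.

Micro-CT acquisitions arrive as one DICOM file per axial slice.  Slices are
sorted into anatomical order by instance number when present, else by the
slice-position attribute, else by filename, so a shuffled directory listing
loads identically.  Rescale slope/intercept are applied when present and
intensities are kept as floating point.

Gantry tilt, multi-frame/enhanced DICOM and non-axial acquisitions are out
of scope.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pydicom

from .volume import Volume

__all__ = ["read_dicom_stack"]

log = logging.getLogger(__name__)


def _sort_key(ds, path):
    if getattr(ds, "InstanceNumber", None) is not None:
        return (0, int(ds.InstanceNumber), str(path))
    ipp = getattr(ds, "ImagePositionPatient", None)
    if ipp is not None and len(ipp) == 3:
        return (1, float(ipp[2]), str(path))
    return (2, 0, str(path))


def _slice_spacing(datasets, spacing_override):
    """z spacing: explicit attribute, else inter-slice position difference."""
    ds0 = datasets[0]
    for attr in ("SpacingBetweenSlices", "SliceThickness"):
        val = getattr(ds0, attr, None)
        if val is not None and float(val) > 0:
            return float(val)
    if len(datasets) >= 2:
        p0 = getattr(datasets[0], "ImagePositionPatient", None)
        p1 = getattr(datasets[1], "ImagePositionPatient", None)
        if p0 is not None and p1 is not None:
            dz = abs(float(p1[2]) - float(p0[2]))
            if dz > 0:
                return dz
    if spacing_override is not None:
        return float(spacing_override[2])
    raise ValueError(
        "slice spacing missing from DICOM attributes "
        "(SpacingBetweenSlices / SliceThickness / ImagePositionPatient); "
        "supply spacing_override=(sx, sy, sz)"
    )


def read_dicom_stack(file_paths, subset=None, spacing_override=None) -> Volume:
    """Load an ordered stack of DICOM slice files (or a subset) into a Volume.

    Parameters
    ----------
    file_paths : sequence of path
        Single-frame DICOM slice files; order is irrelevant (slices are
        sorted by instance number / slice position / filename).
    subset : iterable of int, optional
        Slice indices (into the *sorted* stack, 0-based) to keep; e.g.
        ``range(4, 12)`` keeps slices 4..11.
    spacing_override : (sx, sy, sz), optional
        Fallback voxel spacing used when the DICOM attributes are absent.

    Returns
    -------
    Volume
        dims = (columns, rows, n_selected_slices); intensities preserved
        losslessly as stored values (rescale slope/intercept applied).
    """
    paths = [Path(p) for p in file_paths]
    if not paths:
        raise ValueError("empty DICOM file list")
    datasets = []
    for p in paths:
        if not p.exists():
            raise FileNotFoundError(p)
        datasets.append((pydicom.dcmread(p), p))

    datasets.sort(key=lambda dp: _sort_key(*dp))
    rows0, cols0 = int(datasets[0][0].Rows), int(datasets[0][0].Columns)
    for ds, p in datasets:
        if (int(ds.Rows), int(ds.Columns)) != (rows0, cols0):
            raise ValueError(
                f"inconsistent in-plane dims: {p} is {int(ds.Rows)}x{int(ds.Columns)}, "
                f"expected {rows0}x{cols0}"
            )

    if subset is not None:
        indices = sorted(set(int(i) for i in subset))
        if not indices:
            raise ValueError("empty slice subset")
        if indices[0] < 0 or indices[-1] >= len(datasets):
            raise IndexError(
                f"subset indices {indices[0]}..{indices[-1]} outside stack of "
                f"{len(datasets)} slices"
            )
        datasets = [datasets[i] for i in indices]

    dsets = [ds for ds, _ in datasets]

    pixel_spacing = getattr(dsets[0], "PixelSpacing", None)
    if pixel_spacing is not None:
        sy, sx = float(pixel_spacing[0]), float(pixel_spacing[1])  # [row, col]
    elif spacing_override is not None:
        sx, sy = float(spacing_override[0]), float(spacing_override[1])
    else:
        raise ValueError(
            "PixelSpacing missing from DICOM attributes; "
            "supply spacing_override=(sx, sy, sz)"
        )
    sz = _slice_spacing(dsets, spacing_override)

    slices = []
    for ds in dsets:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0) or 1.0)
        intercept = float(getattr(ds, "RescaleIntercept", 0.0) or 0.0)
        if slope != 1.0 or intercept != 0.0:
            arr = arr * slope + intercept
        # pixel_array is (rows, cols); transpose to data[x=col, y=row]
        slices.append(arr.T)
    data = np.stack(slices, axis=-1)

    ipp = getattr(dsets[0], "ImagePositionPatient", None)
    origin = tuple(float(c) for c in ipp) if ipp is not None else (0.0, 0.0, 0.0)

    log.info("loaded %d DICOM slices -> dims %s", len(dsets), data.shape)
    return Volume(data=data, spacing=(sx, sy, sz), origin=origin)
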