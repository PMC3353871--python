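"""Synthetic micro-CT-like phantoms with analytically known geometry.

Every phantom emulates the structure of a skull CT: a bright shell
(bone-like) around a darker interior (tissue/air), optionally nested
(multilayered structures such as fish skulls, where inner surfaces sit
beneath outer ones) and optionally degraded with additive Gaussian noise
(emulating e.g. specimens fixed in unbuffered formalin).  Rasterization is
at voxel centers with no anti-aliasing by default, so brute-force oracles
over voxel centers are exact; an anti-aliased mode exists for smoother
renderings.

Each generated phantom comes with ground truth: named extremal world points
(the ±x/±y/±z surface extrema of each shell — the analogues of
"anterior-most" / "dorsal-most" landmarks) and, for the bilateral phantom,
exact left/right landmark pairs plus the symmetry plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .volume import Volume

__all__ = ["PhantomSpec", "generate", "write_dicom_fixture", "write_ground_truth"]

KINDS = ("solid_sphere", "spherical_shell", "two_shell", "mirror_blobs")


@dataclass
class PhantomSpec:
    """Parameters of a synthetic phantom.

    Intensities are ordered ``background < soft < bone`` (stored-value
    units); ``noise_sigma`` is the standard deviation of additive Gaussian
    noise, reproducible from ``rng_seed``.  Geometry parameters are in world
    units.  Defaults give a 32^3, unit-spacing grid whose structures fit
    comfortably inside the bounds.
    """

    kind: str = "spherical_shell"
    dims: tuple[int, int, int] = (32, 32, 32)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    radius: float = 12.0           # outer radius (sphere/shell) or blob radius
    inner_radius: float = 6.0      # inner shell outer radius (two_shell)
    shell_thickness: float = 2.0
    blob_offset: float = 8.0       # mirror_blobs: center distance from midplane
    intensities: tuple[float, float, float] = (0.0, 30.0, 100.0)  # bg, soft, bone
    noise_sigma: float = 0.0
    rng_seed: int = 0
    antialias: bool = False

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown phantom kind {self.kind!r}; choose from {KINDS}")
        bg, soft, bone = self.intensities
        if not (bg < soft < bone):
            raise ValueError("intensities must be ordered background < soft < bone")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def _voxel_center_grid(spec: PhantomSpec):
    nx, ny, nz = spec.dims
    sx, sy, sz = spec.spacing
    ox, oy, oz = spec.origin
    x = ox + sx * np.arange(nx)
    y = oy + sy * np.arange(ny)
    z = oz + sz * np.arange(nz)
    return np.meshgrid(x, y, z, indexing="ij")


def _center(spec: PhantomSpec) -> np.ndarray:
    d = np.asarray(spec.dims, dtype=float)
    return np.asarray(spec.origin) + (d - 1) / 2 * np.asarray(spec.spacing)


def _mirror_center_x(spec: PhantomSpec) -> float:
    # midplane through the grid's own mirror axis: i <-> nx-1-i
    return spec.origin[0] + (spec.dims[0] - 1) / 2 * spec.spacing[0]


def _radial_field(spec, center, rule):
    """Fill intensities from distance-to-center and an (lo, hi, value) rule list.

    Each rule assigns ``value`` where ``lo <= |p - center| <= hi`` (later
    rules win on shared boundaries).  With ``antialias`` each voxel is
    supersampled 2x2x2 and the coverage averaged.
    """
    bg = spec.intensities[0]
    X, Y, Z = _voxel_center_grid(spec)

    def classify(x, y, z):
        d = np.sqrt((x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2)
        sub = np.full(spec.dims, bg, dtype=float)
        for lo, hi, val in rule:
            sub[(d >= lo) & (d <= hi)] = val
        return sub

    if not spec.antialias:
        return classify(X, Y, Z)
    acc = np.zeros(spec.dims, dtype=float)
    for dx in (-0.25, 0.25):
        for dy in (-0.25, 0.25):
            for dz in (-0.25, 0.25):
                acc += classify(
                    X + dx * spec.spacing[0],
                    Y + dy * spec.spacing[1],
                    Z + dz * spec.spacing[2],
                )
    return acc / 8.0


def _extrema(name_prefix, center, r, spec):
    """Surface extremal points of a sphere of radius r about center."""
    c = np.asarray(center, dtype=float)
    return {
        f"{name_prefix}_xmin": c - [r, 0, 0],
        f"{name_prefix}_xmax": c + [r, 0, 0],
        f"{name_prefix}_ymin": c - [0, r, 0],
        f"{name_prefix}_ymax": c + [0, r, 0],
        f"{name_prefix}_zmin": c - [0, 0, r],
        f"{name_prefix}_zmax": c + [0, 0, r],
    }


def generate(spec: PhantomSpec) -> tuple[Volume, dict]:
    """Rasterize a phantom and return it with its ground-truth landmarks.

    Returns
    -------
    (Volume, dict)
        The ground-truth dict maps landmark names to world points (ndarray);
        for ``mirror_blobs`` it additionally carries ``"pairs"`` (list of
        (left_name, right_name)) and ``"plane_points"`` (three points on the
        symmetry plane).
    """
    center = _center(spec)
    bg, soft, bone = spec.intensities
    lo_w = np.asarray(spec.origin, dtype=float)
    hi_w = lo_w + (np.asarray(spec.dims) - 1) * np.asarray(spec.spacing)

    def check_inside(c, r):
        c = np.asarray(c, dtype=float)
        if np.any(c - r < lo_w) or np.any(c + r > hi_w):
            raise ValueError(
                f"phantom geometry (center {tuple(c)}, radius {r}) exceeds volume "
                f"bounds {tuple(lo_w)}..{tuple(hi_w)}"
            )

    truth: dict = {}
    X, Y, Z = _voxel_center_grid(spec)

    if spec.kind in ("solid_sphere", "spherical_shell", "two_shell"):
        check_inside(center, spec.radius)
        if spec.kind == "solid_sphere":
            rule = [(0.0, spec.radius, bone)]
        elif spec.kind == "spherical_shell":
            rule = [
                (0.0, spec.radius - spec.shell_thickness, soft),
                (spec.radius - spec.shell_thickness, spec.radius, bone),
            ]
        else:  # two_shell: nested bone shells with soft tissue between
            if spec.inner_radius >= spec.radius - spec.shell_thickness:
                raise ValueError("inner shell must nest strictly inside the outer shell")
            rule = [
                (0.0, spec.inner_radius - spec.shell_thickness, soft),
                (spec.inner_radius - spec.shell_thickness, spec.inner_radius, bone),
                (spec.inner_radius, spec.radius - spec.shell_thickness, soft),
                (spec.radius - spec.shell_thickness, spec.radius, bone),
            ]
        data = _radial_field(spec, center, rule)
        truth.update(_extrema("outer", center, spec.radius, spec))
        if spec.kind == "two_shell":
            truth.update(_extrema("inner", center, spec.inner_radius, spec))
        truth["center"] = center.copy()

    else:  # mirror_blobs: two bone spheres exactly mirrored about x midplane
        cx = _mirror_center_x(spec)
        cl = np.array([cx - spec.blob_offset, center[1], center[2]])
        cr = np.array([cx + spec.blob_offset, center[1], center[2]])
        check_inside(cl, spec.radius)
        check_inside(cr, spec.radius)
        dl = np.sqrt((X - cl[0]) ** 2 + (Y - cl[1]) ** 2 + (Z - cl[2]) ** 2)
        dr = np.sqrt((X - cr[0]) ** 2 + (Y - cr[1]) ** 2 + (Z - cr[2]) ** 2)
        data = np.full(spec.dims, bg, dtype=float)
        data[dl <= spec.radius] = bone
        data[dr <= spec.radius] = bone
        r = spec.radius
        truth.update(
            {
                "left_tip": cl - [r, 0, 0],   # outermost point of the left blob
                "right_tip": cr + [r, 0, 0],
                "left_top": cl + [0, r, 0],
                "right_top": cr + [0, r, 0],
                "left_front": cl - [0, 0, r],
                "right_front": cr - [0, 0, r],
                "left_center": cl,
                "right_center": cr,
            }
        )
        truth["pairs"] = [
            ("left_tip", "right_tip"),
            ("left_top", "right_top"),
            ("left_front", "right_front"),
            ("left_center", "right_center"),
        ]
        truth["plane_points"] = [
            np.array([cx, center[1] - 1.0, center[2]]),
            np.array([cx, center[1] + 1.0, center[2]]),
            np.array([cx, center[1], center[2] + 1.0]),
        ]

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.rng_seed)
        data = data + rng.normal(0.0, spec.noise_sigma, size=data.shape)

    vol = Volume(data=data, spacing=spec.spacing, origin=spec.origin)
    return vol, truth


def write_dicom_fixture(v: Volume, directory, series_description="synthetic phantom") -> list[Path]:
    """Write one single-frame DICOM file per z-slice (test fixture writer).

    Intensities are rounded and clipped to uint16; spacing, position and
    instance attributes are set consistently so
    :func:`voxmark.dicomio.read_dicom_stack` recovers the grid exactly
    (for integer-valued volumes in [0, 65535]).  Not for clinical use.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    nx, ny, nz = v.dims
    sx, sy, sz = v.spacing
    series_uid = generate_uid()
    study_uid = generate_uid()
    paths = []
    for k in range(nz):
        arr = np.round(v.data[:, :, k].T)  # (rows, cols)
        arr = np.clip(arr, 0, 65535).astype(np.uint16)

        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian

        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.Modality = "CT"
        ds.SeriesDescription = series_description
        ds.PatientName = "synthetic^phantom"
        ds.PatientID = "SYNTH"
        ds.InstanceNumber = k + 1
        ds.ImagePositionPatient = [float(v.origin[0]), float(v.origin[1]), float(v.origin[2] + k * sz)]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [sy, sx]  # [row spacing, column spacing]
        ds.SliceThickness = sz
        ds.SpacingBetweenSlices = sz
        ds.Rows, ds.Columns = ny, nx
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.RescaleSlope = 1
        ds.RescaleIntercept = 0
        ds.PixelData = arr.tobytes()

        path = directory / f"slice_{k:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths


def write_ground_truth(truth: dict, path) -> None:
    """Write the ground-truth landmark dict as a plain-text file."""
    with open(path, "w", encoding="utf-8") as fh:
        for name, val in truth.items():
            if name == "pairs":
                for left, right in val:
                    fh.write(f"pair {left} {right}\n")
            elif name == "plane_points":
                for p in val:
                    fh.write(f"plane_point {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
            else:
                p = np.asarray(val, dtype=float)
                fh.write(f"point {name} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
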