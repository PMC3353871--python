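"""Landmark lists, symmetry maps, coordinate export and the precision statistic.

Landmark definitions come from a plain text file of running numbers and
descriptions; an optional symmetry map names the landmarks lying on the
sagittal (median) plane and the left/right pairs, enabling linking lines —
and their computational counterpart, a reflection check — between
corresponding landmarks.  Marked coordinates export to the TPS and NTSYS
plain-text dialects consumed by downstream morphometrics software (IMP
series, MorphoJ, R packages); both dialects ship with readers so round
trips are testable bit-for-bit.

File grammar (UTF-8, ``#`` comments allowed):

* landmark list — one per line: ``<number> <description>`` with an optional
  trailing ``type=1|2|3`` token (Bookstein landmark types: 1 = tissue
  juxtaposition, 2 = curvature maximum, 3 = extremal point relative to a
  geometry); numbers must be contiguous from 1.
* symmetry map — lines ``midline <n> [<n> ...]`` and ``pair <left> <right>``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LandmarkDef",
    "LandmarkSet",
    "SymmetryMap",
    "load_landmark_list",
    "load_symmetry_map",
    "mark_point",
    "jump_stored",
    "export_tps",
    "read_tps",
    "export_ntsys",
    "read_ntsys",
    "precision_stats",
    "symmetry_deviation",
]

log = logging.getLogger(__name__)

_TYPE_TOKEN = re.compile(r"^type=([123])$")


@dataclass(frozen=True)
class LandmarkDef:
    """One landmark definition: running number, free-text description,
    optional Bookstein type (1/2/3) and role (plane/axis anchor or regular)."""

    number: int
    description: str
    lm_type: int | None = None
    role: str = "regular"


@dataclass
class LandmarkSet:
    """Ordered landmark definitions plus their marked world coordinates.

    ``coords[number]`` is None until the landmark is marked; coordinate
    order always follows definition order.
    """

    defs: list[LandmarkDef]
    coords: dict[int, np.ndarray | None] = field(default_factory=dict)
    specimen_id: str = "specimen"

    def __post_init__(self):
        numbers = [d.number for d in self.defs]
        if numbers != list(range(1, len(numbers) + 1)):
            raise ValueError(f"landmark numbers must be contiguous from 1, got {numbers}")
        for n in numbers:
            self.coords.setdefault(n, None)

    @property
    def numbers(self) -> list[int]:
        return [d.number for d in self.defs]

    def unmarked(self) -> list[int]:
        return [n for n in self.numbers if self.coords.get(n) is None]

    def coord_matrix(self) -> np.ndarray:
        """(n, 3) marked coordinates in definition order; raises if incomplete."""
        missing = self.unmarked()
        if missing:
            raise ValueError(f"unmarked landmarks: {missing}")
        return np.array([self.coords[n] for n in self.numbers], dtype=float)


@dataclass
class SymmetryMap:
    """Midline landmarks (on the sagittal plane) and left/right pairs."""

    midline: set[int]
    pairs: list[tuple[int, int]]

    def linking_lines(self, lm: LandmarkSet) -> list[tuple[np.ndarray, np.ndarray]]:
        """End points of the lines linking corresponding paired landmarks."""
        out = []
        for left, right in self.pairs:
            a, b = lm.coords.get(left), lm.coords.get(right)
            if a is not None and b is not None:
                out.append((a, b))
        return out


def _content_lines(path):
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if line and not line.startswith("#"):
                yield lineno, line


def load_landmark_list(path) -> list[LandmarkDef]:
    """Parse a landmark definition file (running numbers + descriptions)."""
    defs = []
    for lineno, line in _content_lines(path):
        parts = line.split(None, 1)
        if not parts[0].isdigit():
            raise ValueError(f"{path}:{lineno}: expected a landmark number, got {parts[0]!r}")
        number = int(parts[0])
        desc = parts[1].strip() if len(parts) > 1 else ""
        lm_type = None
        tokens = desc.split()
        if tokens and (m := _TYPE_TOKEN.match(tokens[-1])):
            lm_type = int(m.group(1))
            desc = " ".join(tokens[:-1])
        expected = len(defs) + 1
        if number != expected:
            raise ValueError(
                f"{path}:{lineno}: landmark numbers must run 1,2,...; "
                f"expected {expected}, got {number}"
            )
        defs.append(LandmarkDef(number=number, description=desc, lm_type=lm_type))
    if not defs:
        raise ValueError(f"{path}: empty landmark list")
    return defs


def load_symmetry_map(path, defs: list[LandmarkDef]) -> SymmetryMap:
    """Parse a symmetry map and validate it against the landmark definitions."""
    known = {d.number for d in defs}
    midline: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for lineno, line in _content_lines(path):
        tokens = line.split()
        kind, args = tokens[0].lower(), tokens[1:]
        if kind == "midline":
            nums = [int(t) for t in args]
        elif kind == "pair":
            if len(args) != 2:
                raise ValueError(f"{path}:{lineno}: pair needs exactly two landmark numbers")
            nums = [int(t) for t in args]
            if nums[0] == nums[1]:
                raise ValueError(f"{path}:{lineno}: a landmark cannot be paired with itself")
        else:
            raise ValueError(f"{path}:{lineno}: unknown directive {kind!r}")
        for n in nums:
            if n not in known:
                raise ValueError(f"{path}:{lineno}: unknown landmark number {n}")
        if kind == "midline":
            midline.update(nums)
        else:
            pairs.append((nums[0], nums[1]))

    paired = [n for pr in pairs for n in pr]
    if len(paired) != len(set(paired)):
        raise ValueError(f"{path}: a landmark appears in more than one pair")
    both = midline & set(paired)
    if both:
        raise ValueError(f"{path}: landmarks {sorted(both)} are both midline and paired")
    return SymmetryMap(midline=midline, pairs=pairs)


def mark_point(lm: LandmarkSet, number: int, cursor) -> LandmarkSet:
    """Store the cursor's coordinates for a landmark (re-marking overwrites)."""
    if number not in lm.coords:
        raise KeyError(f"unknown landmark number {number}")
    if lm.coords[number] is not None:
        log.info("re-marking landmark %d (was %s)", number, lm.coords[number])
    lm.coords[number] = np.asarray(cursor.position, dtype=float).copy()
    return lm


def jump_stored(lm: LandmarkSet, number: int, cursor):
    """Move the cursor to a stored landmark; raises if it is unmarked."""
    if number not in lm.coords:
        raise KeyError(f"unknown landmark number {number}")
    p = lm.coords[number]
    if p is None:
        raise ValueError(f"landmark {number} has not been marked yet")
    cursor.set_position(p)
    return cursor


# ---------------------------------------------------------------------------
# TPS / NTSYS dialects (pinned; readers bundled for round-trip checks)

def export_tps(lm: LandmarkSet, path, strict=True, spacing=None) -> None:
    """Write a 3D TPS file: ``LM3=<n>`` header, ``x y z`` rows, ``ID=`` trailer.

    Coordinates are world units (what downstream shape analysis consumes);
    pass ``spacing`` to write voxel units instead.  ``strict`` refuses
    partially marked sets; otherwise unmarked landmarks are skipped.
    """
    missing = lm.unmarked()
    if missing and strict:
        raise ValueError(f"cannot export: unmarked landmarks {missing}")
    marked = [n for n in lm.numbers if lm.coords[n] is not None]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"LM3={len(marked)}\n")
        for n in marked:
            p = lm.coords[n]
            if spacing is not None:
                p = np.asarray(p) / np.asarray(spacing, dtype=float)
            fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
        fh.write(f"ID={lm.specimen_id}\n")


def read_tps(path):
    """Read a TPS file written by :func:`export_tps`.

    Returns ``(coords (n, 3), specimen_id)``.
    """
    coords = []
    specimen_id = ""
    n_expected = None
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.upper().startswith("LM3="):
                n_expected = int(line.split("=", 1)[1])
            elif line.upper().startswith("ID="):
                specimen_id = line.split("=", 1)[1]
            else:
                vals = [float(x) for x in line.split()]
                if len(vals) != 3:
                    raise ValueError(f"{path}:{lineno}: expected 3 coordinates, got {len(vals)}")
                coords.append(vals)
    arr = np.asarray(coords, dtype=float).reshape(-1, 3)
    if n_expected is not None and n_expected != len(arr):
        raise ValueError(f"{path}: header says {n_expected} landmarks, found {len(arr)}")
    return arr, specimen_id


def export_ntsys(sets: list[LandmarkSet], path) -> None:
    """Write an NTSYS rectangular coordinate matrix.

    Header ``1 <n_specimens> <3*n_landmarks> 0``, then per specimen a row
    label line followed by the flattened ``x1 y1 z1 x2 y2 z2 ...`` row.
    All sets must share the same landmark definitions and be fully marked.
    """
    if not sets:
        raise ValueError("no landmark sets to export")
    ref = [d.number for d in sets[0].defs]
    for s in sets[1:]:
        if [d.number for d in s.defs] != ref:
            raise ValueError("all specimens must share the same landmark definitions")
    mats = [s.coord_matrix() for s in sets]
    n_cols = 3 * len(ref)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"1 {len(sets)} {n_cols} 0\n")
        for s, mat in zip(sets, mats):
            fh.write(f"{s.specimen_id}\n")
            fh.write(" ".join(f"{x:.6f}" for x in mat.ravel()) + "\n")


def read_ntsys(path):
    """Read an NTSYS matrix written by :func:`export_ntsys`.

    Returns ``(coords (n_specimens, n_landmarks, 3), labels)``.
    """
    with open(path, encoding="utf-8") as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty NTSYS file")
    header = lines[0].split()
    if len(header) != 4 or header[0] != "1":
        raise ValueError(f"{path}: unrecognized NTSYS header {lines[0]!r}")
    n_spec, n_cols = int(header[1]), int(header[2])
    if n_cols % 3:
        raise ValueError(f"{path}: column count {n_cols} is not a multiple of 3")
    labels, rows = [], []
    body = lines[1:]
    if len(body) != 2 * n_spec:
        raise ValueError(f"{path}: expected {2 * n_spec} body lines, found {len(body)}")
    for i in range(n_spec):
        labels.append(body[2 * i])
        vals = [float(x) for x in body[2 * i + 1].split()]
        if len(vals) != n_cols:
            raise ValueError(f"{path}: row {labels[-1]!r} has {len(vals)} values, expected {n_cols}")
        rows.append(vals)
    coords = np.asarray(rows, dtype=float).reshape(n_spec, n_cols // 3, 3)
    return coords, labels


# ---------------------------------------------------------------------------
# repeatability statistic

def precision_stats(repeats: list[LandmarkSet], spacing, defs=None) -> dict:
    """Distance-from-median repeatability, pooled by landmark type.

    For each landmark the coordinate-wise median across repeats is taken,
    then each repeat's Euclidean distance to that median, measured in voxel
    units (coordinates divided by the volume spacing).  Distances are
    grouped by Bookstein landmark type; untyped landmarks pool under None.

    Returns ``{lm_type: {"distances": ndarray, "median": float,
    "q1": float, "q3": float}}`` plus the per-landmark medians under the
    ``"per_landmark_median"`` key ((n_landmarks, 3), voxel units).
    """
    if len(repeats) < 2:
        raise ValueError("need at least two repeats")
    if defs is None:
        defs = repeats[0].defs
    spacing = np.asarray(spacing, dtype=float)
    mats = np.stack([r.coord_matrix() / spacing for r in repeats])  # (R, n, 3)
    med = np.median(mats, axis=0)  # coordinate-wise median, (n, 3)
    dists = np.linalg.norm(mats - med[None], axis=2)  # (R, n)

    out: dict = {"per_landmark_median": med}
    by_type: dict = {}
    for col, d in enumerate(defs):
        by_type.setdefault(d.lm_type, []).append(dists[:, col])
    for lm_type, cols in by_type.items():
        pooled = np.concatenate(cols)
        out[lm_type] = {
            "distances": pooled,
            "median": float(np.median(pooled)),
            "q1": float(np.percentile(pooled, 25)),
            "q3": float(np.percentile(pooled, 75)),
        }
    return out


def symmetry_deviation(lm: LandmarkSet, sym: SymmetryMap, plane) -> dict[tuple[int, int], float]:
    """How far each paired landmark lands from its partner under reflection.

    The computational version of the visual linking-line check: for a
    perfectly symmetric specimen marked in the correct order, reflecting
    each left landmark through the sagittal plane lands on its right
    partner.  Returns per-pair distances (world units).
    """
    from .geometry import reflect_point

    out = {}
    for left, right in sym.pairs:
        a, b = lm.coords.get(left), lm.coords.get(right)
        if a is None or b is None:
            raise ValueError(f"pair ({left}, {right}) is not fully marked")
        out[(left, right)] = float(np.linalg.norm(reflect_point(plane, a) - b))
    return out
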