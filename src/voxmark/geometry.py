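"""Plane/axis geometry aids for bilaterally symmetric specimens.

A plane is defined by three landmarks (typically on the sagittal/median
plane of a bilaterally symmetric skull), an axis by two end points that may
or may not also serve as plane points.  The plane supports reflecting the
cursor onto the contralateral side; plane and axis together fix a viewing
frame so extremal landmarks can be digitized from precisely defined angles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .render import ViewState

__all__ = [
    "PlaneSpec",
    "AxisSpec",
    "plane_from_points",
    "axis_from_points",
    "reflect_point",
    "rotate_to_plane",
    "rotate_to_axis",
]

log = logging.getLogger(__name__)


def _unit(v):
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector has no direction")
    return v / n


@dataclass(frozen=True)
class PlaneSpec:
    """A plane through three non-collinear points.

    ``normal`` is the unit cross-product ``(p2-p1) x (p3-p1)`` (sign from
    the point order); ``offset`` is the signed distance of the world origin
    to the plane, so points p on the plane satisfy ``normal . p == offset``.
    """

    p1: np.ndarray
    p2: np.ndarray
    p3: np.ndarray
    normal: np.ndarray
    offset: float


@dataclass(frozen=True)
class AxisSpec:
    """An axis through two distinct end points; ``direction = unit(a2 - a1)``."""

    a1: np.ndarray
    a2: np.ndarray
    direction: np.ndarray


def plane_from_points(p1, p2, p3) -> PlaneSpec:
    """Construct the plane through three landmarks.

    Raises on degenerate input: coincident points are named, collinearity is
    detected by triangle area below ``1e-9 * scale^2``.
    """
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    pts = {"p1": p1, "p2": p2, "p3": p3}
    names = list(pts)
    for i in range(3):
        for j in range(i + 1, 3):
            if np.allclose(pts[names[i]], pts[names[j]]):
                raise ValueError(f"plane points {names[i]} and {names[j]} coincide")
    cross = np.cross(p2 - p1, p3 - p1)
    scale = max(np.linalg.norm(p2 - p1), np.linalg.norm(p3 - p1), np.linalg.norm(p3 - p2))
    if np.linalg.norm(cross) / 2 <= 1e-9 * scale**2:
        raise ValueError("plane points p1, p2, p3 are collinear")
    normal = cross / np.linalg.norm(cross)
    offset = float(normal @ p1)
    return PlaneSpec(p1=p1, p2=p2, p3=p3, normal=normal, offset=offset)


def axis_from_points(a1, a2) -> AxisSpec:
    """Construct the axis through two end points."""
    a1, a2 = np.asarray(a1, dtype=float), np.asarray(a2, dtype=float)
    if np.allclose(a1, a2):
        raise ValueError("axis end points coincide")
    return AxisSpec(a1=a1, a2=a2, direction=_unit(a2 - a1))


def reflect_point(plane: PlaneSpec, p) -> np.ndarray:
    """Mirror a point through the plane: ``p - 2 (n.p - offset) n``.

    An isometric involution, independent of the normal's sign; used to jump
    the cursor from a marked landmark to its contralateral partner.
    """
    p = np.asarray(p, dtype=float)
    return p - 2.0 * (plane.normal @ p - plane.offset) * plane.normal


def _orthonormalize(forward, up_hint):
    """Complete forward + up hint to a right-handed frame (right x up = forward)."""
    forward = _unit(forward)
    for cand in (up_hint, (0.0, 0.0, 1.0), (0.0, 1.0, 0.0)):
        up = np.asarray(cand, dtype=float)
        up = up - (up @ forward) * forward
        if np.linalg.norm(up) > 1e-9:
            up = up / np.linalg.norm(up)
            break
    else:  # pragma: no cover - two fallbacks cannot both be parallel to forward
        raise ValueError("cannot complete viewing frame")
    right = np.cross(up, forward)
    return right / np.linalg.norm(right), up, forward


def rotate_to_plane(view: ViewState, plane: PlaneSpec, flip_normal: bool = False) -> ViewState:
    """Return a view whose direction lies along the plane normal.

    The up vector is the previous up projected into the new view plane
    (minimal rotation), falling back to world z; the look-at center is
    preserved.  ``flip_normal`` views the plane from its other side.
    """
    n = -plane.normal if flip_normal else plane.normal
    right, up, forward = _orthonormalize(n, view.up)
    return replace(view, right=right, up=up, forward=forward)


def rotate_to_axis(
    view: ViewState, plane: PlaneSpec, axis: AxisSpec, flip_normal: bool = False
) -> ViewState:
    """View along the plane normal with the axis along the screen x-direction.

    The axis direction is projected into the view plane and becomes the
    ``right`` vector; raises when the axis is (numerically) parallel to the
    plane normal.
    """
    forward = _unit(-plane.normal if flip_normal else plane.normal)
    a = axis.direction
    a_proj = a - (a @ forward) * forward
    if np.linalg.norm(a_proj) < 1e-6:
        raise ValueError("axis is parallel to the plane normal; screen-x is undefined")
    right = a_proj / np.linalg.norm(a_proj)
    up = np.cross(forward, right)
    up = up / np.linalg.norm(up)
    return replace(view, right=right, up=up, forward=forward)
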