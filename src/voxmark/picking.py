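"""Threshold-based ray picking.

A pixel in the rendered view defines one orthographic world ray; the cursor
is placed on the first structure along that ray whose interpolated intensity
exceeds a user threshold.  On a skull scanned in a live specimen the ray
passes through air and soft tissue and lands on the first bony structure —
provided the threshold is set accordingly.  The threshold is always
explicit: the bone intensity of a CT scan is scanner- and
protocol-dependent, so no default is hard-coded.

The march step is deliberately fine (0.05 of the smallest voxel spacing):
a ray grazing a thin bony shell — the walls of a fish skull, say — can be
supra-threshold over a small fraction of a voxel, and a coarser march would
skip straight through it.  The hit is then refined by bisection between the
bracketing march samples, giving sub-voxel accuracy;
:func:`first_hit_fine_step` is a deliberately naive traversal at the same
density kept as an independent cross-check of the entry/exit and
refinement logic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .render import ViewState, ray_aabb
from .volume import Volume

__all__ = ["Ray", "screen_ray", "first_hit", "first_hit_fine_step", "pick"]

log = logging.getLogger(__name__)

#: march step for picking, as a fraction of the smallest voxel spacing;
#: fine enough to catch grazing crossings of shells ~a voxel thick
PICK_STEP_FACTOR = 0.05


@dataclass(frozen=True)
class Ray:
    """A world line: point on the image plane + unit direction (= view.forward)."""

    base: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "base", np.asarray(self.base, dtype=float))
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if abs(n - 1.0) > 1e-9:
            if n == 0:
                raise ValueError("ray direction must be nonzero")
            d = d / n
        object.__setattr__(self, "direction", d)

    def point_at(self, t: float) -> np.ndarray:
        return self.base + t * self.direction


def screen_ray(view: ViewState, pixel) -> Ray:
    """The orthographic world ray beneath an image pixel (col, row).

    ``base = center + (col - w/2)*pitch*right + (h/2 - row)*pitch*up``,
    direction = the viewing direction.  Fractional pixel coordinates are
    allowed; out-of-image pixels raise.
    """
    col, row = float(pixel[0]), float(pixel[1])
    w, h = view.image_size
    if not (0 <= col < w and 0 <= row < h):
        raise ValueError(f"pixel ({col}, {row}) outside image of size {w}x{h}")
    base = (
        view.center
        + (col - w / 2) * view.pixel_pitch * view.right
        + (h / 2 - row) * view.pixel_pitch * view.up
    )
    return Ray(base=base, direction=view.forward)


def _entry_exit(v: Volume, ray: Ray):
    t0, t1, miss = ray_aabb(ray.base[None, :], ray.direction, v.bounds_lo, v.bounds_hi)
    return float(t0[0]), float(t1[0]), bool(miss[0])


def first_hit(v: Volume, ray: Ray, threshold: float, step=None, refine_tol=1e-3):
    """First point along the ray whose interpolated intensity exceeds threshold.

    Marches from volume entry to exit at a fine fixed step
    (``PICK_STEP_FACTOR`` of the smallest voxel spacing by default) testing
    strict ``intensity > threshold``; the crossing is then refined by
    bisection between the bracketing samples down to ``refine_tol`` voxels
    along the ray.  Returns the world hit point, or None when the ray misses
    the volume or never exceeds the threshold (logged distinctly).
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if step is None:
        step = PICK_STEP_FACTOR * min(v.spacing)
    t_in, t_out, miss = _entry_exit(v, ray)
    if miss:
        log.debug("ray misses the volume bounding box")
        return None
    ts = np.arange(t_in, t_out + step, step)
    ts[-1] = min(ts[-1], t_out)
    pts = ray.base[None, :] + ts[:, None] * ray.direction
    vals = v.sample(pts)
    above = vals > threshold
    if not above.any():
        log.debug("ray entered the volume but never exceeded threshold %g", threshold)
        return None
    i = int(np.argmax(above))
    if i == 0:
        return ray.point_at(float(ts[0]))  # already supra-threshold at entry
    lo_t, hi_t = float(ts[i - 1]), float(ts[i])
    tol = refine_tol * min(v.spacing)
    while hi_t - lo_t > tol:
        mid = 0.5 * (lo_t + hi_t)
        if v.sample(ray.point_at(mid)) > threshold:
            hi_t = mid
        else:
            lo_t = mid
    return ray.point_at(hi_t)


def first_hit_fine_step(v: Volume, ray: Ray, threshold: float, step_factor=0.05):
    """Independent brute-force traversal at a very fine fixed step.

    Walks the ray at ``step_factor * min(spacing)`` (no bisection, no early
    bracketing) and returns the first supra-threshold sample point.  Slower
    than :func:`first_hit`; retained as a cross-check of the traversal
    logic.
    """
    t_in, t_out, miss = _entry_exit(v, ray)
    if miss:
        return None
    step = step_factor * min(v.spacing)
    t = t_in
    while t <= t_out:
        if v.sample(ray.point_at(t)) > threshold:
            return ray.point_at(t)
        t += step
    return None


def pick(session, pixel):
    """Move the session cursor to the first supra-threshold structure under a pixel.

    Composes :func:`screen_ray` and :func:`first_hit` with the session's view
    and threshold, then regenerates the orthogonal slices.  A miss leaves
    the cursor unchanged and emits a warning.
    """
    if session.threshold is None:
        raise ValueError("no picking threshold configured in the session")
    ray = screen_ray(session.view, pixel)
    hit = first_hit(session.volume, ray, session.threshold)
    if hit is None:
        log.warning("pick at pixel %s found no structure above threshold %g; cursor unchanged",
                    tuple(pixel), session.threshold)
        return session.cursor
    session.cursor.set_position(hit)
    session.refresh_slices()
    return session.cursor
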