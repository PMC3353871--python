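"""Scripted landmarking sessions.

A :class:`Session` replaces the original interactive workflow with a
deterministic command stream: load a volume, configure rendering, run
pick/move/mark sequences, manage the symmetry plane and axis, export
coordinates.  There is exactly one cursor per session — every slice, pick
and mark operation reads the same instance — and every state change is
appended to the session log, which suffices to regenerate all outputs
(replaying a log reproduces the exports byte for byte).

Script grammar: one command per line, whitespace-separated arguments,
``#`` comments and blank lines ignored.  The first invalid command aborts
with its line number and removes any partially written outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import cursor as cursor_mod
from . import dicomio, geometry, landmarks, picking, render, volume as volume_mod

__all__ = ["Session", "ScriptError", "run_script"]

log = logging.getLogger(__name__)


class ScriptError(Exception):
    """A session script command failed; carries the 1-based line number."""

    def __init__(self, lineno, command, message):
        self.lineno = lineno
        self.command = command
        super().__init__(f"line {lineno}: {command!r}: {message}")


@dataclass
class Session:
    """All mutable state of one landmarking session."""

    volume: volume_mod.Volume | None = None
    volume_source: str | None = None
    cursor: cursor_mod.Cursor3D | None = None
    view: render.ViewState | None = None
    tf: render.TransferFunction | None = None
    lights: render.LightSet | None = None
    base_colour: tuple = (1.0, 1.0, 1.0)
    landmark_set: landmarks.LandmarkSet | None = None
    symmetry: landmarks.SymmetryMap | None = None
    plane_points: list = field(default_factory=lambda: [None, None, None])  # PL1-3
    axis_points: list = field(default_factory=lambda: [None, None])         # A1-2
    plane: geometry.PlaneSpec | None = None
    axis: geometry.AxisSpec | None = None
    threshold: float | None = None
    commands: list = field(default_factory=list)
    slices: object = None

    # ---- state helpers -------------------------------------------------

    def _require(self, what):
        val = getattr(self, what)
        if val is None:
            names = {
                "volume": "no volume loaded",
                "cursor": "no volume loaded (cursor uninitialised)",
                "view": "no view configured",
                "landmark_set": "no landmark list loaded",
                "plane": "no plane defined (need three plane points)",
                "axis": "no axis defined (need two axis points)",
                "tf": "no transfer function configured",
            }
            raise ValueError(names.get(what, f"{what} not configured"))
        return val

    def set_volume(self, vol, source=None):
        self.volume = vol
        self.volume_source = source
        self.cursor = cursor_mod.init_cursor(vol)
        if self.view is None:
            self.view = render.ViewState.along_axis(vol, "z")
        else:
            from dataclasses import replace

            self.view = replace(self.view, center=vol.center)
        self.refresh_slices()

    def refresh_slices(self):
        if self.volume is not None and self.cursor is not None:
            self.slices = cursor_mod.extract_slices(self.volume, self.cursor)

    def _recompute_plane(self):
        """Eagerly rebuild the plane whenever an anchor changes (logged)."""
        if all(p is not None for p in self.plane_points):
            self.plane = geometry.plane_from_points(*self.plane_points)
            log.info("plane recomputed: normal %s", np.round(self.plane.normal, 6))
        else:
            self.plane = None

    def _recompute_axis(self):
        if all(p is not None for p in self.axis_points):
            self.axis = geometry.axis_from_points(*self.axis_points)
            log.info("axis recomputed: direction %s", np.round(self.axis.direction, 6))
        else:
            self.axis = None

    def _default_render_state(self):
        if self.tf is None:
            raise ValueError("no transfer function configured (use tf or render_config)")
        if self.lights is None:
            self.lights = render.LightSet.headlight(self._require("view"))

    # ---- command handlers ---------------------------------------------

    def cmd_load_fixture(self, path):
        self.set_volume(volume_mod.read_fixture(path), source=f"fixture:{path}")

    def cmd_load_dicom(self, directory):
        paths = sorted(Path(directory).glob("*.dcm"))
        self.set_volume(dicomio.read_dicom_stack(paths), source=f"dicom:{directory}")

    def cmd_downsample(self, fx, fy, fz):
        v = self._require("volume")
        self.set_volume(volume_mod.downsample(v, (int(fx), int(fy), int(fz))),
                        source=self.volume_source)

    def cmd_landmarks(self, path):
        defs = landmarks.load_landmark_list(path)
        self.landmark_set = landmarks.LandmarkSet(defs=defs)

    def cmd_symmetry(self, path):
        lm = self._require("landmark_set")
        self.symmetry = landmarks.load_symmetry_map(path, lm.defs)

    def cmd_specimen(self, specimen_id):
        self._require("landmark_set").specimen_id = specimen_id

    def cmd_threshold(self, value):
        self.threshold = float(value)

    def cmd_tf(self, low, high, max_opacity="1.0", gain="1.0", mode="surface"):
        self.tf = render.TransferFunction(
            float(low), float(high), float(max_opacity), float(gain), mode
        )

    def cmd_render_config(self, path):
        self.tf, self.lights, self.base_colour = render.load_render_config(path)

    def cmd_view(self, axis, w="64", h="64", pitch=None):
        v = self._require("volume")
        self.view = render.ViewState.along_axis(
            v, axis, image_size=(int(w), int(h)),
            pixel_pitch=None if pitch is None else float(pitch),
        )

    def cmd_render(self, out_path, algorithm="raycast"):
        v = self._require("volume")
        self._default_render_state()
        fn = {"raycast": render.render_raycast, "shearwarp": render.render_shearwarp}
        if algorithm not in fn:
            raise ValueError(f"unknown renderer {algorithm!r}")
        img = fn[algorithm](v, self._require("view"), self.tf, self.lights, self.base_colour)
        img.save(out_path)
        return [Path(out_path)]

    def cmd_slices(self, prefix, crosshair="crosshair"):
        v = self._require("volume")
        s = cursor_mod.extract_slices(v, self._require("cursor"))
        burn = crosshair != "plain"
        idx = s.cursor_index
        written = []
        for name, arr, ab in (
            ("yz", s.yz, (idx[1], idx[2])),
            ("xz", s.xz, (idx[0], idx[2])),
            ("xy", s.xy, (idx[0], idx[1])),
        ):
            path = Path(f"{prefix}_{name}.png")
            cursor_mod.save_slice_png(arr, path, cursor_ab=ab, crosshair=burn)
            written.append(path)
        return written

    def cmd_pick(self, col, row):
        self._require("view")
        picking.pick(self, (float(col), float(row)))

    def cmd_move(self, axis, delta):
        cursor_mod.move_cursor(self._require("cursor"), axis, float(delta))
        self.refresh_slices()

    def cmd_cursor(self, x, y, z):
        self._require("cursor").set_position((float(x), float(y), float(z)))
        self.refresh_slices()

    def cmd_mark(self, number):
        landmarks.mark_point(self._require("landmark_set"), int(number), self._require("cursor"))

    def cmd_jump(self, number):
        landmarks.jump_stored(self._require("landmark_set"), int(number), self._require("cursor"))
        self.refresh_slices()

    def cmd_plane_mark(self, which):
        i = int(which)
        if i not in (1, 2, 3):
            raise ValueError("plane point index must be 1, 2 or 3 (PL1-PL3)")
        self.plane_points[i - 1] = self._require("cursor").position.copy()
        self._recompute_plane()

    def cmd_plane_from_landmarks(self, n1, n2, n3):
        lm = self._require("landmark_set")
        pts = []
        for n in (int(n1), int(n2), int(n3)):
            if lm.coords.get(n) is None:
                raise ValueError(f"landmark {n} is not marked")
            pts.append(lm.coords[n].copy())
        self.plane_points = pts
        self._recompute_plane()

    def cmd_axis_mark(self, which):
        i = int(which)
        if i not in (1, 2):
            raise ValueError("axis point index must be 1 or 2 (A1-A2)")
        self.axis_points[i - 1] = self._require("cursor").position.copy()
        self._recompute_axis()

    def cmd_axis_from_landmarks(self, n1, n2):
        lm = self._require("landmark_set")
        pts = []
        for n in (int(n1), int(n2)):
            if lm.coords.get(n) is None:
                raise ValueError(f"landmark {n} is not marked")
            pts.append(lm.coords[n].copy())
        self.axis_points = pts
        self._recompute_axis()

    def cmd_reflect(self):
        c = self._require("cursor")
        c.set_position(geometry.reflect_point(self._require("plane"), c.position))
        self.refresh_slices()

    def cmd_rotate_plane(self, flip="noflip"):
        self.view = geometry.rotate_to_plane(
            self._require("view"), self._require("plane"), flip_normal=flip == "flip"
        )

    def cmd_rotate_axis(self, flip="noflip"):
        self.view = geometry.rotate_to_axis(
            self._require("view"), self._require("plane"), self._require("axis"),
            flip_normal=flip == "flip",
        )

    def cmd_export_tps(self, path, mode="strict"):
        lm = self._require("landmark_set")
        landmarks.export_tps(lm, path, strict=mode != "partial")
        return [Path(path)]

    def cmd_export_ntsys(self, path):
        lm = self._require("landmark_set")
        landmarks.export_ntsys([lm], path)
        return [Path(path)]

    # ---- execution -----------------------------------------------------

    def execute(self, command_line: str):
        """Run one command line; returns the list of files it wrote."""
        tokens = command_line.split()
        name, args = tokens[0], tokens[1:]
        handler = getattr(self, f"cmd_{name.replace('-', '_')}", None)
        if handler is None:
            raise ValueError(f"unknown command {name!r}")
        written = handler(*args)
        self.commands.append(command_line)
        return written or []

    # ---- persistence ---------------------------------------------------

    def save(self, path):
        """Write the session state (volume by reference) as JSON text."""
        def arr(a):
            return None if a is None else [float(x) for x in np.asarray(a).ravel()]

        state = {
            "volume_source": self.volume_source,
            "cursor": arr(None if self.cursor is None else self.cursor.position),
            "view": None
            if self.view is None
            else {
                "right": arr(self.view.right),
                "up": arr(self.view.up),
                "forward": arr(self.view.forward),
                "center": arr(self.view.center),
                "image_size": list(self.view.image_size),
                "pixel_pitch": self.view.pixel_pitch,
            },
            "threshold": self.threshold,
            "tf": None
            if self.tf is None
            else [self.tf.low_intensity, self.tf.high_intensity, self.tf.max_opacity,
                  self.tf.reflectivity_gain, self.tf.mode],
            "defs": None
            if self.landmark_set is None
            else [[d.number, d.description, d.lm_type] for d in self.landmark_set.defs],
            "specimen_id": None if self.landmark_set is None else self.landmark_set.specimen_id,
            "coords": None
            if self.landmark_set is None
            else {str(n): arr(c) for n, c in self.landmark_set.coords.items()},
            "symmetry": None
            if self.symmetry is None
            else {"midline": sorted(self.symmetry.midline), "pairs": self.symmetry.pairs},
            "plane_points": [arr(p) for p in self.plane_points],
            "axis_points": [arr(p) for p in self.axis_points],
            "log": self.commands,
        }
        Path(path).write_text(json.dumps(state, indent=1), encoding="utf-8")

    @classmethod
    def load(cls, path):
        """Restore a session saved by :meth:`save` (volume reloaded from source)."""
        state = json.loads(Path(path).read_text(encoding="utf-8"))
        s = cls()
        src = state.get("volume_source")
        if src:
            kind, _, ref = src.partition(":")
            if kind == "fixture":
                s.set_volume(volume_mod.read_fixture(ref), source=src)
            elif kind == "dicom":
                s.cmd_load_dicom(ref)
            else:
                raise ValueError(f"unknown volume source {src!r}")
        if state.get("view"):
            vw = state["view"]
            s.view = render.ViewState(
                right=vw["right"], up=vw["up"], forward=vw["forward"],
                center=vw["center"], image_size=tuple(vw["image_size"]),
                pixel_pitch=vw["pixel_pitch"],
            )
        if state.get("cursor") is not None and s.cursor is not None:
            s.cursor.set_position(state["cursor"])
        s.threshold = state.get("threshold")
        if state.get("tf"):
            lo, hi, mo, gain, mode = state["tf"]
            s.tf = render.TransferFunction(lo, hi, mo, gain, mode)
        if state.get("defs"):
            defs = [landmarks.LandmarkDef(n, d, t) for n, d, t in state["defs"]]
            s.landmark_set = landmarks.LandmarkSet(defs=defs, specimen_id=state.get("specimen_id") or "specimen")
            for n, c in (state.get("coords") or {}).items():
                if c is not None:
                    s.landmark_set.coords[int(n)] = np.asarray(c, dtype=float)
        if state.get("symmetry"):
            s.symmetry = landmarks.SymmetryMap(
                midline=set(state["symmetry"]["midline"]),
                pairs=[tuple(p) for p in state["symmetry"]["pairs"]],
            )
        s.plane_points = [None if p is None else np.asarray(p, dtype=float)
                          for p in state.get("plane_points", [None] * 3)]
        s.axis_points = [None if p is None else np.asarray(p, dtype=float)
                         for p in state.get("axis_points", [None] * 2)]
        s._recompute_plane()
        s._recompute_axis()
        s.commands = list(state.get("log", []))
        s.refresh_slices()
        return s


def run_script(commands, session: Session | None = None) -> Session:
    """Execute an ordered command sequence, aborting on the first error.

    ``commands`` is an iterable of lines (or a single newline-joined
    string).  On failure a :class:`ScriptError` carries the 1-based line
    number, and every file written by this run is removed, so a failed
    script leaves no partial outputs.
    """
    if isinstance(commands, str):
        commands = commands.splitlines()
    session = session or Session()
    written: list[Path] = []
    for lineno, raw in enumerate(commands, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        try:
            written.extend(session.execute(line))
        except Exception as exc:
            for path in written:
                try:
                    path.unlink()
                except OSError:
                    pass
            raise ScriptError(lineno, line, str(exc)) from exc
    return session
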