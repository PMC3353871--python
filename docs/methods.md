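# Methods

This note records the models, conventions and numerical choices behind
`voxmark`, and what the synthetic phantoms do and do not establish about
behaviour on real scans.

## Volume model and conventions

A volume is a 3D scalar grid of stored-value intensities, assumed monotone
in physical density, with strictly positive voxel spacing (physical units
per voxel) and a world origin. One convention is stated once and asserted
everywhere: indices are 0-based with x = column, y = row, z = slice; a
voxel's coordinate refers to its center, `world(i,j,k) = origin +
(i·sx, j·sy, k·sz)`. The valid interpolation domain is the voxel-center
range `[origin, origin + (dims−1)·spacing]`; rays are clipped to this box,
and the cursor is clamped to it. All sampling is trilinear; intensities are
held as float64 after load (DICOM rescale slope/intercept applied), so
thresholds and transfer functions have a uniform numeric contract.

DICOM slices are sorted by instance number when present, else by the slice
position attribute, else by filename — a shuffled directory listing loads
identically. Missing spacing attributes are an error unless an explicit
`spacing_override` is given; nothing is guessed. Multi-frame DICOM, gantry
tilt and non-axial acquisitions are out of scope.

**Down-sampling** is arithmetic block averaging. Output extents are
`floor(dims/factors)`; trailing voxels that do not fill a complete block
are dropped so that every output voxel is an equal-weight mean (this is
what makes the global mean exactly preserved on divisible dims, and
factor-2-twice exactly equal factor-4). The reduction is performed over one
flattened per-block axis in the block's own memory order, so results are
bit-identical to extracting each block and averaging it. Spacing is
multiplied by the factors and the origin shifts to the first block's
center, keeping world coordinates physically aligned. Factors may differ
per axis.

## Rendering

The reference renderer is a brute-force orthographic ray caster. Per
sample: opacity from the piecewise-linear intensity ramp (0 below
`low_intensity`, `max_opacity` at/above `high_intensity`); reflectivity
`clamp(gain · |∇I| / max|∇I|, 0, 1)`, with the gradient from central
differences scaled by 1/spacing (one-sided at borders) and the volume-wide
maximum norm as normalizer so the transfer function is independent of
intensity units; shading ambient + Lambertian diffuse with the outward
normal `−∇I/|∇I|` (no specular term — "reflectivity" driven by the gradient
maps naturally to a diffuse gain); front-to-back over-compositing with
early termination at accumulated opacity 0.999, residual transparency
filled with the background colour. The projection is orthographic: one
pixel defines exactly one world ray, which is also what makes picking
geometry trivial; perspective is deliberately absent.

Ray marching uses step 0.5·min(spacing) — sub-voxel without excessive cost
— on *globally phase-anchored planes*: sample positions along a ray are
`t = (k + ½)·step` with t an absolute world coordinate along the view
direction, not offsets from each ray's own entry point. Parallel rays with
nearby bases therefore see consistent sampling, which removes per-ray phase
jitter; it is also what makes the two renderers directly comparable.

`surface` mode uses a steep ramp isolating one intensity band; `translucent`
mode a low `max_opacity` over a broad band, rendering all surfaces
simultaneously — the natural display for nested structures. Pseudo-colour
display is a background colour plus an optional foreground tint multiplier.
Transfer-function/light presets round-trip through a plain `key=value`
text format.

**Shear-warp.** The accelerated path factorizes the view: rays are
composited on an intermediate grid aligned with the two volume axes
transverse to the principal viewing axis (sheared object space), then a
single affine 2D warp resamples the premultiplied RGBA intermediate onto
the screen. Because marching is phase-anchored, the only discrepancy vs the
reference is the bilinear warp resampling; it shrinks quadratically in the
intermediate sampling density `refine`. The default `refine=8` keeps the
worst-pixel difference below ~2% of full scale on smooth (anti-aliased)
volumes and is *exact* for axis-aligned views whose intermediate grid nodes
coincide with pixel rays. Honesty note: at that density the intermediate
carries more rays than a small screen image, so this path is not a speed
win for small renders; the factorization pays off for large images over
modest volumes, and the implementation's role here is primarily the
validated factorization structure. Views with a zero principal forward
component (cannot occur for unit vectors, max |component| ≥ 1/√3) would
fall back to the ray caster with a logged notice.

## Cursor, slices, picking

There is exactly one cursor per session; every slice, pick and mark
operation reads the same instance. Slices through the cursor are aligned
with the **volume's** major axes (the rotated view lives only in rendering
and picking geometry) and interpolate trilinearly, so sub-voxel cursor
positions — the point of "first pixels of the structure appear/disappear"
refinement — are fully supported. Cursor steps default to one voxel but any
fractional step is allowed.

Picking tests the strict inequality `intensity > threshold` ("higher
than"), marching from volume entry to exit at 0.05·min(spacing)
(`PICK_STEP_FACTOR`) and refining the bracketing interval by bisection to
10⁻³ voxel along the ray. The fine march matters: a ray grazing a shell
about one voxel thick can be supra-threshold over a small fraction of a
voxel, and a half-voxel march skips roughly 1% of random rays straight
through the thin shell of the nested-shell phantom. Sub-voxel refinement is
pointless if detection itself is coarse, so the march resolves what the
refinement then polishes. A miss (ray outside the box, or never
supra-threshold — logged distinctly) leaves the cursor unchanged with a
warning. No default threshold ships: bone intensity depends on scanner and
protocol, so the threshold is always explicit.

`first_hit_fine_step` is a deliberately naive scalar walk at the same
density, kept as an independent cross-check of entry/exit handling,
traversal order and refinement. Comparing the two at voxel resolution
requires snapping the bisection-refined hit onto the walker's sampling
lattice first (the walker cannot localize a crossing more finely than its
step, and a hit within the bisection tolerance of a lattice point is
disambiguated by sampling that point); with that, hits agree ray-for-ray.

## Symmetry geometry

A plane is built from exactly three non-collinear points (triangle area
> 1e−9·scale² guards degeneracy); its normal takes the sign given by the
point order, a `flip_normal` option chooses the viewing side, and
reflection is sign-invariant. Reflection `p′ = p − 2(n·p − d)·n` is an
exact isometric involution. "Rotate to plane" sets the viewing direction
along the normal and keeps the previous up vector projected into the new
view plane (minimal rotation, falling back to world z then y); applying it
twice changes nothing. "Rotate to axis" additionally projects the axis
direction into the view plane as screen-x; it errors when the axis is
numerically parallel to the normal (angle < 1e−6 rad). Frames are
right-handed with `right × up = forward` and orthonormal to 1e−12 by
construction. Plane anchors PL1–PL3 and axis anchors A1–A2 live in the
session and the plane/axis are recomputed eagerly (and logged) whenever an
anchor changes. Least-squares symmetry-plane estimation from many landmark
pairs is deliberately out of scope: the plane is defined by exactly three
points.

## Landmark files and exports

Landmark lists are UTF-8 text, `#` comments allowed, one definition per
line: running number, free-text description, optional trailing `type=1|2|3`
token (Bookstein types). Numbers must be contiguous from 1 — a gap or
duplicate is reported with its line number. Symmetry maps use `midline n
[n ...]` and `pair left right` directives; a landmark may not be both
midline and paired, nor appear in two pairs.

The TPS dialect is pinned: `LM3=<n>` (3D), n rows of `x y z` at six
decimals, `ID=<specimen>` trailer; coordinates are world units (what
downstream shape software consumes), with an option for voxel units. The
NTSYS dialect is pinned as the rectangular matrix `1 <n_specimens>
<3·n_landmarks> 0`, then per specimen a label line and the flattened
`x1 y1 z1 x2 …` row. Several NTSYS variants exist in the wild; one is fixed
here so round trips are bit-exact, and both formats ship with readers.
Exports of the same data decode to identical coordinate matrices.

**Precision statistic.** Given ≥2 fully marked repeats of one specimen,
coordinates are converted to voxel units (divided per-axis by spacing), the
coordinate-wise (marginal) median across repeats is taken per landmark, and
each repeat's Euclidean distance to that median is pooled by landmark type;
summaries are median and quartiles per type. The marginal median is the
simplest reading of "median landmark position"; the geometric median is a
possible variant and would differ slightly for strongly anisotropic
scatter. The statistic is invariant to repeat order and to rigid joint
translation (not to rotation, since the median is marginal).

## Phantoms: what they emulate and what they do not

Phantoms emulate the structure relevant to each contract: a bright
bone-like shell around darker interior (`spherical_shell`), nested shells
for multilayered structures whose inner surfaces lie beneath outer ones
(`two_shell`), additive Gaussian noise for degraded specimens
(`noise_sigma`, seed-reproducible, sigma 0 bit-exactly deterministic), and
an exactly grid-mirror-symmetric blob pair with known left/right landmark
pairs and symmetry plane (`mirror_blobs`). Rasterization is at voxel
centers without anti-aliasing by default so brute-force voxel-counting and
ray-walking oracles are exact; an anti-aliased mode (2×2×2 supersampling)
exists for renderer tests, where a half-voxel intensity ramp at surfaces is
the realistic regime (real CT has partial-volume averaging) and keeps
silhouettes from being pathological step edges. Ground truth contains the
±x/±y/±z surface extrema of each shell — analogues of "anterior-most" /
"dorsal-most" type-3 landmarks.

What passing these tests does *not* show: phantoms have no beam hardening,
reconstruction artifacts, intensity inhomogeneity or anatomical complexity,
so they validate geometry, traversal, formats and statistics — not
segmentation quality on real tissue contrast. Threshold choice on real
scans remains the operator's anatomical judgement, which is exactly why it
is a required parameter.

## Session semantics

A session executes an ordered command stream; the first invalid command
aborts with its line number and removes files written by that run. Every
executed command is appended to the log, and replaying the log reproduces
all exports byte-for-byte — determinism is a design contract, tested
end-to-end. The CLI persists session state (volume by reference, cursor,
view, threshold, landmarks, anchors, log) in a JSON text file between
invocations; `run` executes a whole script in one process. Keyboard/mouse
customization of the original workflow maps to script command aliases, not
interactive bindings.

## Problem sizes in tests

The test-suite and acceptance phantoms are 32³–64³ with 48²–64² images, 100
random-ray batteries, 1000 random planes/points, and 10 repeats × 12
landmarks for the precision simulation — sizes at which every oracle
(explicit-loop block means, exhaustive voxel counting, fine-step ray walks)
is exact and the whole suite runs in seconds while exercising each contract
at full fidelity.
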