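# voxmark

Headless, scriptable digitization of 3D landmarks on volumetric micro-CT
data, for geometric morphometrics.

Morphometric shape analysis starts from homologous landmark coordinates.
On 2D images a landmark can sit on an intersection of a structure with the
image background; on a 3D skull the same point must be described as, say,
"the anterior-most point of a suture", which requires navigating freely in
the volume. `voxmark` provides that navigation as a library and command
stream instead of a GUI: it loads stacks of DICOM slices, volume-renders
them, places a single synchronized 3D cursor by threshold ray picking,
refines it sub-voxel in the three orthogonal cross-sections, exploits
bilateral symmetry (plane/axis definition, cursor reflection, view
rotation), and exports coordinates as TPS or NTSYS files for downstream
analysis (IMP series, MorphoJ, R).

## The core methods

**Volume rendering.** Every voxel contributes: a sample with intensity
*I* gets opacity from a piecewise-linear ramp
α(I) = α_max · clamp((I − I_lo)/(I_hi − I_lo), 0, 1)
and reflectivity r ∝ |∇I| (normalized gradient magnitude); it is shaded
ambient + Lambertian,
c = k_a·c_base + Σ_l k_l·c_l·c_base·r·max(0, n·l), with n = −∇I/|∇I|,
and composited front-to-back along each orthographic ray:
C ← C + (1−A)·α·c, A ← A + (1−A)·α.
Unlike thresholded surface rendering this has no pseudo-fenestrations
(non-physical holes where a single global threshold is locally too high)
and is robust to noise. A brute-force ray caster is the reference; a
shear-warp factorization (composite on a volume-axis-aligned grid, then one
affine 2D warp) is validated against it.

**Threshold picking.** A pixel defines one world ray
(base = center + (col−w/2)·pitch·**right** + (h/2−row)·pitch·**up**,
direction = **forward**); the cursor jumps to the first point along the ray
whose trilinearly interpolated intensity strictly exceeds a user threshold,
refined by bisection to 10⁻³ voxel. On a live-specimen scan the ray passes
through air and soft tissue and lands on the first bony structure. No
default threshold is hard-coded: bone intensity is scanner-dependent.

**Symmetry geometry.** A plane through three landmarks (p′ = p −
2(n·p − d)·n reflects the cursor to the contralateral side) and an axis
through two points fix a viewing frame ("rotate to plane" / "rotate to
axis"), so extremal (Bookstein type 3) landmarks are digitized from
precisely defined angles.

**Precision statistic.** For repeated digitizations of one specimen, each
landmark's coordinate-wise median across repeats is taken and each repeat's
Euclidean distance to it (in voxels) is pooled by Bookstein landmark type
(1 = tissue juxtaposition, 2 = curvature maximum, 3 = extremal point).

Synthetic phantoms with analytically known geometry (solid spheres, single
and nested bright shells, exactly mirror-symmetric blob pairs) make every
step testable without any scan data; they can be written out as genuine
DICOM slice stacks.

## Worked example

Digitize the anterior-most point of a skull-like two-shell phantom:

```sh
$ voxmark phantom --kind two_shell --dims 64,64,64 --seed 1 --out ph
wrote ph/volume.npz (64x64x64 voxels)
$ printf '1 anterior-most point of outer shell type=3\n' > lm.txt
$ voxmark -s s.json load ph/volume.npz
$ voxmark -s s.json landmarks lm.txt
$ voxmark -s s.json pick --pixel 32,32 --threshold 50
31.500000 31.500000 19.500000
$ voxmark -s s.json move z -- -0.25      # sub-voxel refinement
$ voxmark -s s.json mark 1
$ voxmark -s s.json export-tps out.tps
$ cat out.tps
LM3=1
31.500000 31.500000 19.250000
ID=specimen
```

The pick rays march along +z from the default view; the printed hit
(31.5, 31.5, 19.5) is the front surface of the outer shell — exactly
`center_z − radius = 31.5 − 12` — and the TPS file carries the refined
world coordinates. The phantom's `ph/ground_truth.txt` lists the analytic
extremal points for comparison. The same commands can be written one per
line in a file and replayed with `voxmark run script.txt`; replays are
byte-identical.

The library mirrors the CLI one-to-one (`voxmark.run_script`,
`render_raycast`, `first_hit`, `reflect_point`, `precision_stats`, ...);
see the docstrings and `docs/methods.md`.

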