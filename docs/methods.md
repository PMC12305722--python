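# Methods

This note documents the models behind `gantryscan`, the parameters that
matter, the conventions that were genuinely open choices, and what the
simulation does and does not claim about real scanning.

## Coordinate and pose conventions

World coordinates are millimetres: `x` along the linear rail, `y` lateral,
`z` depth (downward from the phantom surface at `z = 0`). Voxel centers sit
at `origin + index · spacing` (node-centered). A probe pose is
`(x, pitch, roll)`; the pose's `y` field exists for symmetry with
two-coordinate position logs but is frozen at 0 because the gantry has a
single actuated linear axis.

The gimbal pivot sits `pivot_height` (default 20 mm) above the surface at
the station's `(x, lateral_center)`. Orientation is composed **pitch about
the lateral axis first, then roll about the travel axis**, both through the
pivot; the composition order is not dictated by the hardware and is fixed
here as a documented convention. At zero tilt the imaging plane is the
lateral–depth plane at the station, normal along the rail. Pitch tilts the
beam along the rail; roll swings it sideways — which is what lets a tilted
slice reach laterally off-axis structure that no untilted plane touches.
The image rectangle (default 60 × 60 mm) starts one `pivot_height` along
the beam from the pivot, i.e. at the surface for an untilted probe.

## Phantom model

A phantom is an echogenicity grid in [0, 1] plus an integer lesion-label
grid. Defaults emulate a commercial breast phantom: 160 × 120 mm footprint
with lesions 12–18 mm in diameter; the depth (60 mm) is a package default,
as physical phantoms are specified by footprint only. Lesions are
ellipsoids labeled by the voxel-center inclusion rule (exact and testable,
no partial-volume weighting); they must lie fully inside the extent, and
overlaps resolve to the later lesion. Echogenicity inside a lesion is
background plus a contrast in [−1, 1] (default −0.25, hypoechoic, as solid
tumors usually appear). A seeded, smoothed zero-mean texture (standard
deviation 0.05) keeps slices from being piecewise constant; it claims no
acoustic realism. Identical arguments and seed give bit-identical phantoms.

## Image formation

Slices are formed by resampling the phantom on the pose's plane: trilinear
interpolation for echogenicity, nearest-neighbor for labels, at
`pixel_spacing` (default 0.5 mm; the fixtures use 1 mm, which makes an
untilted slice at a lattice-aligned station reproduce the voxel plane
bit-exactly). Samples outside the voxel-center hull take the background
level, carry no label, and are flagged out-of-volume; scores normalize by
in-volume pixels only.

Display intensity is
`I = echogenicity · exp(−μ·depth) · s`, with attenuation
`μ = 0.01 /mm` by default and `s` multiplicative Rayleigh speckle with
scale `√(2/π)`, hence mean exactly 1; then log compression
`log1p(g·I)/log1p(g)` with gain `g = 50`, scaled to 8 bits. The per-pose
speckle seed is a stable hash of the global seed and the pose lattice key,
so an image is reproducible regardless of visit order. The plane is a
rectangle rather than the convex-probe fan: fan geometry changes nothing
about the search and complicates masks; this is a deliberate divergence
from the physical probe.

## Scoring

The surrogate scorer maps the lesion area fraction `a` of in-volume pixels
to `p = a/(a + a₀)`: zero when the plane misses every lesion, 0.5 at
`a = a₀`, saturating toward 1. The default `a₀ = 0.02` puts typical
cross-sections of 12–18 mm lesions in the high-probability regime
(`p ≈ 0.67–0.77` for the default 60 × 60 mm slice) without saturating
differences away — the search needs only monotonicity in the physically
meaningful quantity. The scorer also reports per-lesion probabilities
(same map applied to each label's own area fraction), which is how the
linear-vs-angular comparison attributes detections. The black-box
interface (`image → score`) keeps a learned classifier pluggable.

Saliency for an arbitrary scorer uses occlusion sensitivity: each
`patch × patch` window (default 8 px, stride 4) is replaced by a background
intensity and stripped of lesion content, and the rectified score drop is
accumulated and normalized to [0, 1]. Binarization takes
`saliency ≥ t·max` (default `t = 0.5`) and keeps the largest connected
component (ties to the first in scan order). Mask agreement is reported as
Dice and IoU, both defined as 1 when both masks are empty (correct
prediction of absence). Note the occlusion map is blocky at the patch
scale, so Dice against the pixel-exact ground truth is structurally below
what a pixel-level activation map could reach.

## Search

Angular sweep order: the pitch range `P` runs `−sθ..+sθ` when the
direction indicator `d = 1` and reversed when `d = 0`; within the r-th
pitch value the roll range runs forward for even `r` and backward for odd,
so consecutive poses always differ by one step of one servo (minimal
mechanical motion). `d` alternates with the running station count
(`d = k mod 2`). The relation between the index half-range `sθ` and the
angle bounds is enforced as `α·sθ ≤ min(θmax, φmax)`.

Station rule: the untilted slice is scored first (`lprob`); the station's
best pose is the untilted one when `lprob ≥ aprob` — linear wins exact
ties — otherwise the sweep argmax. All argmaxes everywhere break ties in
favor of the first-visited pose.

Refinement: the step is divided by `refine_factor = 2` each round
(bisection-style coarse-to-fine); the next round scans
`center ± previous_step` in the new step around the incumbent best `x`,
clipped to the rail, and rounds continue while the step is at least `ε`.
Angular sweeps repeat during refinement rounds so refined stations compete
on an equal footing. Scores are memoized on a quantized pose key, so
revisited poses return identical values and best-of-round never decreases.
With `slin0 = 32`, `ε = 1` this gives exactly the step sequence
32, 16, 8, 4, 2, 1 and roughly 13 % of the evaluations of exhaustive
1 mm-resolution search at the same angular lattice.

The exhaustive oracle simply scores an explicit pose list with the same
per-pose seeding and returns the exact argmax; the search must agree with
the oracle run over the union of the lattices it visited, exactly, and does
so on the single-lesion fixture for every seed tested.

## Coverage

A voxel is covered when its center lies within half the slice thickness
(default 2 mm) of an acquired plane and inside the image rectangle.
Coverage analysis runs on the **round-0 acquisition schedule** (all
stations, and in angular mode the full sweep lattice at each), not on the
refinement trace: refinement stations depend on what was found, so the two
modes would visit different rail positions and neither pose set would
contain the other. On the common schedule the angular pose set is a strict
superset of the linear one, making the coverage comparison meaningful.
Large grids may be strided (default stride 2 in the orchestrator) —
fractions are then over the sampled centers.

## Fixtures

* `single_centered` — one 14 mm sphere on the central scan line at
  (80, 60, 30) mm; search at `slin0 = 16`, `sθ = 2`. The benign case for
  oracle-equivalence checks.
* `two_tumor` — tumor 1 (14 mm) at (60, 60, 30) on the scan line; tumor 2
  (18 mm) at (100, 102, 40), i.e. 42 mm lateral of the line. The geometry
  is chosen analytically: the closest zero-angle sample column is 30 mm
  from the line, and tumor 2's nearest surface is 33 mm out, so every
  untilted slice scores exactly 0 for it; at roll 14° (= `α·sθ` with
  `sθ = 7`) the beam center at the lesion's depth is displaced
  `(depth + pivot) · sin 14° ≈ 14.5 mm`, bringing most of the lesion's
  cross-section inside the rectangle (`p ≈ 0.73`). Both lesions sit on
  round-0 stations (`slin0 = 10` from `x = 10`), mirroring the usual
  validation phantoms in which the reference tumor is placed on the
  central scanning line.
* `off_axis_only` — tumor 2 alone: every untilted slice is lesion-free.

Fixture searches use 1 mm pixels and `ε = 2 mm`; these sizes keep a full
linear-plus-angular comparison (≈ 5 200 slice evaluations) to a few
seconds while leaving every geometric margin above quantization noise.

## Determinism

All randomness flows from one seed through stable hashes: the phantom
texture stream and each pose's speckle stream are derived from
`(seed, purpose, key)`. Reports contain no timestamps; two runs of the
orchestrator with the same seed are byte-identical across the JSON report,
CSVs, PNGs and NIfTI coverage maps (wall-clock timings go to a separate
log). Configuration is YAML only, with unknown keys rejected and errors
naming the offending stage.

## Limitations

The image model is first-order: no wave propagation, shadowing,
refraction, elevation focus or coupling effects, and a rectangular rather
than fan-shaped field of view. The surrogate scorer sees geometric ground
truth, so it is an upper bound on what an image-based classifier could do:
passing results validate the *search and acquisition logic* — that the
coarse-to-fine schedule finds the exhaustive optimum, that angular sweeps
reach what linear scanning cannot — not classifier performance on real
tissue, which would require trained weights and real data. Phantoms are
homogeneous outside lesions; real tissue heterogeneity (fat, fibrosis,
margins) is absent even from the physical phantoms this emulates.
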