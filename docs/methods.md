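# Methods

## Scope and data model

`ctviz` models, as a deterministic headless library, the preprocessing and
rendering pipeline of a browser-style volume viewer working under hard
resource limits. The central object is `Volume`: a 3D scalar grid indexed
`(x, y, z)` with `z` the slice axis, per-axis spacing in mm, and a world
origin at the centre of voxel `(0, 0, 0)`; the bounding box extends half a
voxel beyond the outermost centres, so its edge lengths are exactly
`dims × spacing`. Voxel indices are 0-based and all index ranges (chunks,
ROI boxes) are half-open, which makes concatenation and tiling unambiguous.

Resource limits (`ResourceProfile`) are configuration, not probed hardware:
a headless artifact has no graphics context or heap API to query, so the
texture edge limit, heap limit, upload fraction and fallback budget come
from config/CLI. Defaults: texture 2048 voxels, upload fraction 0.75,
fallback budget 2048 MiB (the fallback's magnitude is an artifact choice),
chunk factor 0.25.

## Chunk streaming

`chunkSize = min(⌊maxTex·chunkFactor⌋, ⌊budget/2⌋)` is implemented literally,
mixing a voxel-count operand with a byte-count operand inside the `min` —
for realistic budgets the texture term governs (2048 · 0.25 = 512 slices at a
3071.8 MiB budget). An opt-in `budget_in_slices` path converts the byte
budget to slices via bytes-per-slice first, for callers who want unit-
consistent behaviour; both paths agree on the reference configuration.
Streaming yields one chunk at a time together with cumulative payload bytes
(container overhead is not counted); a single chunk exceeding the budget is a
hard error. Chunks inherit spacing and get their origin shifted by
`z0 × sz`, preserving world coordinates, and recombination requires
contiguity and matching in-plane dims/spacing, returning the parent volume
bit-exactly.

## Level of detail

The downsampling trigger is `max(dims) > maxTex/2` (strictly greater; the
boundary passes through). One isotropic factor reduces all axes, so the
largest axis lands exactly on the target and aspect ratios are preserved.

Resampling conventions, chosen where the resize rule (ceil division,
trilinear weights) does not pin them down:

- **Grid alignment** is endpoint-preserving: output index `i` maps to input
  coordinate `i·(nIn−1)/(nOut−1)` (axis centre when `nOut = 1`), so the
  first and last samples of each axis are reproduced exactly. The mapping is
  isolated in one helper and could be swapped for a cell-centred convention.
- **Spacing update**: `outSpacing = inSpacing · (inDim/outDim)`, preserving
  physical extent to within rounding of the ceil-resize.
- **Dtype**: integer volumes are rounded back to their input dtype; float
  volumes stay float. Interpolation happens in float64.
- Coordinates outside the grid clamp to the border; integer in-range
  coordinates return stored values exactly, which the tests exploit.

Trilinear interpolation is the package's own 8-corner weighted sum
(vectorised); `scipy.ndimage.map_coordinates` appears in the tests as an
independent oracle, never in the implementation path.

## Transfer functions

Opacity is an unnormalised Gaussian mixture — the peak of each node equals
its weight, making weights directly interpretable as maximum opacities — and
is clamped to [0, 1] after summation. Colour is linear interpolation between
strictly increasing nodes with end-clamping; this is algebraically the
tent-kernel sum over node positions, verified against an explicit kernel
oracle in the tests. No bias/skew parameters are modelled. The three presets
(`ct-vascular`, `ct-bone`, `ct-soft`) are package-defined anchor tables on
the Hounsfield scale (air ≈ −1000 HU transparent; contrast ≈ 400 HU and
cortical bone ≳ 1000 HU opaque); they are design choices, not published
values.

## Ray casting

Orthographic (default) or perspective rays are intersected with the volume's
world box by the slab method; ties at faces resolve toward inclusion.
Marching starts half a step inside the entry point with step
`sampleDistance × min(spacing)` mm, `sampleDistance ∈ [0.1, 1]`. Per sample:
trilinear value lookup → transfer function → optional scalar-opacity
attenuation → optional gradient modulation and Lambertian shading → opacity
step correction → front-to-back compositing with early termination at
accumulated α ≥ 0.99 (configurable; the truncated tail is bounded by
1 − threshold).

Interpretations chosen for controls whose quantitative mapping is not
published, kept behind `RenderSettings`:

- **Sample distance** is a fraction of the smallest voxel spacing; the
  opacity-correction reference step is that spacing, so per-node weights are
  calibrated "per minimum-spacing step". The correction
  `α ↦ 1 − (1−α)^(step/ref)` makes accumulated transmittance step-invariant
  for homogeneous media; with it the discrete compositor matches the
  closed-form integral `c(1 − e^{−τD})`, `τ = −ln(1−α_ref)/ref`, to better
  than 2 % at sampleDistance 0.1 (tested).
- **Gradient control** multiplies α by `(1−s) + s·clamp(|∇|/g₉₈, 0, 1)`
  where `g₉₈` is the volume's 98th-percentile gradient magnitude and `s` is
  the control value: 0 is off, 1 weights opacity fully by edge strength.
- **Scalar opacity reference** operates on intensities affinely normalised
  to [0, 255]: below the reference, α is attenuated linearly to zero at 0;
  the control at 0 disables it.
- **Shading** is a single headlight: diffuse `|n·view|` scaled 0.8 plus 0.2
  ambient, with normals from the (central-difference) gradient field.
- **Clipping planes** discard samples with `(p − point)·normal < 0`; with no
  planes the output is order-independent trivially, and plane order never
  matters because clipping is a pure conjunction.
- **Max-intensity blending** tracks the per-ray maximum and maps it through
  the colour/opacity functions once at the end.

Gradients use central differences divided by `2 × spacing` in the interior
and one-sided differences at borders (numpy.gradient's convention) — exact
for linear fields.

Output is 8-bit RGBA PNG; rendering is fully deterministic (no jittering),
so identical inputs give bit-identical files.

## ROI refinement

A box on the downsampled grid is mapped to original indices by
`[⌊a0·f⌋, ⌈a1·f⌉)` with clamping — outward rounding guarantees the mapped
box's world extent contains the requested one. The crop is a pure slab copy
(never resampled); its origin shifts by `a0 × spacing` and spacing is
unchanged, so the re-render resolves structures at native voxel size. If the
crop itself still exceeds the texture target, the LOD pass is re-applied to
the subvolume, keeping the resource invariant recursive. The caller's camera
is never mutated; rendering uses a copy re-targeted to the subvolume centre
with direction, up, projection and zoom preserved. Published
native-resolution ROI dimensions for the reference series are reproduced
within ±3 voxels per axis by this rule; the exact index arithmetic behind
those printed rows is not recoverable, so they are checked loosely only.

## Synthetic phantom

The generator emulates a contrast-enhanced peripheral-artery CT at reduced
scale: default grid 128 × 128 × 410 voxels at (0.955, 0.955, 0.625) mm, so
the slice axis dominates as in clinical series. Voxel values are background
(40 HU, soft tissue) plus vessel contributions — peak 400 HU on the
centreline with a smooth cosine radial falloff to zero at the radius, smooth
enough to test trilinear fidelity and closed-form enough for geometric
oracles — plus hard bone-density cylinders (1200 HU) and seeded Gaussian
noise (σ = 15 HU), rounded to int16. The intensity ordering
bone > vessel > background is guaranteed, which the transfer-function
presets rely on. The exact centreline is returned as ground truth.

What the phantom does **not** emulate: curved/branching vasculature,
stenoses, partial-volume and beam-hardening artefacts, anatomical texture,
or any CT physics. Tests passing on the phantom therefore validate the
pipeline's geometry, resampling and compositing arithmetic — not clinical
image quality.

## Evaluation statistics

Ratings are long-form (characteristic, tool, structure, rating ∈ [1, 5]).
Summaries use the arithmetic mean and the sample (n−1) SD — the convention
fixed by the reference summaries — with half-up display rounding at two
decimals alongside full precision (display rounding is configurable since
published tables mix conventions). The one-way ANOVA computes SSB, SSW and
`F = (SSB/(k−1))/(SSW/(N−k))` in a two-pass form, with the p-value from the
`F(k−1, N−k)` upper tail (scipy); p-values below 0.001 are reported as
"< 0.001". Requirements: ≥ 2 groups, ≥ 2 observations per group, nonzero
within-group variance. The decomposition identity SSB + SSW = SST holds to
1e−9 and the statistic matches `scipy.stats.f_oneway` to 1e−10 in the tests.

## Problem sizes and numerical tolerances

Tests and the acceptance script run at reduced scale — phantoms up to
~128 × 128 × 410, render targets of 16–64 px, split/combine identity at
8 × 8 × 1639 — sizes chosen so the full suite completes in minutes on one
CPU while still exercising the reference depth values and every code path;
the dimension arithmetic for the full 512 × 512 × {1639, 2239, 2041} series
is exact at any scale, so only the resampling itself is exercised reduced.
Key tolerances: round-trip spacing 1e−6 mm; trilinear vs corner-sum oracle
1e−12; compositing vs direct sum 1e−10; compositing vs continuous integral
< 2 % at sampleDistance 0.1; ANOVA decomposition 1e−9.

## Known limitations

- Single-frame, uncompressed DICOM only; no multi-frame/enhanced CT, no
  DICOM writing. When SliceThickness and inter-slice distance disagree, the
  inter-slice distance (median of position differences) wins.
- The `.vti` dialect is the package's own (inline base64, uint64 byte-count
  header, one `"intensity"` array); it round-trips through this package and
  is structurally VTK XML ImageData, but compressed/appended VTK encodings
  are not parsed.
- The ray caster is a CPU reference implementation: no GPU, no frame-rate
  targets, no stochastic sampling, no ambient occlusion.
- Per-axis (anisotropic) LOD factors and mipmap pyramids are out of scope;
  one isotropic factor mirrors the pipeline being modelled.
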