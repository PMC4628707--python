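# Methods

This note records the model, the numerical choices and their rationale, what
the synthetic data does and does not emulate, and known limitations.

## Coordinate conventions

Array axis k of an `ImageStack` maps to world axis k; the world position of
voxel (i, j, k) is (i, j, k) · spacing in mm, right-handed, 0-based. The
historical left-handed stack convention of the acquisition software is
absorbed entirely by the slice-frame axis assignment (the y-axis is the
*negated* Frenet normal), so no data flipping occurs anywhere. Cross-section
contours live in slice pixel coordinates (u, v); pixel (u, v) of a slice with
frame (origin, X, Y, Z) sits at world
`origin + (u − c)·px·X + (v − c)·px·Y`, c = (size−1)/2. `back_transform` is
the exact inverse of this sampling convention (round-trip identity to 1e-9 mm,
asserted in tests).

## Preprocessing

* **Two notions of "rescaling".** The source protocol scales a 52-slice
  sagittal stack by 3.0 ("156 images with 0.35 mm pixels") and then reslices
  until voxels are uniform. `scale_stack` reproduces the first operation
  literally (sample counts ×factor on every axis; 52 → 156, 1.04 → 0.3467 mm);
  `make_isotropic` performs the single equivalent resample to truly cubic
  voxels (edge = in-plane/factor; slice count = extent/edge, rounded).
  The two differ because scaling a 1.8 mm-thick stack by 3 gives 0.6 mm slice
  spacing, not 0.35 mm; the pipeline uses `make_isotropic`, since downstream
  geometry assumes cubic voxels.
* Resampling is trilinear. Within-volume edge samples clamp to the boundary
  voxel (a constant volume must stay constant under resampling); samples
  outside the volume during cross-section reformation take 0.
* **Diffusion.** Perona–Malik with exponential conductance
  g(∇I) = exp(−(∇I/κ)²) on the 6-connected stencil, explicit Euler.
  Defaults: 10 iterations, κ = 30 intensity units, step 0.15. The validated
  step ceiling is 0.25 (bounded since |1 − 6·step| < 1); the default stays
  below the monotone bound 1/6 so smoothing can never create new extrema
  (property-tested). κ should sit well below the lumen/wall contrast so the
  air–tissue edge conducts (almost) nothing.

## Centerline and frames

* **Spline.** Hermite cubics with Catmull–Rom tangents
  m_i = (p_{i+1} − p_{i−1})/2 (one-sided at the ends): local support, no
  global solve, exactly reproduces straight polylines, C1 by construction.
  Interior segments reproduce a parabola through uniformly spaced samples to
  machine precision; end segments (one-sided tangents) deviate up to ~4e-2 at
  0.5 mm node spacing — centerline ends should be picked slightly past the
  anatomy of interest.
* **Arc length** by adaptive quadrature of ‖ċ‖ per segment (rel. error
  < 1e-6); the inverse s ↦ (segment, t) uses a 256-sample cumulative table
  per segment with Newton refinement. Slice frames are stepped in *arc
  length*, not spline parameter: the protocol's "fixed spacing between image
  centers" is a physical distance (default step 1.04 mm, the source in-plane
  pixel; default cross-section pixel 0.35 mm, the rescaled pixel — the
  protocol does not state the reformatted pixel size, so it is exposed).
* **Degenerate curvature.** Where ‖ċ × c̈‖ < 1e-8·‖ċ‖² the binormal is
  undefined; the previous frame's x-axis is parallel-transported onto the new
  normal plane (a fixed arbitrary perpendicular seeds a fully straight
  curve). When a previous frame exists, the binormal sign is chosen to
  minimize the angle to it, so frames never flip 180° between adjacent
  slices — a flip would corrupt the inter-slice deviation energy.

## Greedy snake

Term discretizations for a candidate position c of node i (closed contour,
neighbours p = v_{i−1}, n = v_{i+1}):

| term | formula | role |
|---|---|---|
| E_cont | α·(‖n − c‖² + ‖c − p‖²)/2 | expansion control (α < 0 expands) |
| E_curv | β·‖n − 2c + p‖² | bending stiffness |
| E_ext | −γ·‖∇I‖² (bilinear sample) | edge attraction |
| E_dev | δ·d⁴, d = min distance to previous contour's nodes | inter-slice coherence |

* **Symmetric first difference for E_cont.** A one-sided (forward) difference
  with α < 0 rewards *any* move away from the next node; the cheapest such
  move is tangential-backward, which scatters nodes and inverts the polygon
  (observed on disk phantoms). The symmetric form cancels tangential trades
  and rewards only radial stretch.
* **Normalization.** The raw terms live on incommensurate scales (px² vs
  intensity²·px⁻² vs px⁴), so each term is min–max normalized over the 3×3
  search window before weighting — the classical greedy-snake practice. The
  external term's denominator is floored at 5% of the image-wide gradient
  maximum, otherwise flat-lumen noise is amplified to full scale and pins the
  contour. Raw (unnormalized) mode is available (`normalize: false`).
* **A structural fact worth knowing:** with the symmetric E_cont, the
  windowed curvature term is an exact affine function of the continuity term
  (‖n + p − 2c‖² = 4·E_cont/α·… + const per window), so after per-window
  normalization only the *sum* α + β matters. α + β > 0 acts as a tangential
  node-attraction (nodes bunch along edges until deletion), α + β < 0 as a
  repulsion that destabilizes node ordering. The defaults α = −0.8,
  β = +0.8 therefore make the internal terms *inert at ties* — geometry is
  regularized by the spacing rules and the deviation energy, and motion is
  driven by the image. Users tuning α, β in normalized mode should preserve
  α + β ≈ 0.
* **Capture range.** A gradient ridge attracts only over ~2–3 px; a seed
  circle in the middle of a wide lumen would never reach it. Each slice
  therefore runs a short coarse-to-fine ladder: greedy passes on the edge map
  blurred with σ = 4 then 2 px (each capped at `max_iter` passes), then up to
  `refine_iter` = 15 passes on the raw map to land on the true ridge. Blur σ
  larger than the lumen radius must be avoided — the blurred ring then peaks
  at the lumen *center* and implodes the contour — which is why the ladder is
  short and the seed circle is sized from the image: a flood fill of
  intensities within half the maximum deviation from the seed-point intensity
  gives an equivalent lumen radius; the seed circle takes 0.8 of it, with the
  node budget sized for the full estimated perimeter at 2·s_min spacing.
  `edge_blur_px: 0` restores the single-map literal iteration.
* **Iteration.** Nodes are visited in order and updated in place; ties prefer
  the current position, then the smallest offset, then row-major window
  order — determinism is absolute (identical inputs give bit-identical
  contours; asserted). After each pass, spacings are restored into
  [s_min, s_max] = [3, 12] px (midpoint insertion above s_max, deletion of the
  second node of too-close pairs, never below 3 nodes); interleaving
  resampling with greedy passes is the default, `resample_each_iter: false`
  resamples once per slice.
* **Propagation.** Slice k uses slice k−1's result as both initialization and
  deviation reference; the start slice has no deviation term. Bidirectional
  propagation from the start slice is supported (default). Overrides (JSON
  contours) replace computed slices verbatim and feed their successors —
  the file-based stand-in for expert manual correction; per-slice masks mark
  forbidden pixels (infinite external energy), standing in for manual teeth
  exclusion. A collapsed slice (< 3 nodes) is recorded as failed and skipped;
  propagation continues from the last good contour.

## Reconstruction

* Areas: |shoelace|/2 × pixel², orientation- and start-node-invariant;
  self-intersecting polygons warn and return the signed-area magnitude.
* Volumes: rectangle rule (area × step summed) to match "superposition of
  segment areas"; trapezoid available. Failed slices flanked by valid ones
  are linearly interpolated in the area function only; leading/trailing gaps
  stay missing and the mesh skips them.
* Lofting: all rings are resampled to one common vertex count (the largest
  ring; pairwise counts would give a ring two different vertex sets and break
  watertightness), wound consistently (Newell normals), and aligned pairwise
  by the cyclic shift minimizing total inter-ring edge length (minimal
  twist). Optional centroid-fan caps close the tube; with caps the mesh is
  watertight and its divergence-theorem volume matches the area-function
  superposition within the chord/stair-step discretization error
  (~2 × perimeter × pixel per slice).

## Synthetic data

The phantom emulates what the pipeline actually consumes: an elongated dark
lumen (air) inside brighter tissue on an anisotropic sagittal grid
(1.04 × 1.04 × 1.8 mm defaults), with sub-voxel Gaussian border blur
(0.7 mm) and additive Gaussian noise (5% of the lumen/wall contrast by
default), over straight, circular-arc or spline-node centerlines and
constant/tapering/sinusoidal radius profiles. The tube is extended
tangentially a few mm past the centerline ends (the real tract continues past
any chosen end landmarks) so end slices see a full cross section.

Not emulated: Rician MRI noise statistics, bias fields, phonation/motion
blurring, bifurcations (piriform sinuses, vallecula), teeth signal voids, and
non-tubular cross-section shapes. Passing the phantom suite therefore shows
the geometry/segmentation chain is correct and self-consistent at the stated
noise level — not that segmentation of in-vivo MRI needs no manual
correction (the override mechanism exists precisely for that).

Reference recovery conditions (acceptance suite and `scripts/acceptance.py`):
128³ voxels, tube radius 8 mm, curvature radius 40 mm, noise 5% of contrast,
full pipeline; per-slice area error must stay below the one-pixel bound
2 × perimeter × pixel size, total volume within 5% of analytic, and two runs
byte-identical. Unit-test phantoms use 48³–72³ grids so the default suite
stays fast; the reference run uses the full 128³ size.

## Known limitations

* The snake resolves boundaries to ~1 px; relative area error grows as
  1/r for narrow lumens (plus an inscribed-polygon chord deficit of
  (spacing/r)²/6), so very narrow constrictions (r ≲ 2 px) are at the
  method's edge — the spacing bounds then force a coarse triangle.
* Strongly concave cross sections beyond the blur ladder's reach rely on
  propagation from a neighbouring slice or an override.
* The centerline is user-supplied; no skeletonization or automatic centering
  is attempted, and a centerline far from the lumen axis biases the frames
  and the area function.
* Compartment boundaries (e.g. uvula, arytenoids) are anatomical judgments;
  the API takes them only as user-chosen slice indices.
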