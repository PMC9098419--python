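# Methods

`boneseg` implements a semi-automatic, gradient-based pipeline for isolating
a bone (patella-scale) from volumetric MRI or CT, together with the
validation protocol used to quantify its repeatability. This note records
the model, the parameters that matter, the numerical choices, and the
limits of what the synthetic experiments can show.

## Coordinate convention

Voxels are indexed `(slice, row, col)`, 0-based. Physical coordinates are

- `x = x0 + row * dr` — the in-plane row axis, oriented perpendicular to
  the articular face (anterior–posterior); the signed surface distance is
  measured along this axis,
- `y = y0 + col * dc` — the in-plane column axis,
- `z = z0 + slice * ds` — the through-plane axis (medial–lateral),

with spacing `(ds, dr, dc)` in mm. Cropping shifts the origin so retained
voxels keep their mm coordinates.

## Segmentation pipeline

1. **Edge detection.** Each slice is run through a Canny detector
   (Gaussian smoothing, Sobel gradients, non-maximum suppression,
   hysteresis). The user-facing threshold lives on a normalized 0–1
   scale: the hysteresis high threshold is that fraction of the slice's
   maximum smoothed-gradient magnitude, and the low threshold is fixed at
   0.4 × high, the conventional hysteresis ratio. Per-slice
   normalization is what lets a single threshold range serve a whole
   scan despite brightness variation; useful ranges are about 0.02–0.07
   for MRI and 0.15–0.25 for CT. The Gaussian standard deviation default
   is 1.0 px; a legacy value of 0.10 px is accepted but performs almost
   no smoothing, so 1.0 px is the recommended setting. The detector is
   a thin wrapper over scikit-image's Canny; the normalization constant
   is computed with the identical smoothing/Sobel pipeline so the
   fraction-of-max thresholds land on the magnitude scale the hysteresis
   actually sees.

2. **Seeded selection.** On a subset of slices (about one in five), an
   edit script — the scripted stand-in for interactive clicking — removes
   a few pixels to break 8-connections between the bone boundary and
   stray edges, then seeds the 8-connected components to keep.

3. **Propagation.** Remaining slices are processed outward from their
   nearest initialized slice; at equal distance the lower initializer
   wins, and a slice once assigned is never overwritten (which also makes
   repeated propagation a no-op). Each boundary pixel of the source
   slice pulls its nearest edge pixel (Euclidean pixel distance, ties
   broken by smallest `(row, col)`) on the target slice, capped by a
   search radius of 3 px. An empty result is recorded with a warning and
   propagation continues from the last non-empty slice.

   Because the pull is source→target and many-to-one, a propagated
   boundary is a subsample of the target's edge ring: it carries 1–2 px
   gaps, and gaps compound over propagation chains. Downstream code
   treats propagated rings as fragmentable (see *Meshing*).

4. **Auto-seeding from ground truth.** For phantom experiments the
   operator is emulated by `auto_seed_from_mask`: every n-th slice
   (default 5) receives one seed per edge component overlapping the 2-px
   dilated true bone boundary, plus removals that cut every 8-connection
   from those components to edges outside the band (any escaping path
   must pass through a removed pixel, so kept components stay in the
   band). With `dense_radius_px` set (the experiments use 2 px), slices
   whose cross-section shifts faster than that per slice — the poles of
   the bone, where the contour moves 4–10 px between slices — are seeded
   directly, exactly as a human operator initializes the fast-changing
   images near the ends of the bone.

## Meshing

Per-slice boundaries are rasterized to filled masks: the ring is bridged
by a morphological dilate→fill-holes→erode with a disk of radius 2 px
(retried at 3 and 4 px if the filled area falls below 60% of the ring's
convex-hull area, the signature of an unclosed ring). This rasterization
is deliberately independent of contour ordering, because propagated rings
are fragmented; the polygon-ordering operation (`order_contour`,
greedy nearest-unvisited-neighbour) remains available for clean rings.

The filled masks are stacked into a binary volume, padded, and smoothed
with a Gaussian of 0.7 voxel before marching cubes extracts the 0.5
isosurface in mm coordinates. The field smoothing serves two purposes:
it removes the voxel staircase (raw binary marching cubes overstates a
sphere's area by ~9%; with the field smoothing the error is ~1%), and it
eliminates the non-manifold pinch points that arise where mask pixels
touch diagonally, so the extracted surface is closed. Uniform Laplacian
smoothing (default 10 iterations, factor 0.5) finishes the mesh. The
identical post-processing is applied to every mesh that enters a
comparison, so its systematic effects cancel in signed distances.

## Validation metrics

- **Contrast** between bone and cartilage is
  `|I_bone − I_cart| / I_cart`.
- **Slice-weighted Dice** is computed on filled contour interiors (a
  1-px boundary Dice would be pathologically sensitive), per slice, and
  averaged with weight `|X_s| + |Y_s|` — the symmetric reading of
  "pixels present in each slice", which preserves Dice's symmetry.
- **Signed surface distance.** Both meshes are centered by subtracting
  model A's vertex-mean centroid. The analyzed region is model A's
  cartilage-adjacent vertices (within 1 mm of cartilage) after a
  *perimeter reduction*: the flagged vertices are projected on the y–z
  plane, their boundary polygon (convex hull — exact for the convex
  facet projections used here) is scaled about its area centroid by
  1 − fraction (default 25%), and only vertices projecting inside the
  scaled polygon are kept. This trims edge effects at the cartilage rim.
  Each surviving vertex gathers all model-B vertices within 2.5 mm; the
  signed distance is the difference of the two local patch means'
  x-coordinates, positive where model A is locally larger. Using model
  A's own patch mean (rather than the raw vertex) cancels the inward
  bias both patch averages share on curved surfaces: comparing a mesh
  with itself yields exactly zero, and a pure x-translation of a planar
  face is recovered exactly. On curved regions a residual
  second-order membership bias remains, proportional to the offset and
  the surface slope within the matching radius.
- **ICP registration** is point-to-point: centroid pre-alignment, then
  alternating KD-tree nearest-neighbour correspondence with the
  closed-form (SVD, reflection-rejecting) rigid fit, until the RMS
  residual changes by less than 1e-6 mm or 100 iterations. No trimming
  by default. The convergence basin comfortably covers the ≤ 10°, ≤ 5 mm
  misalignments exercised in tests; it is not a global aligner.

## The phantom

The bone is a superellipsoid, `|x/a|^e + |y/b|^e + |z/c|^e ≤ 1` with
`e = 2.5` and semiaxes `(22, 18, 14)` mm — patella-scale, with a facet
flatter than an ellipsoid's so the "perpendicular to the articular
surface" convention is axis-exact. Cartilage is a 3 mm shell over the
central 80% (by silhouette fraction) of the +x face; thickness is
measured along x, which on the flattened facet coincides with the normal
direction to first order, and the 80% cap keeps cartilage off the
equatorial rim as articular cartilage is. Ground-truth masks
(bone, cartilage, cartilage-adjacent bone surface) are rasterized from
the same analytic geometry and are independent of noise.

Modality profiles (voxel spacing `(ds, dr, dc)` mm; nominal intensities
bone/cartilage/background; additive Gaussian noise SD):

| arm | spacing | intensities | noise |
|---|---|---|---|
| T1-VIBE-like MRI | (0.7, 0.4, 0.4) | 5 / 100 / 40 | 2 |
| DESS-like MRI | (1.0, 0.3, 0.3) | 28 / 100 / 40 | 2 |
| CT | (0.6, 0.3, 0.3) | 1000 / 100 / 0 | 10 |

The MRI intensities make the bone/cartilage contrast 0.95 (T1-VIBE-like)
and 0.72 (DESS-like), the values typical of those sequences. Noise is
additive Gaussian, not Rician: the pipeline is gradient-based and the
simpler model keeps every oracle analytic; this is a deliberate
deviation from MR physics. No partial-volume averaging, bias fields, or
motion/metal artifacts are simulated — so passing phantom experiments
demonstrates the pipeline's internal consistency and geometric fidelity,
not robustness to those real-data effects.

A 6 mm background margin around the anatomy gives a T1-VIBE grid of
about 58 × 155 × 120 voxels; experiments crop to the bone's slices plus a
14 px in-plane margin before segmenting. "Scan/re-scan" is emulated as
two noise realizations plus a small rigid pose perturbation (0.5° per
axis, (0.3, 0.3, 0.2) mm) of the anatomy before rasterization, so the
second acquisition genuinely samples the tissue on a different grid.

## Phantom experiments

- `same_scan_repeatability` — one acquisition, segmented twice with the
  auto-seed slice grid offset by one; reports slice-weighted Dice and the
  signed surface distance over the perimeter-reduced cartilage region.
- `scan_rescan` — two acquisitions (noise + pose), ICP-registered.
- `mri_vs_ct` — the same anatomy at MRI and CT resolution/intensity
  profiles with modality-appropriate thresholds (0.05 vs 0.20),
  ICP-registered.

All randomness flows from the config seeds; re-running a config
reproduces every report byte for byte. Each experiment runs in a few
seconds on one CPU at the default problem size.

Typical magnitudes at the defaults: same-scan weighted Dice ≈ 0.998 with
mean signed distance within ±0.01 mm; scan/re-scan mean within ±0.03 mm
(dominated by sub-voxel quantization of the edge position under the pose
shift — the same mechanism that limits real scan/re-scan agreement);
MRI-vs-CT mean within ±0.03 mm.

## Known limitations

- Propagation quality degrades where the contour moves faster per slice
  than the search radius; the operator emulation compensates by seeding
  those slices, as a human would, but fully automatic end-to-end
  tracking of pole slices is out of reach of the nearest-pixel rule.
- The perimeter-reduction polygon is the convex hull of the projected
  region; for strongly non-convex cartilage regions a concave boundary
  (alpha shape) would be needed.
- The signed distance carries a small residual bias on curved, offset
  surfaces (membership slide of the 2.5 mm matching window); it vanishes
  on planar faces and cancels entirely at zero offset.
- ICP is local; initial misalignments beyond ~10–20° are not recovered.
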