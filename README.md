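# boneseg

Semi-automatic, gradient-based bone segmentation from volumetric MRI and
CT, with the complete validation protocol for judging how repeatable and
how accurate the resulting bone surface models are.

Manual slice-by-slice segmentation of bone from MR images is accurate
but takes about an hour per bone, which throttles orthopaedic studies
that need subject-specific bone and cartilage models. `boneseg`
implements the alternative: a Canny-edge-driven pipeline in which a user
initializes the bone boundary on roughly one of every five slices and
the algorithm propagates it through the rest of the stack, producing a
3D point cloud and a closed surface mesh. Everything interactive is
replaced by scripted edit lists, so runs are reproducible and the whole
pipeline can be exercised end to end on a synthetic knee-phantom.

## The method in brief

Per slice, edges are found with a Canny filter whose hysteresis high
threshold is a fraction *t* of the slice's maximum smoothed-gradient
magnitude (low = 0.4 high); *t* ≈ 0.02–0.07 works for MRI, 0.15–0.25 for
CT. On initialized slices the user (or script) keeps the 8-connected
edge components on the bone boundary; other slices receive, for each
boundary pixel of the nearest processed slice, its nearest edge pixel
within 3 px. Boundaries become point clouds (mm), and meshes via filled
contour masks → marching cubes → Laplacian smoothing.

Validation metrics:

- bone/cartilage contrast `|I_bone − I_cart| / I_cart`;
- Dice similarity `DSC = 2|X∩Y| / (|X| + |Y|)` per slice on filled
  contours, averaged with per-slice pixel-count weights;
- rigid ICP registration between models;
- signed surface distance: after centering and a 25% perimeter
  reduction of the cartilage-adjacent region, each model-A vertex is
  matched to the mean of model-B vertices within 2.5 mm and the signed
  difference of x-coordinates (x ⊥ articular surface) is reported as
  mean ± SD; positive means model A is locally larger.

The synthetic phantom is a superellipsoid bone (semiaxes 22 × 18 × 14 mm,
exponent 2.5) with a 3 mm cartilage layer on its flattened +x facet,
rendered at T1-VIBE-like MRI, DESS-like MRI, and CT resolutions and
intensities (bone/cartilage contrasts 0.95 and 0.72 for the MRI arms)
with seeded Gaussian noise, plus exact ground-truth masks. See
`docs/methods.md` for every assumption and parameter.

## Worked example

Run the same-scan repeatability experiment — one phantom acquisition,
segmented twice with the initialized-slice grid offset by one:

```sh
boneseg experiment --name same_scan_repeatability --seed 1 --out report.json
```

prints

```json
{
 "experiment": "same_scan_repeatability",
 "n_dice_slices": 40,
 "seeds": [1, 2],
 "surface_distance": {
  "matched": 2104,
  "mean_mm": -0.0070459800344844494,
  "region": "perimeter_reduced",
  "sd_mm": 0.025375164769790744,
  "unmatched": 0
 },
 "weighted_dice": 0.9978029195368148
}
```

Reading it: the two segmentations of the same 40-slice scan overlap with
a slice-weighted Dice of 0.998, and across the 2104 mesh vertices of the
perimeter-reduced cartilage-adjacent region the second model differs
from the first by −0.007 ± 0.025 mm along the axis perpendicular to the
articular surface — i.e., the pipeline's own repeatability error is an
order of magnitude below voxel size. The other experiments are
`scan_rescan` (two noise realizations plus a ≤ 1°/0.5 mm pose
perturbation, ICP-registered) and `mri_vs_ct` (same anatomy at MRI and
CT profiles).

Individual stages are also available as subcommands
(`simulate`, `detect-edges`, `segment`, `mesh`, `register`, `compare`,
`dice`), or directly from Python:

```python
from boneseg import default_spec, generate, detect_edges
vol, truth = generate(default_spec(), "MRI_T1VIBE")
edges = detect_edges(vol, high_threshold=0.05)
```

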