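# Methods

This note documents the models, parameters and numerical choices behind
`treereg`, what the synthetic scan simulator does and does not emulate, and
the known limitations of both.

## Setting and assumptions

Two terrestrial laser scans of one leafless tree, taken from stations on
opposite sides (~180° apart, ~2.3 m away), must be aligned by a rigid
transform. The package assumes:

* **Leveled scanner.** Both scans share the vertical axis (TLS instruments
  are leveled to well under a milliradian), so the unknown rotation is a
  single yaw angle plus a 3D translation (4-DoF). Clouds are never
  re-leveled; heights are signed distances to the fitted ground plane.
* **Single tree with ground included.** Coordinates in meters; the ground
  is a roughly horizontal surface at the bottom of each scan.
* **Tall-spindle architecture.** A dominant near-vertical trunk with short
  primary branches inserted at 50–90° — the geometry that makes the key
  ring (below) informative.

## Preprocessing

Order: ground-plane RANSAC → ground removal → statistical outlier removal →
voxel grid. Parameters (config block `preprocess`):

| parameter | default | meaning |
|---|---|---|
| `ground_dist_thresh` | 10 mm | RANSAC plane inlier distance |
| `ground_iters` | 1000 | plane hypotheses |
| `ground_max_tilt` | 20° | max plane tilt from horizontal |
| `ground_band` | 20 mm | points below this height are discarded |
| `sor_k`, `sor_std_mult` | 5, 0.1 | SOR neighbors and cutoff multiplier |
| `voxel` | 8 mm | voxel-grid centroid downsampling |

Two robustness choices in the plane fit are worth spelling out. Hypothesis
triples are drawn from the lowest 30% of the cloud (under a leveled scanner
the ground is the bottom-most structure; sampling uniformly starves the fit
when ground coverage is sparse). Candidate planes tilted more than
`ground_max_tilt` from horizontal are rejected: the visible half-shell of a
large trunk is nearly planar at the 10 mm scale and can otherwise collect
more inliers than the true ground. Both follow directly from the leveled-
scanner assumption; neither restricts sloped-but-plausible terrain within
the 20° budget.

The SOR cutoff is one-sided (keep mean k-NN distance ≤ μ + 0.1σ); a second
pass may remove further points (the filter is deliberately not idempotent —
removing the sparse tail changes μ and σ).

## Branch matching

* **Key region** `(0.2, 1.6) m` above ground: above the basal anchor zone,
  below the wind-prone crown. A trunk cylinder is RANSAC-fitted here with a
  vertical axis prior (max deviation 10°).
* **Key ring** `0.07–0.14 m` from the trunk axis: close enough to be
  wind-stable, far enough that branch–trunk junction irregularities are
  excluded, and likely to be visible from both stations.
* **Clustering**: Euclidean clustering with 12 mm tolerance (1.5× voxel so
  voxel-thinned surfaces stay connected), size gate [30, 2000] points. The
  lower bound is set from geometry: a visible branch segment in the ring is
  roughly a half-tube of radius r ≈ 7–16 mm and length ≈ 0.07–0.11 m; at one
  point per occupied 8 mm voxel that is ~25–75 points, so a bound much above
  ~30 would silently discard thin-but-valid primary branches while one much
  below admits fragments that cannot support a cylinder fit.
* **Cylinder quality gate**: inlier ratio ≥ 30% at a 4 mm distance
  threshold (5 mm for trunks, which taper).
* **Features**: r (fitted radius), θ = arccos|b·t| ∈ [0, π/2] (the absolute
  dot folds the sign ambiguity of fitted axis directions), h (height of the
  member-point centroid above ground).
* **Gate**: strict inequalities Δr < 5 mm, Δθ < 15°, Δh < 50 mm. A residual
  exactly at tolerance fails (the boundary convention must be fixed
  somewhere; strictness makes the gate the exact complement of the score's
  domain, where the normalized residual 1 has weight −ln 1 = 0).
* **Score**: normalized residuals are clamped to [10⁻⁶, 1−10⁻⁶] before the
  negative-log weighting (−ln is undefined at 0; a zero weight-sum is
  impossible after clamping). When all three residuals are equal the
  weights take their analytic limit 1/3 exactly, making the score equal the
  common residual.
* **Assignment**: greedy one-to-one in ascending score (each source and
  target branch used at most once), then the final pair is the accepted
  candidate with the largest *combined* (source + target) cylinder inlier
  count, ties broken by lower score. Summing the two inlier counts treats
  both fits as equally informative; a per-side maximum would let one
  well-sampled side mask a poorly-supported partner.

## Coarse registration

The matched branch axes are oriented to point away from their trunk axes
(making the rotation angle between their horizontal projections
single-valued), projected to the XOY plane, and intersected. Rotating by
the signed angle α about the vertical line through the intersection O maps
the source axis line onto the target axis line; the leftover sliding along
the line is absorbed by the translation stage. When the projections are
near-parallel (|sin α| < 10⁻³, i.e. α ≈ 0 or π) the intersection is
ill-conditioned and the rotation center falls back to the source trunk's
horizontal footprint. A vertical branch axis (projection shorter than 10⁻⁶)
aborts the coarse stage.

Translation: each scan's basal trunk slab (0.20–0.30 m above its own
ground plane) is fitted with a vertical-prior cylinder; G is the axis point
at 0.25 m height (the slab's mid-height — an axis point is preferred over a
point-centroid because one-sided visibility biases the centroid toward the
scanner by ~r·2/π, while the fitted axis is unbiased to first order).

## Fine registration

Branch-only trimmed point-to-point ICP:

| parameter | default | meaning |
|---|---|---|
| `overlap_ratio` | 0.90 | fraction of closest correspondences kept |
| `max_iter` | 50 | iteration cap |
| `rel_rms_tol` | 1e-5 | relative trimmed-RMS convergence threshold |
| `max_corr_dist` | 40 mm (5× voxel) | far-field correspondence cap |
| `trunk_margin` | 15 mm | trunk exclusion = axis distance < radius + margin |

Each iteration: exact nearest neighbors (KD-tree), keep the closest
⌈0.9·N⌉ pairs, drop pairs beyond `max_corr_dist`, closed-form SVD rigid
solve (reflection-corrected), accumulate. The trimmed RMS sequence is
non-increasing; iteration stops on relative change < 10⁻⁵, at an absolute
floor of 10⁻¹² m (exact alignment), or at `max_iter`. The refinement is
full 6-DoF: the 4-DoF restriction is a property of the coarse model, not of
the ICP, and residual sub-milliradian leveling errors are worth absorbing.

## Evaluation metrics

Rotation error via the axis-angle magnitude of R̃Rᵀ (trace argument clamped
to [−1, 1]; floating-point traces can exceed the range by ~10⁻¹⁶ and the
arccos has square-root-scale sensitivity near 0 — identity comparisons are
accurate to ~10⁻⁸ rad, not machine epsilon). Translation error is the
Euclidean distance of translation vectors. Pointwise error is the mean
distance between the two mappings of every source point; per-axis
components are means of *absolute* coordinate differences (reported
positive). Reporting units are mrad/mm/cm; everything internal is
radians/meters. Completeness is directional: the fraction of reference
points with a test-model neighbor within 5 mm. Structural parameters reuse
the matcher's ring-and-cylinder machinery over the full trunk height with a
relaxed cluster gate, counting primary branches with basal diameter > 1 cm
and no thicker than the trunk (first-order branches are thinner than their
parent stem; a larger fitted diameter is a degenerate grazing-cylinder fit,
not a branch).

## The synthetic scan simulator

`treesim` generates a procedural tall-spindle tree: a linearly tapered
near-vertical trunk (defaults 3.3 m, basal diameter 6.2 cm, 20% radius loss
per meter, 0.8° lean), 8–18 straight tapered branch frusta (basal diameters
1.4–3.3 cm, insertions 0.3–2.8 m at 50–90°, lengths 0.3–0.7 m, azimuths on
a jittered golden-angle spiral), and a flat ground disc. Surfaces are
ring-sampled at 2 mm with isotropic Gaussian noise (σ = 2 mm, matching the
2 mm spatial sampling and instrument accuracy class of orchard TLS
campaigns); the ground disc is sampled at 12 mm (a full-density ground
would dominate runtime without informing any stage past the plane fit).
Every point carries a semantic label, a branch id and an analytic outward
normal.

Two stations at 2.3 m and azimuths 0°/180° (scanner height 1.4 m, a typical
tripod) see the tree through a visibility operator: by default front-face
culling against the analytic normals (exactly reproducible); spherical-flip
hidden-point removal is available for harder fixtures. The target scan
keeps the tree frame; the source is mapped through the inverse of a sampled
4-DoF ground-truth transform (yaw uniform on (−π, π], ±2 m horizontal,
±0.2 m vertical), with an optional ≤ 0.5° roll/pitch jitter for robustness
studies.

What the simulator does **not** emulate: branch curvature (off by default so
the feature oracles stay closed-form), secondary branches/spurs and bark
roughness, inter-branch shadowing under front-face culling, beam-divergence
footprints, range-dependent noise, and wind deformation. Passing tests
therefore demonstrate correctness of the algorithms under idealized smooth
geometry, not field performance.

## Known limitations

* **Complementary-shell over-registration.** Front-face culling of a smooth
  straight tube from opposed stations yields two *exactly* complementary
  half-shells whose true overlap is confined to silhouette strips — about
  10% of branch points have a genuine counterpart within 5 mm at the true
  pose. The 90%-keep trimmed ICP objective is then lower at a pose that
  slides the source shells ~one branch diameter along the inter-station
  axis (measured: trimmed RMS 4.6 mm at the biased pose vs 10.6 mm at
  truth), and a correct implementation converges there: on the 20-pair
  synthetic suite the branch match succeeds in 20/20 trials and the fine
  rotation is recovered to ~3 mrad (median), but the fine translation
  retains a ~15 mm median bias that the coarse stage (median pointwise
  error ~7 mm) does not have. Aggressive trimming does not cure it (the
  8 mm voxel floor blurs the anchoring strips), and real dormant branches —
  curved, spurred, rough — do not present this worst-case geometry, which
  is why field deployments of branch-focused trimmed ICP report
  millimeter-level pointwise errors. Users of the simulator should read
  fine-stage translation numbers with this geometry in mind, or compare
  against the coarse pose.
* The 20° ground-tilt budget rules out steeply terraced terrain.
* One best-matched branch pair drives the rotation; trees whose candidate
  branches are geometrically ambiguous (similar r, θ, h) can match wrongly
  — mirrored in the two failure trees of the field protocol this package
  models — and the pipeline then reports failure rather than guessing.
* Trunks are modeled as straight cylinders during fitting; strongly swept
  or forked leaders violate the vertical-prior fit.
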