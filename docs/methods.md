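# Methods

`prosegvar` quantifies inter- and intra-observer variability of manual
versus semi-automatic 3D prostate-surface segmentation. Because the
clinical TRUS cohort behind the emulated study design is not publicly
deposited, the package pairs the analysis machinery with a synthetic
multi-expert cohort generator that reproduces the statistical structure the
analysis assumes; the only quantities reproduced *numerically* are the
cross-study effect sizes, which depend on printed summary statistics alone.
Everything else is reproduced as orderings and qualitative findings on the
synthetic cohort.

## Geometry and metrics

All coordinates are millimetres in an abstract right-handed frame; meshes
are closed triangle surfaces, annotations are sparse expert point sets with
three labelled landmarks (apex, base, posterior).

* **Closest point on mesh** is the exact point-to-triangle minimum over all
  faces. A KD-tree over face centroids prunes candidates; pruning is
  certified per query (a pruned face whose centroid lies farther than the
  current best distance plus the maximal centroid-to-corner radius cannot
  win), with an exhaustive fallback, so results equal brute force
  bit-for-bit. Ties go to the lowest face index.
* **ASD** (average surface distance) between points and a mesh is the mean
  unsigned closest distance. Mesh-to-mesh ASD defaults to the symmetric
  average of the two directed vertex-to-surface means: pairwise rater
  tables are order-free, so a symmetric value is required for them to be
  well defined; directed variants remain available for diagnostics.
* **Hausdorff** uses mesh vertices against the opposing full surface. With
  the tessellations used here (edge length well under 2 mm) the
  vertex-sampling error is far below the dispersion of any reported table.
* **Dice** is volumetric overlap on a voxelization of both watertight
  interiors. Voxel centers live on a single world-anchored lattice
  (default pitch 0.46 mm, the in-plane resolution of the source imaging),
  so two meshes voxelized independently share the grid; the interior test
  is z-column ray parity, exact for closed surfaces. A small fixed lattice
  offset keeps voxel centers off symmetric mesh coordinates.
* **Rigid alignment** is Kabsch with a reflection guard; similarity
  (scaled) alignment is optional and off by default for fitting (TRUS is
  metric) but on for registration to the reference shape (patient sizes
  vary).

## Statistical shape model and the two mesh methods

The SSM is generalized Procrustes alignment (rigid, no scaling) followed by
PCA of stacked vertex coordinates on shared topology. The retained mode
count is the smallest reaching 95% of total variance (default).

**Strict fit ("manual_SSM")** alternates: closest-point correspondence in
barycentric form, a ridge-regularized linear solve for the mode loadings
(clamped at ±3√λ, standard practice to avoid implausible shapes), and a
pose update. The ridge is scaled to the trace of the per-iteration design
matrix (1e-3·tr(DᵀD)/K) so sparse-point fits stay stable without shrinking
well-determined loadings. The reported objective (RMS point-to-mesh
distance) is non-increasing by construction: an iteration that fails to
improve reverts to the best iterate and stops. The output mesh lies in the
mode subspace exactly (re-projection residual ~1e-14 mm).

**Soft fit ("manual_soft-SSM" / the semi-automatic method)** starts from
the strict solution and adds a free-form deformation: a cubic B-spline
lattice (default spacing 10 mm) over the bounding box, minimizing the sum
of squared point-to-surface distances plus a bending energy
(sum of squared second differences of control displacements — a thin-plate
analogue with closed-form gradient) and a small zeroth-order ridge on
control displacements (1e-3). The ridge is needed because affine fields
lie in the bending operator's null space: with few attraction points the
solver would otherwise recruit a global shear at zero bending cost. The
deformation field is evaluated at the initial vertex positions, keeping
the objective linear-quadratic in the controls; each correspondence update
is followed by an exact sparse solve and a backtracking step, so the true
objective is non-increasing.

The default bending weight (10) was calibrated by ground-truth recovery:
mean ASD between the soft reconstruction and the true surface over
synthetic manual annotations at the default 1 mm noise improved up to
w≈10 and plateaued beyond. After later generator refinements the
calibration curve is flat (0.805–0.809 mm across w = 1–100), so the
default was left in place. The commercial algorithm this module stands in
for is proprietary; these constants are openly documented surrogate
choices with the same structure (shape prior + B-spline-regularized
deformation driven by user points), not a reimplementation.

## STAPLE-like mesh consensus

An EM fixed-point on corresponded meshes: initialize at the unweighted
vertex mean; iterate (E) score each input by its ASD to the current
consensus, (M) re-average vertices with weights ∝ 1/(d² + ε²), ε = 0.1 mm,
until the maximal vertex displacement falls below 1e-4 mm. The inverse
-square kernel is bounded and scale-free; a Gaussian kernel variant is
exposed for sensitivity analysis. Unlike voxel-probability STAPLE there
are no sensitivity/specificity rater parameters — reliability is purely
geometric.

## Statistics

Summaries are median and type-7 (linearly interpolated) quartiles.
Group contrasts use Shapiro–Wilk as a normality note and Wilcoxon tests
(signed-rank when paired), with Bonferroni correction over the three main
manual-method comparisons. Cross-study Cohen's d uses medians in place of
means where only medians are printed, σ ≈ IQR/1.35, and the unweighted
pooled SD sqrt((σ1²+σ2²)/2) — the only pooling variant that reproduces all
eight published values to two decimals, which is why it is the
implementation. Published summary statistics ship as a CSV fixture; one
source discrepancy (an intra-observer IQR printed differently in two
places of the source) is recorded in the fixture's note column, with the
results-section value used. Within-study effect sizes that would require
the unpublished SD of paired differences are not computed.

## Spatial variability maps

Manual annotations are registered to the model mean shape by landmark
similarity alignment plus closest-point projection. The density map is a
per-vertex Gaussian kernel sum normalized so its area integral equals the
point count; the ASD map is the kernel-weighted (Nadaraya–Watson) mean of
per-point distances, with vertices below a kernel-mass floor flagged
unobserved. The kernel is Euclidean at 5 mm bandwidth — prostate-scale
surfaces are near-convex, so geodesic refinement would change little.
Apex/base regions for summaries are geodesic caps of 25% surface area
around the landmark poles (the source design gives no numeric region
definition). The association between maps is summarized by Spearman rank
correlation over observed vertices.

## Synthetic cohort generator

The generator defines the study conditions; its defaults mirror the
emulated design: 100 patients, 4 experts, a shared manual subset of 12,
5 bis (repeat) patients, a 25-patient manual cap per expert, manual point
budgets of 90–496 per session and semi-automatic budgets of 39–77
(the observed per-expert ranges), 0.46 mm Dice voxels, 2 mm axial slice
spacing (a typical annotation spacing; the source states only the in-plane
pixel size).

* **Toy shape model.** Training shapes are triaxial ellipsoids (semi-axes
  U(15, 30) mm) with band-limited radial perturbations (spherical-harmonic
  degrees ≤ 4, peak amplitude ≤ 3 mm) on a shared icosphere topology
  (subdivision 3; 642 vertices). Sampled shapes have volumes concentrated
  in the prostate-plausible 15–90 mL range.
* **Ground truth.** A model sample (b ~ N(0, λ), clamped at ±3√λ) plus a
  high-frequency radial detail field (degrees 5–7, 1 mm RMS) the model
  cannot represent, under a small random rigid pose. The out-of-subspace
  detail is deliberate: it is the mechanism that separates the strict and
  soft mesh methods, rather than assuming the separation. Amplitudes of
  stochastic fields are RMS by convention (the training-shape bound above
  is a peak bound, honoring its stated ceiling).
* **Expert behaviour.** Each expert carries a smooth systematic radial
  bias field — three random spherical-harmonic bands of degrees 3–5 at
  1 mm RMS. The regional (not near-global) scale matters twice: raters
  disagree on specific zones of the gland, and such fields lie outside the
  span of the global shape prior, so rater bias contributes to
  inter-observer distances for every meshing method instead of being
  absorbed by the model subspace. Placement noise is iid N(0, 1 mm) along
  the local surface normal (boundary ambiguity and slice thickness move
  the perceived capsule in and out, so the error leaves the viewing plane
  slightly).
* **Manual sessions.** Points are sampled on axial slice contours at the
  configured spacing plus one medial sagittal and one medial coronal
  contour (10% of the budget each), with per-slice allocation proportional
  to contour length, thinned inside the apex/base z-caps by the pole
  -sparsity factor (default 0.6) — including on the medial slices, which
  cross the poles.
* **Semi-automatic sessions.** Landmarks are placed with the same
  noise/bias; the initial mesh is the shape prior (mean shape) posed on
  the landmarks — three points cannot determine mode loadings. Correction
  points are drawn from the expert's perceived boundary (surface samples
  displaced by bias + noise, thinned at the poles like manual points)
  where the current mesh error is largest, in batches of six; after the
  first batch the full two-stage fit (subspace solve + deformation) is
  re-run on everything accumulated, keeping the prior in play throughout
  the interaction, and subsequent batches re-run the deformation stage.
* **Design allocation.** All experts annotate the shared subset manually
  and semi-automatically; remaining patients are distributed round-robin
  (manual: one expert each up to the cap; semi-automatic: two experts
  each, so every patient supports a pairwise comparison); two experts
  repeat the bis subset semi-automatically, all experts manually.
  Everything is deterministic under (config, seed); the manifest carries
  both plus content hashes.

What the generator does **not** emulate: ultrasound image content and
speckle, pathology (median lobes), per-slice operator fatigue, or any
image-driven forces in the deformable model. Passing tests therefore show
that the *analysis machinery* reproduces the study's comparative structure
under its stated noise model — not that the numbers would match a new
clinical cohort.

## Pipeline and problem sizes

The study runner reconstructs every manual session with both mesh methods,
then builds the comparison tables (manual inter/intra per method, meshing
-method fidelity, semi-automatic pairwise and leave-one-out consensus
tables with ASD/Dice/Hausdorff, manual-vs-semi-automatic and
vs-consensus), runs the Wilcoxon/Bonferroni contrasts, and accumulates the
spatial maps. Manual inter-observer ASD is computed points→mesh exactly as
the source design specifies (a manual session has no intrinsic mesh); the
semi-automatic tables are mesh↔mesh. Comparison counts are audited against
the manifest.

Tests and the analysis scripts run the design at reduced size — typically
4–6 patients with all of them in the shared subset, chosen so the full
suite completes comfortably on one CPU — with every noise, bias, sparsity
and point-budget parameter at its default. Orderings among the tables, not
magnitudes, are the reproduction target at this scale. At the reference
acceptance seed the margins are: soft-SSM inter-observer ASD below strict
by ~0.01 mm (this contrast is intrinsically small under a 1 mm
out-of-subspace detail field and is the least stable of the five
orderings), intra below inter by 0.06–0.10 mm, fidelity gap 0.09 mm,
consensus below pairwise by 0.10 mm, and a clearly negative density–ASD
rank correlation.

## Known limitations

* Dense correspondence across meshes comes free from the shared synthetic
  topology; establishing correspondence on arbitrary clinical meshes
  (e.g., spherical parameterization) is out of scope, and arbitrary
  -topology consensus inputs are first re-parameterized by strict-SSM
  projection.
* The strict-vs-soft inter-observer contrast is small under the default
  study conditions (see above); on real data the published gap is an
  order of magnitude larger because the clinical shape prior misfits real
  anatomy far more than the toy prior misfits its own samples.
* The generator models polar under-annotation (density sparsity) but not
  polar boundary ambiguity (elevated placement error near apex/base from
  the slice increment and poor visibility). The density–ASD anticorrelation
  therefore emerges only from prior reversion in sparsely corrected
  regions, a contrast of the same order as sampling noise at the reduced
  cohort sizes: individual small cohorts can show weak or even inverted
  correlations.
* The deformable model is point-driven only; real semi-automatic systems
  also use image forces.
* Hausdorff is vertex-sampled; 95th-percentile variants are not provided.
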