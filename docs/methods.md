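# Methods

`vcohort` builds a statistical shape model (SSM) of the aortic root in
patients undergoing transcatheter aortic valve implantation (TAVI), expands
it into a virtual patient cohort for in-silico device trials, and links the
shape features to valve function and device sizing. This note records the
model, the numerical choices, and what the synthetic test bed does and does
not demonstrate.

## Inputs and representation

Each subject contributes two labeled point clouds in millimetres: the
aortic-root wall (annulus to mid-ascending aorta, open at both ends) and
the calcific plaques, assumed present on all three leaflets. STL and PLY
files are read through trimesh; STL carries no units, and coordinates are
interpreted as mm, the CT convention. Writes use ASCII STL or a
double-precision ASCII PLY because binary encodings truncate to float32,
which at coordinates of tens of mm violates the package's 1e-6 mm
round-trip guarantee.

Clouds are randomly subsampled (without replacement, seeded) to a working
resolution. Grid sufficiency is checked by the resolution-convergence
procedure: the pipeline is run at increasing point counts and the first
shape mode's explained-variance fraction is tracked; the resolution is
accepted at the first level whose relative change against the previous one
drops below 5%. The variance *fraction* is used because a "change in the
first mode" is otherwise unit-ambiguous. Full imaging resolution for this
anatomy is about 30,000 wall / 50,000 calcification points; the package's
defaults run well below that (2,000 / 1,500) so that the whole pipeline is
exercisable in minutes, and the convergence check is the tool for deciding
whether a chosen resolution suffices.

## Correspondence

The cohort is corresponded by the classic point-distribution-model chain:

1. **Global initialization.** ICP is a local optimizer, so each subject is
   first carried to the template by a deterministic canonical frame. Plain
   PCA axes are unreliable for near-tubular shapes (the transverse
   covariance is nearly degenerate), so the frame uses stable functionals:
   the long principal axis signed so the flared (ascending-aorta) end is
   positive, the centerline bend direction for the azimuth, and a
   right-handed completion. The residual leaflet-to-leaflet ambiguity of a
   nearly 3-fold-symmetric root is resolved by testing twelve rotations
   about the long axis and keeping the best closest-point cost.
2. **Rigid then similarity ICP** (Kabsch / Umeyama solves on KD-tree
   closest-point pairs). Iteration stops when the mean point displacement
   induced by the three most recent transform estimates falls below the
   tolerance — 0.01 mm for walls, relaxed to 0.2 mm for plaque-only
   alignment — with a hard cap of 120 iterations (a warning flag is set on
   the transform if the cap is hit).
3. **Non-rigid template warp.** The template is deformed onto each subject
   by a smoothed closest-point flow: each template point moves toward a
   *soft* correspondence (Gaussian-weighted average of its 4 nearest target
   points, kernel width proportional to the nearest distance — hard
   assignments flip discretely at Voronoi boundaries and would make the
   result unstable), and the displacement field is smoothed by a Gaussian
   kernel over the template. The bandwidth anneals geometrically from 5% of
   the template bounding-box diagonal down to the template's median point
   spacing over 10 iterations (coarse to fine); a fixed-bandwidth variant
   is available, whose large-bandwidth limit is a pure translation. The
   warped template keeps the template's point count and ordering, which is
   what creates the dense correspondence. This scheme is a deliberate
   stand-in for heavier non-rigid algorithms (Amberg-style optimization,
   coherent point drift): simple, seedless, and analytically testable.
4. **Mean-shape iteration.** To remove reference bias, the mean of the
   corresponded rows becomes the new template and steps 1-3 repeat until
   the mean moves less than 0.05 mm on average (cap 10 outer iterations).
   Two stabilizers are applied, both standard in generalized Procrustes
   analysis: the mean's centroid size is renormalized each round (otherwise
   the similarity-scale bias of closest-point matching compounds and the
   template drifts in scale), and the template update is damped by 1/2
   (the raw update can enter a period-2 limit cycle of correspondence
   flips). At coarse resolutions the iteration settles into a small
   residual limit cycle (~0.1-0.3 mm, about a tenth of the point spacing)
   rather than below the 0.05 mm tolerance; the cap then applies and a
   warning is emitted. This is a resolution effect, not a failure mode.

Rows are reported in a canonical template frame (mean centered at the
origin, axes from the stable-frame construction), which makes the cohort
matrix invariant (to ~1e-9 mm) under a common rigid motion of all inputs.
The similarity scale used during matching is undone on each row about the
template centroid, so subject *size* stays in the data and the first PCA
mode can capture it — matching the usual finding that mode 1 of an
aortic-root atlas is a scale factor.

Calcifications are corresponded after the walls: each subject's plaques are
carried into the wall template frame by that subject's wall transform, the
three 120-degree rotations about the root axis are searched (plaques sit on
three leaflets, so leaflet identity is ambiguous), and a plaque-only
rigid + similarity ICP at the relaxed 0.2 mm tolerance precedes the
template warp. Plaque correspondence across patients is a modeling
assumption, not an anatomical fact; a conditional model of plaque location
would be the proper generalization.

## The shape model

PCA on the corresponded rows: mean, orthonormal modes, eigenvalues with
divisor N-1, computed by SVD of the centered matrix for numerical
stability. Modes with eigenvalues below 1e-12 of the leading one are
discarded; each mode's sign is fixed so its largest-magnitude entry is
positive (signs are arbitrary; fixing them makes runs reproducible). A new
anatomy is `mean + sum_j w_j * sigma_j * phi_j` with weights in sigma
units.

Model quality: compactness (cumulative variance, and the smallest M
reaching a target fraction) and generalization

    GE(M) = (1/N) * sum_i || x_i - x_hat_i(M) ||,

the leave-one-out reconstruction error as a function of retained modes.
The norm is the per-point RMS Euclidean distance in mm so GE is
resolution-independent. Folds reuse the full-cohort alignment (no
re-registration per fold); re-registering each fold would be more
conservative but ~N times the cost.

## Virtual cohort generation

Virtual patients deform the mean along the modes retaining 90% of the
variance, with each weight drawn independently and uniformly from the
discrete grid {-2, -1.5, ..., +2} sigma (boundary 2, step 0.5). Uniform
over the grid is the least-informative reading of "random variation in
half-sigma steps"; wall and calcification weights are drawn independently
from one seeded stream so a whole cohort reproduces from a single seed.

Each draw is annotated with an occurrence probability — the one-sided
standardized upper tail at its largest per-mode deviation: 30.85% at 0.5
sigma, 15.87% at 1, 6.68% at 1.5, 2.28% at 2, 0.62% at 2.5, 0.135% at 3.
A +/- 2 sigma cohort therefore omits under 2.28% of per-mode shape
variation. A chi-square variant (squared Mahalanobis distance, k = 3
degrees of freedom) is exposed separately; it is a different quantity (its
2-sigma tail is 26.1%) and is not used by the sampler.

Visual inspection for folded or overlapping geometry is replaced by an
automated screen. With a triangulation: no intersection between
non-adjacent triangles (KD-tree-pruned pairwise tests) and face normals
agreeing with the mean shape's for at least 99% of faces. Without faces
(the usual case after resampling): local orientation via neighbor cross
products on the mean-shape k-nearest-neighbor graph, plus a
displacement-continuity test that flags any point whose displacement
deviates from its neighbors' average by more than 3 local spacings (this
catches single-vertex spikes). Calcification clouds are volumetric, so
only the continuity test applies to them. Rejected draws are resampled, up
to 50 attempts per shape. The thresholds (99%, 3 spacings) are tolerances
for numerical noise, chosen once from the geometry scales involved.

## Morphometric validation

Two declared conventions (the field does not standardize either):

* **Annulus diameter** — the wall is open at the annulus, so the most
  proximal cross-section rim defines the annulus plane. Because a curved
  root tilts the global principal axis away from the end cross-sections by
  tens of degrees, the local end direction is found by an iterated
  short-slab fit (a tube's short end slab is wider than long, so its
  smallest principal direction is the local axis), polished by a rim-ring
  plane fit. The rim band (default 1 mm; wider at reduced resolutions so at
  least one cross-section ring is captured) is projected on its best-fit
  plane and the convex-hull area A gives the TAVI-sizing convention
  2*sqrt(A/pi).
* **Calcification volume** — density clustering (DBSCAN, 2 mm neighbor
  radius, clusters under 20 points discarded) followed by per-cluster
  convex hulls, summed; a global hull would inflate disjoint plaques.

Cohort comparison uses the two-sided Mann-Whitney U test: exact by full
enumeration of group assignments when both groups have n <= 8 (ties handled
by direct pairwise counting; two-sided p = 2*min(tail probabilities),
capped at 1), the tie-corrected normal approximation otherwise. In the
pipeline's validation stage the real subjects are measured on their
*corresponded rows* rather than the raw clouds, so both groups share one
representation; the residual bias of the correspondence itself (the warp
erodes the open rim by roughly one point spacing at coarse resolutions) is
assessed separately by the generalization curve, not smuggled into the
cohort comparison.

## Shape-function learning

Mode scores are the projections `(x - mean) @ Phi` (mm). Pearson
correlations (two-sided t-based p) link individual modes to clinical
variables, with missing values pairwise-dropped.

The stenosis peak pressure gradient (AS-PPG, mmHg) is regressed on the six
modes with the largest |r| against it, by a polynomial-kernel support
vector regression inside a standardization pipeline (coef0 fixed at 1 so
even and odd polynomial terms both contribute). Hyperparameters (C
log-uniform in [1e-2, 1e3], gamma log-uniform in [1e-3, 10], degree in
{2, 3, 4}) are tuned by a small in-house Bayesian optimizer — a Matern-5/2
Gaussian process with expected-improvement acquisition over seeded random
candidates — minimizing the mean ten-fold cross-validated RMSE. Because
in-sample and predictive fit differ, R^2 is reported twice: out-of-fold
(cross-validated predictions; the honest predictive number) and
refit-on-all.

Device size (23 vs 26 mm prosthesis) is classified from the six modes with
the highest one-way ANOVA F-scores, by four families — multilayer
perceptron (one hidden layer of twice the feature count), logistic
regression, k-nearest neighbors (k = 5), and an RBF-kernel SVM — on a
stratified 70/30 split, reporting accuracy, per-class recall/precision,
confusion matrices, ROC curves and AUROC (decision-function scores where
available, class probabilities otherwise). All estimators are seeded;
results are bitwise reproducible per seed.

## The synthetic test bed

No patient data ship with the package; every stage is exercised against a
parametric emulator with known latent factors. A wall is a tube of varying
radius swept along a quadratic centerline: radius
`annulus * scale * (1 + sinus bump + flare)` with a Gaussian sinus bulge
(3-fold cosine modulation) near the annulus and an 18% sigmoidal flare
toward the ascending aorta. Calcification is three ellipsoidal plaques at
the leaflet azimuths. Latents (per-patient draws): global `scale`
(1.00 +/- 0.09), centerline `curvature` (8 +/- 2.5 mm), `annulus` radius
(12 +/- 0.9 mm), `sinus_width` (0.35 +/- 0.06), total `plaque_volume`
(800 +/- 250 mm^3), and `plaque_gap` (azimuthal spread, 0 +/- 0.12 rad).
These means put the annulus diameter near 24 mm — the boundary between the
23 and 26 mm prosthesis — and give realistic root proportions. Every
anatomy is emitted under a random rigid motion so alignment is genuinely
exercised, and the generator is bit-reproducible from its seed.

The clinical link draws the peak gradient as
`79.11 + sum_j slope_j * z_j + noise` over standardized latents
(slopes -7 scale, -6.5 annulus, +3.5 sinus, +5 plaque volume, +2
curvature, mmHg per SD; noise SD 8.97), calibrated so the population is
79.11 +/- 14.59 mmHg with ~62% of the variance latent-explained. Ancillary
variables (age 80.5 +/- 6.0 y, BSA 1.77 +/- 0.20 m^2, jet velocity via the
simplified Bernoulli relation v = sqrt(gradient/4), calcium score coupled
to plaque volume, and so on) use the study-population moments with simple
directionally-correct couplings. Device size follows a 24 mm threshold on
the true annulus diameter with 5% label noise. A `scale_dominant_config`
shrinks the non-scale anatomical SDs so mode 1 has an unambiguous
interpretation — the regime the latent-recovery benchmark assumes.

What passing the synthetic suite shows: the correspondence machinery
recovers planted transforms and generative latents; the PCA, sampling,
probability and testing math is correct against independent oracles; the
virtual cohorts it emits are statistically indistinguishable from their
training sets under the package's own morphometrics. What it does not
show: performance on real segmented anatomy (manual editing artifacts,
non-tubular pathology, bicuspid valves, plaques missing from a leaflet),
leaflet geometry (not modeled at all), or hemodynamics — the synthetic
clinical link is linear by construction, so the SVM's numbers here say
nothing about how nonlinear real shape-function relations are.

## Problem sizes and runtime

Defaults are chosen so the full nine-stage pipeline (68 patients, 2,000
wall / 1,500 calcification points, 100 virtual patients) completes in a few
minutes on one CPU; the test suite uses 12-30 patients at 300-700 points.
The acceptance script runs the pipeline at 68 patients with 1,200/900
points. Dense Gaussian smoothing is used up to 4,096 template points and a
64-neighbor truncated kernel beyond, so full-resolution (30k/50k) runs
remain feasible, just slower.

## Known limitations

* The non-rigid warp is a smoothed closest-point flow, not an optimized
  deformation model; open-boundary rims erode by about one point spacing,
  and correspondence sliding contributes a noise floor to the small
  eigenvalues at coarse resolutions.
* Calcification correspondence assumes three-leaflet plaque presence.
* The annulus and volume estimators are package conventions; absolute
  values depend on band width and clustering radius, so only
  like-for-like comparisons are meaningful.
* The mean-shape iteration's 0.05 mm tolerance is only reachable at high
  point densities; at reduced resolutions the iteration cap applies.
* Wall and calcification weights are sampled independently; real plaque
  anatomy is conditional on root anatomy.
* Virtual calcification volumes sit slightly below the training
  distribution: the mean of corresponded plaque clouds is more compact
  than any individual (correspondence blur cancels outward excursions),
  and truncating to 90% variance removes further spread, so a cohort
  centered on the mean shape inherits a small downward volume bias. The
  annulus diameter, which depends on a cross-section rather than a cloud
  envelope, does not show this effect. Depending on the seed, the
  Mann-Whitney comparison of plaque volume can flag the bias at n = 100.
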