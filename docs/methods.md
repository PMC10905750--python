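# Methods

## Scope and data model

The package analyses multichannel 3D volumes of neuromast-like
epithelial rosettes: a membrane channel, a nuclear channel, optional
marker channels, and nucleus/boundary *probability* volumes. The
probability volumes are treated as given inputs — in a real deployment
they come from trained detection models; here the synthetic generator
produces them directly. Training or running such models is outside the
package's scope, as is interactive proofreading (an externally edited
label volume can be substituted for any segmentation stage's output).

All label volumes are `(z, y, x)` integer arrays with voxel sizes in
micrometres; geometry code works in `(x, y, z)` micrometre coordinates.
Angles are degrees in `(-180, 180]` with the atan2 convention about +x.

## The synthetic rosette generator

`synthetic.generate_neuromast` emulates the tissue geometry the
analysis assumes, not microscopy physics (no PSF, no anisotropic blur
model, no time-lapse). Two parametric families define cells:

- **HC-like** — a solid of revolution whose radius profile is a beta
  function (exponents 1.2/2.2, peak at ~35% of height) times an
  ellipsoidal end-rounding, giving a flask: wide basal body, narrow
  apical neck, widest section below mid-height. Star-shaped about the
  centroid.
- **SC-like** — a tapered elliptical column with superelliptical
  end-rounding, an apical inward lean of 1.4 µm, and a sideways bow.
  The default bow (0.5 µm) leaves the cell star-shaped; the *concave*
  variant (bow 3.6 µm) is crescent-like and deliberately not
  star-shaped, so a known fraction of cells must fail the radial SH
  encoding and be caught by the exclusion QC.

Default family means (height 11/19 µm, radii 2.0/1.7 µm) were chosen
once as plausible for larval neuromast cells at 5 dpf and tuned only to
reproduce the qualitative contrasts the analysis tests: central flask
versus peripheral columnar shapes and dorsoventral versus peripheral
placement. Per-cell factors get ~5–7% lognormal-like jitter.

Placement is deterministic given the stream: HC-like cells on a
phyllotaxis disk at the centre (raised basally, as HC bodies sit
apically above SC bodies), SC-like cells on a middle and an outer ring.
Outer-ring cells are the "peripheral" subtype; middle-ring cells within
45° of the dorsoventral poles are the "DV" subtype. For perpendicular
organs the DV poles sit on the x axis (the organ is rotated 90° in the
image frame); the location adjustment below undoes this. Concave cells
are drawn preferentially from the middle ring — mid-radius, tall,
curved — which is where poorly parameterizable cells concentrate.
Infeasible requests (rings exceeding the organ radius, or overlapping
footprints) raise `PlacementError` with the offending counts.

Channels are blurred indicator functions on a unit intensity scale:
membrane = Gaussian-blurred label boundaries, nuclear = blurred nucleus
interiors; the probability maps are the same fields clipped to [0, 1].
Markers paint their truth-positive population (central → HC,
dorsoventral → DV subtype, peripheral → outer ring) in the nucleus or
whole-cell mask at unit amplitude times a per-organ gain
`max(1 + N(0, offset_sd), 0.2)`, emulating organ-to-organ reporter
brightness variation; additive Gaussian noise (`noise_sd`, default
0.05) goes on every channel. Nuclei are ellipsoids whose sections
follow the cell's own (possibly bowed) axis at 80% of the local
cross-section, guaranteeing strict containment; curved cells therefore
carry curved nuclei.

One `numpy` Generator seeded by `(seed, organ_index)` drives all
randomness, so identical calls are bit-identical.

**What passing tests on this generator does and does not show.** The
generator provides exactly the structure each stage is designed to
recover — separable shape families, per-organ marker offsets, a planted
concave fraction — with none of real data's confounds: no deconvolution
artifacts, no touching cells across organs, no segmentation-model
errors beyond additive noise, no partial-volume effects. Green tests
certify the machinery (correct formulas, determinism, recovery of
planted structure at realistic effect sizes), not performance on real
microscopy.

## Segmentation

Probability maps are binarized at 0.6 (nucleus) and 0.4 (membrane),
comparison `>=` (documented; the boundary-inclusive choice makes
binarization reproducible). Nucleus splitting zeroes nucleus voxels
under the membrane mask, optionally restricted to regions of interest.
Nucleus labeling: Euclidean distance transform → Gaussian smoothing
(`smoothing_sigma`, default 2 voxels) → `peak_local_max` seeds with
`min_seed_distance` (default 5 voxels) → watershed on the inverted
(unsmoothed) distance transform restricted to the mask. Seeds are
sorted lexicographically so ids and ties are reproducible. Cell
segmentation floods the raw boundary probability from the nucleus
seeds; cells keep their nucleus's id (they are deliberately not
renumbered after small-fragment removal, so the nucleus–cell pairing
survives). Connectivity is 6-neighborhood throughout, avoiding
diagonal leakage through one-voxel membrane gaps.

The flood needs a foreground support. When none is supplied it is
derived by hole-filling the thresholded boundary shell united with the
nuclei, then eroding by one voxel: a thresholded shell straddles the
true surface, so the filled region overshoots the tissue by roughly
the shell's outer half-width, and the erosion recentres it. The
default (1 voxel) matches the default synthetic shell geometry; users
with their own tissue masks pass `foreground_mask` directly.

`resample_isotropic` rescales depth by `z_spacing / xy_spacing`
(nearest-neighbor for labels, linear for intensities), producing cubic
voxels at the xy spacing — e.g. 0.22 × 0.05 × 0.05 µm data becomes
0.05 µm isotropic with 4.4× the slice count.

## Alignment and location

"Long axis" is the dominant eigenvector of the projected second-moment
matrix of the surface vertices, sign-fixed so the applied rotation is
at most 90°; near-isotropic projections (eigenvalue ratio within 1e-6)
skip their rotation with a flag. Cells' rotation 2 is uncapped;
nuclei's is capped at 45° (axis sent to x beyond that); rotation 3 is
capped at 45° for both (axis sent to y), which prevents horizontally
lying shapes from being flipped upright. The net rotation matrix is
stored so the inverse pose, and the ray directions used by the
field-based SH sampling, are exact.

Locations: d = xy distance to the organ centroid normalized by the
farthest cell's distance; o = the rotation-1 angle; a = o for parallel
organs and `wrap(o - 90°)` for perpendicular ones. The sign of the 90°
offset is a configuration switch (`perpendicular_offset_deg`): the
mapping is a circular isometry either way, and the chosen default maps
the perpendicular organ's poles onto those of parallel organs.
Geometric features are canonical-pose extents (width/depth/height =
x/y/z), voxel-count volume for digitized shapes (mesh volume
otherwise), and triangulated surface area.

## Spherical-harmonics encoding

The shape code is a single radius function about the centroid, sampled
on a Gauss–Legendre (colatitude, 64 nodes) × uniform (azimuth, 128)
grid and projected onto real orthonormal spherical harmonics
(Condon–Shortley phase) by FFT in azimuth and Gauss–Legendre
quadrature in colatitude. The quadrature is exact for band-limited
inputs, so the grid's only requirements are ≥ L_max+1 colatitudes and
≥ 2(L_max+1) azimuths; expand→reconstruct error is pure truncation.
Coefficients live in two (L_max+1)² grids (cosine and sine terms;
entries with m > l and sine terms with m = 0 are structurally zero),
serialized as (l, m, cos, sin) — 2178 numbers at the default
L_max = 32.

Two samplers produce the radius grid. Mesh ray casting
(`spherical_parameterize`) uses vectorized Möller–Trumbore with
spherical-bin candidate pruning; field ray marching
(`spherical_parameterize_field`) marches trilinear samples of a
smoothed voxel mask and interpolates the level crossing — equivalent
up to interpolation and much faster on dense marching-cubes meshes, so
the pipeline uses it, passing the alignment rotation to the ray
directions instead of rotating the volume. Both take the *outermost*
crossing on multi-crossing rays (keeping the surface closed) and count
those rays as star-shapedness violations. A centre outside the shape
(any ray with no crossing) is an error: the parameterization is
refused.

Reconstruction error is the directed Hausdorff distance from the
original surface points to the reconstruction, with the reconstruction
sampled both on a dense grid and along the original points' own
directions so the measure reflects shape disagreement, not sampling
density. The exclusion QC fits a 2-component Gaussian mixture to the
per-cell errors (fixed seed, k-means initialization) and flags cells
assigned to the higher-mean component; if the means are closer than
twice the larger component s.d. the distribution is treated as
unimodal and nothing is excluded. Nuclei — near-ellipsoidal, with far
lower errors — are never excluded.

## Shape space

PCA (full SVD) on the mean-centred coefficient table retains 8 cell /
4 nucleus components; cell and nucleus spaces are fitted independently
on their independently aligned shapes, the cell space only on
QC-retained cells. Component signs follow a fixed rule (largest-
magnitude loading positive) so mode semantics are reproducible; scores
are z-scored by dividing by the per-component standard deviation
(scores are mean-zero by construction, so no re-centring is needed).
Mode binning uses centres {−2, −1, 0, 1, 2} with half-width 0.5,
open-ended end bins, and boundary ties to the larger centre.
Rank-deficient input below the requested component count is rejected.

## Clustering and embedding

The kNN graph (default k = 30 in the library, smaller in desk-scale
pipeline configs; Euclidean in mode space) carries Jaccard
shared-neighborhood weights by default (uniform weights are a config
option). Leiden (RB-configuration objective, resolution 1.0, fixed
seed) partitions it; cluster ids are relabeled by ascending median
normalized distance d, so central clusters get low ids (ties by size,
then original id). Connectivity between clusters is observed
inter-cluster edges divided by their expectation under uniform random
placement of the graph's edges given cluster sizes; the 0.1 threshold
applies only when drawing, never to the stored matrix. UMAP is
initialized from a spring layout of the cluster graph (per-cell
positions at their cluster's node plus deterministic jitter) with a
fixed `random_state`, making the embedding reproducible and its global
arrangement anchored by the cluster graph. Representative cells
minimize Euclidean distance to their cluster's centroid (ties to the
lowest id).

## Markers and statistics

Mean intensities use the nucleus mask for nuclear-localized reporters
and the whole-cell mask for cytoplasmic ones. z-scores are computed
within each organ with the population (1/n) standard deviation;
positivity is `z >= 1` (the comparison and threshold are
configurable). Calls are invariant to per-organ affine intensity
changes with positive gain — the organ-offset problem the z-scoring
exists to solve. Group comparisons use Pearson's χ² without continuity
correction, dof = (r−1)(c−1), rejecting tables with zero expected
counts.

## Classifier

Exact stratified 80/20 split (per-class shuffle and round, so subset
class proportions match the population within one cell). Logistic
regression with a small ridge penalty (C = 1, lbfgs) keeps the fit
defined under perfect separation, which is flagged. ROC/AUC on the
test split; the confusion matrix thresholds predicted probability at
0.5. The idealized mean shape per class is the mesh reconstructed from
the class-mean mode vector.

## Pipeline and reproducibility

`run_pipeline` chains every stage over a list of organs (generated
with polarities cycling through the config, or supplied), producing a
single manifest table — one row per segmented cell; stages append
columns, never mutate them. Excluded cells carry nucleus-mode scores
but no cell-mode scores. Every random stage consumes the global seed,
and a rerun with an identical config writes a byte-identical manifest.
A provenance record (config hash, seed, QC counts) accompanies the
outputs; rerunning into the same directory with an unchanged hash
reloads the finished table instead of recomputing.

## Problem sizes

Tests, examples and the acceptance script run desk-scale organs — 12 to
16 cells, 16 µm radius, 0.4 × 0.2 × 0.2 µm voxels, two to three organs
per run — chosen so the full suite completes in minutes while every
statistical stage still sees the effect sizes it is designed for. The
generator's *defaults* keep the emulated study conditions (0.22 × 0.05
× 0.05 µm voxels, 40 cells, 23% HC, 16% concave); full-scale volumes
are simply larger and slower.

## Known limitations

- The radial SH encoding cannot represent non-star-shaped cells; they
  are excluded by QC rather than re-parameterized (signed-distance or
  other encodings are out of scope).
- Alignment is a fixed three-rotation sequence, not an optimization;
  rotation 3 can perturb the xz moments slightly, so re-alignment
  residuals are sub-degree for upright cells but can exceed 1° for
  extreme flat oblique shapes.
- The synthetic organ leaves interstitial space between cells, unlike
  confluent tissue; the foreground-erosion default compensates for the
  resulting shell overshoot and would be unnecessary with a real
  tissue mask.
- Cluster count depends on data and resolution; the package fixes the
  algorithmic contract (determinism, relabeling rule, connectivity
  formula), not a particular cluster count.
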