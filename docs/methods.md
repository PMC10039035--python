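# Methods

This note documents the models, conventions, numerical choices and known
limitations of the `otolith` package: what each stage assumes, which knobs
matter, what the synthetic generator does and does not emulate, and therefore
what passing tests do and do not establish about real data.

## Landmark scheme and superimposition

A full configuration has 108 points: 22 single landmarks (LM1–LM10 on the
bony vestibule — membrana-limitans attachments, the oval-window margin, the
spherical-recess border and the aqueductal point; LM11–LM16 on the membranous
organ walls; LM17–LM19 the utricular and LM20–LM22 the saccular macula
triads) and five semilandmark curves (SemiLM1 spherical-recess border,
SemiLM2 oval window — both bony; SemiLM3 utricle contour, SemiLM4/5 the
macular contours — membranous; 20+18+16+16+16 = 86 points). Point order is
the homology contract and is validated by label equality, never geometry.

Generalized Procrustes analysis scales each configuration to unit centroid
size (pre-scaling sizes are kept for the size regressions), aligns
iteratively to the recomputed consensus, and stops when the change in the
total Procrustes sum of squares falls below 1e-10 (at most 100 iterations);
the returned consensus is the plain pointwise mean of the aligned
coordinates. Reflections are excluded everywhere (rotations have det +1):
left/right labyrinths must be mirrored explicitly upstream, because
anatomical sidedness is meaningful. Tangent-space projection is *not*
applied before the multivariate statistics; raw Procrustes residuals are
used (shape variation in all test regimes is small, where the distinction is
negligible). Blocks are always split *after* joint superimposition, never
re-superimposed — relative position and size of bony vs membranous parts is
part of shape here.

Ordinary Procrustes distance is the root summed squared residual between two
unit-size, optimally rotated configurations; it is symmetric in its
arguments.

## Thin-plate splines and sliding

The 3D TPS uses the biharmonic kernel family with U(r) = −r. The sign is a
package convention: with −r the bending-energy quadratic form (the upper k×k
block of the inverted TPS system matrix) is positive semidefinite, so
energies are non-negative and zero exactly on affine maps; the interpolant
itself is identical either way. Systems are solved exactly; only if the
exact system is singular (degenerate sources) is a Tikhonov term (1e-8)
added, making interpolation approximate at that tolerance.

Semilandmarks slide along local curve tangents (central differences,
one-sided at the fixed endpoint anchors), by the linearized
bending-energy-minimizing update relative to the current consensus; slid
points are snapped back onto the current curve polyline by closest-point
projection (so a zero slide is exactly a no-op), slides are capped at the
local point spacing to stay inside the linearization's validity, GPA is
re-run after each pass, and passes stop on a relative energy change below
1e-6 (default 5 passes). A pass that would increase the energy is discarded
and sliding stops — the energy trace is non-increasing by construction.
Sliding minimizes bending energy, not Procrustes distance; endpoints are
anchored by default (configurable).

## Covariation statistics

- PCA: centered SVD; each loading's largest-magnitude element is made
  positive so PC1 regressions are sign-stable across runs.
- OLS: `scipy.stats.linregress`; the F statistic of the 1-df slope test is
  t², with the identical two-sided p.
- 2B-PLS: SVD of the cross-block covariance; r-PLS is the Pearson
  correlation of the first-pair scores; the null permutes specimen rows of
  block B; p uses the add-one estimator (1+#{≥obs})/(1+n perm), upper tail;
  the effect size z is computed on the raw statistic (no Fisher transform).
  Internally the permutation loop runs in the blocks' row spaces (thin SVDs
  reduce each permuted cross-covariance to an n×n problem), which changes
  nothing statistically and makes 10 000 permutations cheap.
- CR modularity: CR = ‖S_AB‖F / √(‖S_AA°‖F ‖S_BB°‖F) where ° zeroes each
  landmark's own 3×3 covariance block. Excluding whole within-landmark
  blocks (not just the scalar diagonal) is what makes CR invariant to
  rotations of the joint configuration, which Procrustes data require. The
  null reassigns landmarks (not coordinates) to modules of the original
  sizes; small CR indicates modularity, so p is lower-tailed.
- The RV coefficient is deliberately not provided: its strong dependence on
  sample size and variable count makes it a poor summary at n ≈ 12.
- Wilcoxon rank-sum comparisons wrap `scipy.stats.mannwhitneyu`: exact
  enumeration when both samples have n ≤ 8 without ties, otherwise the
  normal approximation with midranks and continuity correction.
- Multiple testing: the regression batteries report raw p-values; a
  Benjamini–Hochberg column can be added downstream but is off by default.

Interpretive caveat, relevant to real data as much as to the generator: the
CR landmark-permutation null assumes exchangeable landmarks. Spatially
coherent substructures — here, the macular discs, whose 19 points share a
center — look "modular" to CR even when a single factor drives everything.
On fully integrated synthetic data the CR test still flags the module split
in roughly a quarter of runs for exactly this reason. Single summary
statistics of landmark covariance should be read with this in mind.

## Maculae-plane analysis

Triad planes are exact (normalized cross products); surface planes are
total-least-squares (smallest principal direction). Angles are folded to
[0°, 90°] via the absolute normal dot product and are invariant to rigid
motion of a specimen; plane comparisons run in the original, unsuperimposed
specimen frames, because orientation *relative to bone* is the quantity of
interest. The spherical-recess "selection" is a supplied point set, never
auto-detected. The default eight pairings compare the two utricular bony
triads (LM2/4/6 and LM2/4/5) and the two saccular sources (LM8–10 and the
recess selection) against each macula's triad and surface.

## SPHARM modeling

Parametrization: vertices are normalized by the mesh's second-moment
ellipsoid and radially projected from the volume centroid
(ellipsoid-adjusted radial projection). This is exact for star-shaped
surfaces, spreads parameter density evenly over flattened shapes (the
utricle), and — important for correspondence — gives affinely related
specimens nearly identical parametrizations. If any spherical triangle is
flipped, damped spherical Laplacian relaxation with reprojection runs until
none is. This is a deliberate simplification of full area-preserving
optimization; it is validated by round-trip and orientation properties, not
by bit-parity with any external tool. Genus-0 topology is enforced (Euler
characteristic 2, watertight).

Basis: orthonormal *real* spherical harmonics, ordered l = 0..L, m = −l..l,
without the Condon–Shortley phase; fits are least squares per Cartesian
coordinate, weighted by per-vertex area on the parameter sphere, and require
(L+1)² ≤ vertex count. Default degrees: vestibule 25, saccule 25, utricle 15
(the oblong utricle destabilizes higher degrees). A side effect of the
ellipsoid-adjusted parametrization is that ellipsoids are represented
*exactly* at degree 1.

PDM sampling evaluates the series at linear icosahedral subdivisions: level
s splits each icosahedron edge into s+1 parts, giving 10(s+1)²+2 directions
(level 0 = the icosahedron's 12; level 15 = 2562). Identical levels give
identical directions — the correspondence contract. Correspondence across
models aligns each model's degree-1 ellipsoid map onto the *first* model's
by a rotational Procrustes fit; this avoids per-model axis ordering and sign
conventions, which are unstable when two ellipsoid axes are nearly equal
(the vestibule's are). Rotations are baked into the coefficients by a dense
least-squares refit of the rotated band-limited function (exact up to solver
tolerance), so no Wigner rotation matrices are needed. Nearly spherical
degree-1 parts fall back to identity with a warning.

Taubin smoothing alternates λ = 0.5 shrink and µ = −0.53 inflate steps
(default 10) with uniform Laplacian weights; boundary vertices of open
meshes are pinned.

## Model assembly and reconstruction

Mean SPHARM meshes are registered onto the consensus landmark configuration
(expressed in mm via the mean centroid size) by closed-form least-squares
similarity transforms on per-structure fiducials (vestibule: LM1–10;
utricle: LM11–13 + 17–19; saccule: LM14–16 + 20–22). Macular wireframes are
the consensus SemiLM4/SemiLM5 contours. The perilymphatic negative-space
mesh rasterizes all three meshes on one voxel lattice (default 0.05–0.12 mm
pitch depending on context), subtracts organ voxels from vestibule voxels
(organ voxels outside the vestibule raise a containment error with a count),
and extracts the boundary by marching cubes; the voxel-count volume is kept
as metadata. Voxel booleans match the labelmap workflow the analysis chain
emulates; exact mesh CSG is deliberately not used.

Reconstruction fits a TPS from the model's ten bony landmarks to a target's
and carries the mean organ meshes through it; the bony landmarks are
interpolated exactly, and global similarity changes are reproduced exactly
(TPS affine exactness). Validation distances are one-directional
(modeled → original) closest-point point-to-triangle distances; the
inter-specimen baseline registers every specimen onto the first by
similarity on the single landmarks and pools all ordered pairwise organ
distances. Distances below 1e-12 mm are clamped to zero so degenerate
comparisons tie instead of ranking floating-point noise. Point-to-triangle
queries use a KD-tree candidate prefilter with a provable exactness bound
(verified bit-identical to brute force).

## The synthetic generator

The generator is the package's study-condition definition: 12 specimens by
default, full 108-point scheme, genus-0 mesh trios (vestibule semi-axes
3.0/2.5/2.2 mm enclosing a flattened oblong utricle 1.7/1.0/0.5 mm and a
sac-like saccule 0.9/0.75/0.65 mm — arbitrary-unit shapes scaled to
plausible millimetres, not measured anatomy).

Deformation model. One smooth shared field S — a TPS interpolant through
random displacement vectors at the ten bony landmark nodes — displaces both
tissues, scaled per block by factor scores α_bony = a f + b g and
α_memb = a f + b h (f, g, h independent standard normals, a² + b² = 1;
requesting regression R² = r sets a = r^{1/4}, since block PC1 scores are
proportional to the αs and corr = a²). Membranous points additionally
displace along a membrane-local field T (a TPS through the membranous
landmark nodes) with RMS `membrane_local_ratio` (default 0.5) times the
shared field's membranous RMS — the part of membranous variation no bony
landmark can predict. Because S is a TPS through the bony landmarks
themselves, the shared membranous component is *exactly* the warp a
bony-landmark TPS reconstruction produces: bone genuinely carries the shared
deformation, as the anatomy the pipeline targets would. Both patterns are
projected to have zero similarity-mode (translation/rotation/scale) response
over their own block; without this, joint GPA transfers a trace of one
block's factor score into the other block's aligned coordinates and the
2B-PLS null rejects at several times its nominal rate. Matching log-size
factors (sd `size_amp` = 0.015) scale each block about its center with the
same scores.

Maculae. Each specimen's macular planes are constructed by rotating its bony
triad planes (LM2/4/6, LM8/9/10) by `plane_offset_deg` (default 4.6°) plus
noise about the planes' common perpendicular axis — so in the noise-free
generator the bony-vs-macular approximation angle equals the offset
*exactly*, and setting `angle_r2` calibrates the offset noise against the
empirical bony inter-plane angle variance to hit a requested inter-macular
angle regression R² exactly in expectation. Triad and contour points get
additional per-point *in-plane* displacements (plane offsets stay exact).
LM5 is constructed ~4° off the LM2/4/6 plane, so triads that include it
approximate the macula strictly worse — the aqueductal-point analog (LM6) is
the better landmark by construction. The null covariance mode ties macular
plane orientation to jittered copies of the *base* planes instead, because
plane tethering is itself bone–membrane covariation.

Covariance modes. `integrated` (default): shared factor at the requested
R²; the boundary value r² = 1.0 means one exact shared factor. `modular`:
independent greater-utricle and greater-saccule factors (bony LM1–6 with the
membranous utricle units; bony LM7–10 + SemiLM1/2 with the saccular units)
plus a small shared component (`modular_shared_frac` = 0.25). `null`: no
shared factor, no shared size variation, no global scale jitter, decoupled
maculae — under joint-GPA shape space those channels *are* covariation, so a
generator claiming none must exclude them.

What the generator does not emulate: real segmentation/staining artifacts,
fixation shrinkage, true anatomical shape detail (the organs are deformed
ellipsoids), observer-dependent landmark error structure (noise is iid
isotropic), or the absolute millimetre reconstruction errors of real
specimens. Passing tests therefore establish that the *machinery* is
correct and calibrated under controlled conditions — not that real bone
predicts real membrane; that is an empirical claim about data.

## Calibration results and problem sizes

The test suite verifies, at desk scale (chosen once as the package's default
experiment sizes):

- OPA equals an independent rotation-space optimizer on 50 random pairs to
  1e-6; GPA is invariant to input similarity transforms and its sum of
  squares is non-increasing.
- TPS interpolates landmarks to 1e-8 and reproduces 100 random affine maps
  with bending energy ≤ 1e-10; coefficients match a directly assembled dense
  solve.
- Sliding's bending-energy trace is non-increasing, and a re-parametrized
  curve recovers toward the consensus.
- Under the null generator (600 replicates, 199 permutations, n = 12) the
  PC1 regression and 2B-PLS rejection rates sit in [0.03, 0.07]; the CR test
  holds the same band on the landmark-exchangeable null variant (iid
  landmark noise only — the only regime where its permutation null is
  exact). Under the r² = 0.5 generator the recovered R² over 20 seeds is
  within ±0.15 of target.
- Noiseless plane offsets of 5°/10°/30° are recovered to 1e-9; with default
  noise, per-seed mean recovered angles stay within ±1° of 4.6°; the
  least-squares plane matches a refined direction-grid search within 0.1°.
- Spheres are exact at SPHARM degree 1; the RMSE ladder over degrees
  1,2,3,4,5,10,15,25 is monotone non-increasing; known radius coefficients
  round-trip within 1e-3 relative; the mean of concentric spheres is the
  mid-radius sphere to 1e-6.
- Similarity fits recover noiseless transforms exactly; the perilymphatic
  shell volume of concentric spheres at 0.02 mm voxels is within 3% of the
  analytic value; an identity warp reproduces the model organs to 1e-10; and
  in the five-specimen efficacy design (population, consensus, SPHARM sample
  and validation targets all the same five specimens, mirroring an n = 5
  efficacy test) the reconstruction-error median beats the inter-specimen
  median with rank-sum p < 0.05 in ≥ 90% of 20 seeds.
- Two end-to-end runs with one seed produce bit-identical report bundles.

## Known limitations

- The spherical parametrization is the ellipsoid-adjusted radial map, not a
  full area-preserving optimization; strongly non-star-shaped or
  high-curvature surfaces may fail to untangle (an error is raised, never a
  silent bad fit).
- PDM correspondence rests on the first-order ellipsoid plus parametrization
  consistency; across very dissimilar shapes the corresponded points drift
  tangentially, blurring mean shapes.
- CR's landmark-permutation null mis-sizes in the presence of coherent
  landmark clusters and after superimposition of strongly structured data
  (see the interpretive caveat above).
- The efficacy test's inter-specimen baseline uses landmark-based similarity
  registration, a documented substitute for surface-based registration.
- Only curve semilandmarks are implemented (no surface sliding), and only
  two-module CR contrasts.
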