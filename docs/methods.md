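# Methods

This note documents the models implemented in `stimmap`, the parameters that
matter, what the synthetic generators do and do not emulate, and the
numerical and design choices made where the construction was genuinely open.

## Volume-conductor model

Both stimulation modalities are treated quasi-statically: tissue is a purely
resistive, isotropic conductor, capacitive and inductive effects are
neglected, and the 0.2 ms DES pulse is modeled as DC.  The head is a labeled
voxel grid (0 background, 1 skin, 2 skull, 3 CSF, 4 grey matter, 5 white
matter, 6 tumor) with a NIfTI affine; all world coordinates are RAS in mm,
voxel indices 0-based, intervals half-open.  Conductivities (S/m): skin
0.465, skull 0.010, CSF 1.654, GM 0.2765, WM 0.126; glioma tissue is assigned
the grey-matter value.  The stock phantom is a 5-layer concentric sphere with
outer radii (92, 86, 80, 78, 70) mm at 2 mm spacing — conventional
layered-sphere head dimensions, declared rather than derived, since no
subject geometry is available or wanted here.  At 2 mm the CSF shell is one
voxel thick; the construction warns about under-resolved layers but builds
them faithfully.

The elliptic problems are discretized in conservative finite-volume form:
fluxes live on voxel faces with harmonic-mean face conductances, which makes
the operator symmetric positive (semi-)definite and guarantees discrete
current conservation to the solver residual; a zero face conductance at the
conductor boundary *is* the zero-normal-current condition.  Systems are
solved with Jacobi-preconditioned conjugate gradients to relative residual
1e−8 (configurable); the pure-Neumann TMS system is gauged by pinning one
node and removing the mean afterwards (its right-hand side sums to zero
exactly by construction, because the source term is assembled from the same
face fluxes).  Gradients are reconstructed per voxel by averaging the face
differences of its conductive faces; cell-centered fields are therefore
first-order accurate at boundaries and second-order inside.

### TMS

The figure-8 coil is a pair of coplanar, oppositely wound wings (default
wing radius 35 mm, wing-center separation 70 mm, 10 mm standoff above the
scalp).  Each wing is modeled as a *uniform sheet of magnetic dipoles*
sampled on three concentric rings with area weights — the magnetostatic
equivalent of the rim current loop.  A bare ring of dipoles, although simpler,
puts the primary-field maximum 16 mm off the junction and was rejected for
that reason; with the sheet model |E_p| peaks directly beneath the junction,
as a figure-8 coil must.  Stimulation intensity is an arbitrary linear scale
(`rate`, default 1e7 s⁻¹): no coil-current waveform is modeled, and every
downstream comparison (CoG, overlap) is scale-free or threshold-relative.

### DES

Electrodes are voxelized balls (a sub-voxel ball inflates to its nearest
conductive voxel) held at fixed potential: ±1 contrast for the bipolar pen
(default, 1 mm balls 4.4 mm apart), or anode vs a remote return region for
the monopolar mode (the inferior slab of the model, the full outer boundary,
or an explicit mask).  The solution is rescaled so the net discrete current
leaving the anode equals the configured intensity (1–6 mA); this
normalization also absorbs the geometric error of electrode voxelization.
Both drive modes are provided because the clinical description covers both;
bipolar is the default.

## Accuracy, verified against independent closed forms

The test suite carries its own oracle implementations (spherical-harmonic
series for a tangential magnetic dipole over a spherically symmetric
conductor; Legendre series for point sources in grounded homogeneous and
two-layer spheres; brute-force enumeration for the trial rule).  The
discretization facts a user should know:

- **Staircase boundaries dominate the error budget.**  Field accuracy is
  quoted over the *grid interior* (voxels whose six neighbours are all
  conductive): there the TMS solve matches the series solution to a few
  percent relative L2 at 2 mm spacing, while the single staircase boundary
  layer carries O(1) local geometric error that does not represent solver
  failure.  The same applies to internal tissue interfaces: with the head's
  conductivity contrasts (up to 165×) a spherically-symmetric relabeling
  changes the interior field by several percent at 2 mm — a resolution
  artifact that shrinks with spacing and nearly vanishes (<1 %) at ≤2×
  contrast — although the continuum field is provably unchanged.
- **Potentials near point-like sources** are compared shell-averaged, which
  suppresses the lattice anisotropy of the 7-point stencil; an unbounded
  medium is represented by a grounded sphere and the comparison uses the
  grounded-sphere closed form I/(4πσ)(1/r − 1/L), whose 1/L term is the
  potential reference, not a fit.
- Current conservation and normalization are exact to the solver residual;
  σ-scaling invariance of the TMS field and bipolar reciprocity hold to
  1e−9.

## Hotspots, CoG and the overlap metric

A site is positive iff its outcome sequence contains ≥3 consecutive
interruptions (verified exhaustively against enumeration up to length 8).
CoG reductions use uniform weights for site lists (sites carry no amplitude)
and |E| weights for field maps; field-map CoGs are meaningful over a
stimulation area (e.g. the half-max sub-patch), since weighting an entire
closed surface pulls the centroid into the interior.

**Overlap.**  The published comparison — "the percentage of the nTMS
stimulation area included in the area of the DES field in a DES-determined
ROI" — leaves both thresholds and the ROI construction unspecified.  Two
constructions are implemented:

- *ROI-coverage* (package default): the nTMS stimulation area is its
  half-max isocontour on the GM surface; the DES stimulation area is the
  DES-determined ROI itself, a 20 mm-radius disc centered on the DES hotspot
  CoG.  overlap% = area(nTMS area ∩ ROI)/area(nTMS area)·100.  This is the
  construction under which co-located targets *can* score 100 % and which
  degrades monotonically with displacement.
- *Per-field half-max* (`des_mode="fraction"`): the symmetric rule — both
  fields thresholded at 50 % of their in-ROI maximum, overlap measured
  within the ROI.

The symmetric rule cannot reproduce the clinical ≥90 % figure even in
principle: a ball electrode's field decays like 1/r² (1/r³ bipolar), so its
half-max area is a few voxel faces, orders of magnitude smaller than the TMS
half-max area it would have to cover.  The ROI-coverage rule is the
scientifically meaningful default, but on a *smooth spherical* phantom it
also stays far below 90 %: the figure-8 half-max area at ~24 mm depth is
~14 cm², elongated ±30–45 mm along the junction axis, and no 20 mm disc can
contain it.  The clinical ≥90 % depends on folded cortical geometry — real
gyri concentrate the TMS field onto the crown nearest the coil, shrinking
and co-locating the stimulation area with the DES site — which the spherical
phantom deliberately omits.  The two acceptance tests that encode the ≥90 %
(and the degenerate-cohort 100 %) expectation are therefore left failing by
design; a passing result on this phantom would indicate a tuned, not a
faithful, metric.  What the passing tests *do* establish is the machinery:
thresholding, area bookkeeping, ROI handling, scale invariance and the
expected monotonic degradation with coil displacement.

## Tractography

Deterministic streamline tracking: component-wise trilinear tensor
interpolation, eigen-decomposition at each step, principal eigenvector with
sign kept coherent with the incoming direction, Euler steps of 1 mm (half
the 2 mm voxel), 45° turning limit, seeds on the voxel-center lattice within
5 mm of the CoG.  The stopping threshold implements the clinical convention
"0.1 as well as 50 % of the individual FA threshold" as
max(0.1, 0.5·FAmax), with FAmax the FA maximum within twice the seed radius
of the seed point — reading "individual FA threshold" as the individual's
local FA maximum; the alternative reading (an individually calibrated
threshold) has no operational definition here.  Streamlines shorter than
20 mm are discarded.  Tracking is seed-lattice deterministic: no randomness
anywhere.

Synthetic bundles are flat-ended tubes (straight, or quarter-circle arcs)
of cigar tensors aligned with the centerline tangent; eigenvalues are solved
in closed form from the target FA at fixed mean diffusivity 0.7e−3 mm²/s
(λ_axial = MD(1+2c), λ_radial = MD(1−c), c = FA/√(3−2FA²)).  Corridor
membership is half-open along the centerline so that, with trilinear
interpolation, the tracked length reproduces the nominal centerline length
to about one integration step.  Defaults: corridor radius 4 mm, inside FA
0.8, background FA 0.05 (below the 0.1 floor, so tracking cannot escape).

## Group statistics

Summaries are mean ± SD (n−1 denominator).  The default independent test is
Welch with Satterthwaite degrees of freedom — robust to unequal variances
and consistent with the published preoperative WAB p-value to rounding
(0.659 vs 0.658 printed).  The published *postoperative* p (0.0321 for
78.4 ± 10.4, n=9 vs 59.5 ± 8.8, n=7) is not consistent with any standard
t-test on those summaries (Welch and pooled both give ≈0.002); the package
computes and reports the standard result and does not attempt to reproduce
the printed value.  Similarly, the printed 95 % CI of 3.9–8.7 mm for the CoG
distances is not the t-interval of (6.32, 2.6, n=9); `confidence_interval`
implements only the standard formula.  A permutation test (Welch statistic,
10⁴ resamples) serves as an independent cross-check in the tests.

## Synthetic data: what it does and does not show

All generators are pure functions of (spec, seed) and return ground truth
with the data.  Cohorts place DES sites uniformly on a 25° cap of the GM
sphere and displace each subject's nTMS sites by a single tangent-plane
vector with truncated-Normal(6.32, 2.6) norm — one displacement per subject,
so the paired CoG distance equals the drawn norm exactly and parameter
recovery is a sharp test.  Five sites per subject is a typical clinical
mapping yield; the value only affects geometry, not the distance statistics.
Trial records are Bernoulli sequences; WAB scores are Normal draws at the
published group summaries (clamping to the 0–100 scale is off by default so
summary recovery is exact; the means are far from the bounds).

None of this emulates cortical folding, realistic AF/SLF geometry, lesion
mass effects, or outcome distributions beyond two-moment summaries.  Passing
tests therefore demonstrate that the *pipeline* is correct and statistically
calibrated under its stated model — not that the clinical effect sizes would
be recovered from real images.

## Problem sizes

Default analyses run on: the 97³ phantom grid at 2 mm (~4·10⁵ conductive
voxels per field solve), an 81³ sphere for the TMS oracle, 81³ at 1.5 mm for
the DES oracles, 9-subject cohorts, 10⁴-site trial simulations, 10⁴
permutations, 2000 CI-coverage and 1000 power replicates, and a 3 mm grid
for the end-to-end determinism runs.  These sizes were chosen so the full
validation remains a desk-scale computation; every one of them is a
parameter, not a constant.
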