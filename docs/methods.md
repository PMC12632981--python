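# Methods

This note documents the models, numerical choices and known limitations of
`hippodti`, in the spirit of a software methods appendix. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Laplace coordinate fields

The grey-matter domain is a labelled voxel grid. For each axis (AP, PD, IO)
we solve the discrete Laplace equation with the standard 6-neighbour
finite-difference stencil, weighted by 1/h² per grid axis for anisotropic
spacing. Labelled boundary voxels are Dirichlet anchors *at their voxel
centres* (source ψ = 0, sink ψ = 1); neighbours outside the solved set are
treated as zero-flux by dropping them from the stencil (mirror condition),
which keeps the coordinate flat along free walls. Center-anchoring makes a
slab with source plane x = 0 and sink plane x = L reproduce ψ = x/L
exactly, which pins the convention.

Two solvers share the stencil:

* **Red-black Gauss-Seidel with successive over-relaxation** (default;
  ω = 1.8, convergence when the largest absolute update in a sweep falls
  below `tol`, default 1e-6). Red-black ordering is a Gauss-Seidel variant
  chosen because it vectorises; the converged solution is independent of
  sweep ordering (tested), and fixed inputs give bit-identical output.
* **Sparse direct** (`method="direct"`): SuperLU factorisation of the same
  linear system, used when a near machine-precision residual matters more
  than memory.

Gradients use central differences on interior voxels and one-sided
differences where only one neighbour carries a value (Dirichlet voxels
participate, giving correct one-sided stencils at walls). The voxel-index
gradient is mapped to world space via the inverse-transpose of the affine's
3×3 block, then unit-normalised; magnitudes below 1e-8 are flagged invalid
and excluded downstream rather than imputed.

**Discretisation accuracy.** Voxelised Dirichlet walls are jagged: on an
annulus with walls clamped just outside radii (r0, r1) = (8, 14) voxels,
the solution deviates from the closed form ln(r/r0)/ln(r1/r0) by up to
~0.06 (the effective wall sits ~0.3 voxel outside the nominal circle).
This is a property of the voxelisation, not the solver — the error falls
roughly linearly with refinement (tested), reaching ~0.015 at
(r0, r1) = (64, 112). The acceptance script therefore evaluates the
annulus agreement at that refined resolution; the coarse-grid behaviour is
asserted at its measured level in the unit tests. Phantom grids place the
cylinder axis on a voxel *corner* so no voxel centre falls exactly on a
wall circle, which would otherwise create degenerate clamping.

## Tensor model

`S = S0·exp(−b·gᵀDg)` with b in ms/μm² and D in μm²/ms. Fitting is
log-linear least squares with a design built from the b-matrix
(lower-triangular component order Dxx, Dxy, Dyy, Dxz, Dyz, Dzz); the
default estimator is the standard two-step WLS (OLS pass, then weights
equal to squared predicted signals), with plain OLS behind a flag. The fit
requires ≥ 6 unique non-zero directions (antipodal pairs counted once) and
≥ 1 b = 0 measurement. Voxels with any non-positive signal are excluded
rather than clamped, negative eigenvalues are retained but flagged
`non_spd` (silently clamping would bias MD), and λ1 − λ2 < 1e-9 flags a
degenerate V1 that is excluded from orientation metrics. V1 has no
physical sign; a deterministic sign convention (largest-magnitude
component positive) is applied purely for reproducibility, and all
downstream metrics are provably sign-blind.

## Orientation metrics

Long-axis, tangentiality and radiality are |Ĥ·V̂1| against the AP, PD and
IO fields. Both operands are unit vectors, so the value is clipped only
against floating-point overshoot. Validity is the conjunction of a valid
tensor fit, non-degenerate V1 and a valid axis vector. On an exactly
orthonormal frame the three squared metrics sum to 1; on solver-derived
frames the deviation of that sum from 1 is a per-run QC number
(`frame_orthogonality`), reported, not corrected.

Metrics are computed on voxels and, separately, at surface vertices by
interpolating the *six tensor components* and eigendecomposing at the
vertex. Interpolating the cosine scalars or the eigenvectors themselves
would be unstable across the V1 sign discontinuities; tensor interpolation
is sign-blind by construction (tested with adjacent +V1/−V1 voxels).

## Surface sampling and parcels

Trilinear interpolation in voxel space with validity re-weighting: corners
flagged invalid get zero weight and the remainder renormalised; a vertex
with no valid corner is invalid, and vertices outside the volume are
counted and flagged. Trilinear sampling is exact for globally affine
fields (tested). Parcel means are unweighted over valid vertices
(area-weighted means are available behind a flag); subfields are the five
bands Sub/CA1/CA2/CA3/DG-CA4 and the AP bins are head/body/tail.
Hemisphere averaging is the arithmetic mean per parcel or per vertex
(vertex maps in unfolded correspondence; a vertex must be valid in both).

## Group statistics

* **Hemisphere × group screening:** per metric, an F-test between nested
  OLS models `DV ~ age + hemi + group + age:group + age:hemi` (reduced)
  and the same + `hemi:group` (full). FDR correction across metrics is
  applied only if some raw p is significant; metrics with a non-significant
  interaction get hemisphere-averaged. The screening model carries no sex
  term while the vertex-wise model does; both are implemented exactly as
  specified rather than harmonised.
* **Welch ANOVA** with n_i/s_i² weights and Welch-Satterthwaite
  denominator df, chosen for robustness to unequal variances and group
  sizes; **Games-Howell** pairwise tests use the studentized-range
  distribution at q = t√2 with per-pair Welch-Satterthwaite df, at
  α = 0.01. Per metric, the ANOVA family (5 subfields or 3 AP bins) is
  BH-FDR corrected at α = 0.05 and post-hoc tests run only in corrected-
  significant parcels. All p-values are two-sided.
* **Vertex-wise models:** per-vertex OLS with vertex thickness as a
  covariate (accounting for partial-volume-like dependence), age-contrast
  maps fitted per group and group-contrast maps pooled with AD as the
  reference level (encoded in the intercept), emitting MCI and CN t maps.
  Per-vertex designs are solved batched via normal equations with a
  conditioning check (normalised Gram matrix eigenvalue > 1e-10); an
  ill-conditioned vertex (e.g. constant thickness) is invalid, and a
  vertex invalid for any participant is dropped listwise to keep the
  design balanced.

Categorical encodings are dummy codes against fixed reference levels:
group AD, sex F, hemisphere L. All estimators are validated against
independent brute-force oracles (normal equations; literal transcriptions
of the Welch and Games-Howell formulas; step-up enumeration for BH) and
against `pingouin`/`statsmodels` where those implement the same test.

## Spin tests

Maps are rasterised onto a regular grid in the unfolded rectangle (default
126×32, near-isotropic cells for typical vertex densities; the phantom
uses its native 64×32 vertex grid) by binning vertices and averaging
within cells; empty cells are missing. The null displaces one map by a
uniform toroidal shift plus optional u/v axis flips — the planar analogue
of spherical rotation nulls, preserving the map's marginal distribution
and (up to wrap effects) its spatial autocorrelation. The identity draw
(no flip, zero shift) is excluded: the observed arrangement already enters
through the add-one rule p = (1 + #{|R_null| ≥ |R_obs|})/(1 + n_perm), so
p is never 0 and floors at 1/(n_perm + 1). Permutations whose valid
overlap with the fixed map falls below 50% of the observed overlap are
redrawn (bounded). The null generator is pluggable (`null_fn`) so a
rotation- or variogram-based surrogate can be swapped in. Map-set
comparisons apply Bonferroni with a configurable family size (3 for
across-group age-map comparisons, 5 for metric-versus-metric).

## Synthetic ground truth

**Phantom.** A cylindrical-shell sector (defaults r0 = 8, r1 = 14 voxels,
θ ∈ [0, π], length 40, 1 mm isotropic) stands in for the hippocampal
sheet: ψ_AP = z/L, ψ_PD = (θ−θ0)/(θ1−θ0), ψ_IO = ln(r/r0)/ln(r1/r0) are
all harmonic with compatible zero-flux side walls, and the analytic frame
(ẑ, θ̂, r̂) is exactly orthonormal. Boundary labels are painted on
one-voxel-thick shells outside the corresponding faces. The midthickness
surface sits at r = √(r0·r1) on a 64×32 unfolded grid, with subfield bands
of deliberately unequal PD widths (0.28, 0.30, 0.08, 0.12, 0.22 — CA2
smallest, as in real anatomy), AP tertiles for head/body/tail, constant
thickness (r1−r0) mm and a smooth synthetic gyrification pattern.
`interior` marks voxels ≥ 3 voxels from any wall, where one-sided
differencing and wall jaggedness no longer degrade the gradient
directions (≤ ~1.3° from analytic there, vs ~4° in the first two voxel
layers).

**DWI.** V1_true is the normalised (w_AP, w_PD, w_IO) blend of the
analytic frame, completed to an orthonormal eigenframe; D = R·diag(λ)·Rᵀ
with default eigenvalues (1.8, 0.3, 0.3) μm²/ms (prolate, FA ≈ 0.8, MD =
0.8 — representative of anisotropic grey-matter signal at b = 1 ms/μm²).
The gradient scheme is a Fibonacci hemisphere (46 directions, 5 interleaved
b = 0 by default, matching common clinical schemes). Noise is Rician —
magnitude MR realism — with σ = S0/SNR applied to every measurement.

**Cohorts.** Per participant and hemisphere, each vertex metric map is
`baseline·pattern·group_scale + slope·(age − mid) + subject_offset +
smoothed vertex noise`. Defaults are three groups AD/MCI/CN with
n = 40/30/50, ages uniform on [55, 90], sex Bernoulli(1/2). The default
group effects are multiplicative shifts with CN as baseline (MD ×1.15 in
AD and ×1.07 in MCI; thickness and gyrification reduced in AD; long-axis
raised and tangentiality reduced in AD; radiality unaffected), reflecting
the qualitative pattern of hippocampal degeneration with an effect
magnitude that gives subject-level standardised differences of order 1-2
for the weakest contrast (MCI vs CN) at the default noise levels
(σ_subject = 0.03, σ_vertex = 0.05 for MD, smoothing 2 raster cells).
Presets: `CohortSpec.null()` (no effects, for type-I calibration),
`CohortSpec.with_effects()` and `CohortSpec.cn_age_slope()` (a CN-only MD
age slope of +0.005 μm²/ms per year, sized to give clearly super-null
age-contrast t values at n = 50). One RNG stream per participant keyed by
(seed, index) makes cohorts extensible without perturbing existing draws.

What the cohort generator does **not** emulate: real segmentation or
registration error, folding/gyrification geometry (the phantom supplies
thickness and gyrification as given per-vertex quantities), partial-volume
and CSF contamination, longitudinal structure, or site effects. Passing
tests therefore demonstrate the *correctness of the computational chain
and the calibration of the statistics*, not robustness to those real-data
failure modes. Cosine-valued cohort metrics are generated as unbounded
Gaussian fields around their baselines; they are statistical stand-ins,
not resampled cosines.

## Problem sizes

The default test and acceptance runs use: a 32³ slab and the refined
(64, 112)-voxel annulus for solver agreement; the default phantom
(≈ 8 700 domain voxels, 2 048 vertices, 51-measurement scheme) for
orientation recovery; 100 random fixtures per statistical oracle; 1 500
replicates for Welch calibration, 1 500 vertices for vertex-wise
calibration and 500 map pairs at 999 permutations for spin calibration;
the default cohort (120 participants × 2 hemispheres × 6 metrics) for
effect recovery. These sizes were chosen so each stage's sampling error
is comfortably below the margins being tested while a full run stays
interactive.

## Known limitations

* The Laplace solver is a voxel finite-difference code; no sub-voxel
  (cut-cell) boundary placement, so coordinate accuracy near jagged walls
  is first-order in voxel size (quantified above).
* Single-tensor DTI only: no multi-shell, multi-fibre or ODF models; FA
  is not computed because no analysis here consumes it.
* The unfolded-space null uses translations/flips on a torus; it slightly
  distorts autocorrelation across the wrap seam for non-periodic maps,
  and its fidelity to rotation-based spherical spin tests is by analogy,
  not derivation (the generator is pluggable for that reason).
* Head/body/tail bins on the phantom are u-tertiles; real unfolding tools
  place these boundaries anatomically, so bin edges are configuration.
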