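# Methods

## Overview

`tbmorph` implements a longitudinal tensor-based morphometry pipeline for
three-timepoint small-animal structural MRI: preprocessing, dense
diffeomorphic registration, log-Jacobian change maps, group-wise template
construction, one-tailed permutation inference with Monte-Carlo
cluster-extent correction, and atlas ROI overlap tables with
reversible/enduring pattern labels. All stages are validated on synthetic
phantoms whose deformations have closed-form Jacobians.

## Phantom model

The base phantom is an ellipsoidal brain envelope (semi-axes 0.44 of the
grid extent per axis, centred on voxel (N−1)/2 so the anatomy is exactly
symmetric under the grid-index mirror used for bilateral averaging) containing
ten ellipsoidal compartments named for the structures a binge-ethanol study
highlights: prelimbic and infralimbic cortex, nucleus accumbens, lateral
ventricles, central and VPL/VPM thalamus, anterior pretectal nuclei, superior
and inferior colliculi, and a CSF pool above frontal cortex. Contrast is
T2-like: background ≈ 0, tissue 100, compartment tissue 135, CSF 220
(arbitrary units). The default geometry is a 160×160 matrix of 0.2 mm
in-plane voxels with 32 slices; through-plane spacing is a configuration knob
(default 1.0 mm, slice plus gap — the acquisition this emulates quotes both an
isotropic nominal voxel and a thicker slice prescription, so the knob is left
to the user); tests run at 64×64×32 with the same spacings for speed.

A smooth random intensity texture (Gaussian noise, σ = 1.2 voxels, amplitude
20 by default) is added inside the envelope. Two deliberate design choices
attach to it:

- its amplitude is comparable to the tissue-class contrast because dense
  registration needs *interior* intensity evidence: with textureless
  compartments, displacement is determined only at compartment edges and the
  regulariser fills the interior by diffusion, which materialises as spurious
  broad volume change in the recovered Jacobians (the aperture problem);
- it is projected orthogonal to the degree-3 polynomial space on the eroded
  envelope so it cannot masquerade as an intensity inhomogeneity field. The
  orthogonalisation holds for the unweighted fit; under the robust
  (Tukey-weighted) fit a few percent of a strong texture still aliases into
  the polynomial, which is why the bias-recovery oracle tests use a
  low-texture phantom (`texture_amplitude=5`). This is a known identifiability
  limit of any smooth bias model, not a defect of the fit.

### Effect warps

A regional volume change with known ground truth is a compactly supported
radial warp about the ROI centre. Two radial profiles exist:

- **hermite** (the oracle profile): uniform scaling by v^(1/3) inside the
  inner radius, cubic Hermite blend to the identity at the outer radius.
  `det ∇φ = v` exactly inside the inner ball; the compensating strain lives
  in the blend shell. Monotonicity of the profile (fold-freeness) is checked
  on 1024 samples before any field is emitted.
- **incompressible** (the cohort-generation profile): the same scaled inner
  ball, then R(r) = (r³ + Δ)^(1/3) with Δ = (v−1)·a³ out to an outer radius
  placed *beyond the brain envelope*, which is exactly volume-preserving
  (det ∇φ = 1), followed by a Hermite blend to the identity outside the
  brain. Remote structures translate by sub-voxel amounts but carry no
  volume change, so the simulated "physiology" does not impose spurious
  expansion or shrinkage on unrelated ROIs; the compensating strain of the
  blend lands in background where it is invisible and irrelevant.

Scans are generated by pull-back: the image with an expanded structure
samples the earlier anatomy through the inverse-ratio warp, so the forward
map (earlier → later) has determinant v inside the ball exactly. Ground-truth
per-ROI volume ratios are recorded as partial-volume integrals of linearly
interpolated ROI indicators through the composed warps — unlike
nearest-neighbour label counts, these track sub-voxel boundary motion (a 15 %
volume change of a small ROI moves boundaries by < 0.5 voxel and is invisible
to nearest-neighbour counting at 1 mm slices).

### Cohort structure

Defaults emulate the study conditions: 13 ethanol-exposed and 12 control
subjects, three scans each. Each subject receives a fixed smooth anatomical
jitter (max 2 voxels), constant across its timepoints; each *scan*
additionally receives an independent smooth state deformation (max 0.9
voxels, ~0.2 mm in-plane) modelling positioning and physiological fluctuation between sessions.
The state deformations are what give the longitudinal change maps realistic
between-subject variance; without them every subject's maps would be nearly
identical and arbitrarily small systematic registration artefacts would reach
statistical significance, which no real cohort exhibits. Acquisition
artefacts per scan: a random low-order polynomial multiplicative bias field
(unit mean over the brain, amplitude 0.2) and additive Gaussian noise
(σ = 4 on the 0–220 intensity scale; Rician optional).

## Preprocessing

1. **Denoise**: non-local means (patch radius 1, search radius 2), filter
   strength tied to a MAD-based background noise estimate; strength 0 is the
   identity.
2. **Bias correction**: degree-3 polynomial fit to log-intensity by
   iteratively reweighted least squares (Tukey biweight, c = 3·MAD), on the
   brain mask eroded by 2 voxels (partial-volume shell voxels are dim and
   would masquerade as low bias), with nearest-neighbour extension of the
   fitted field into the boundary rind instead of polynomial extrapolation.
   Without a brain mask (the pre-stripping pass) the fit domain is an Otsu
   foreground. The corrected image times the field reconstructs the input
   exactly. Applied twice, before and after skull stripping.
3. **Skull strip**: the template is registered to the scan with the
   diffeomorphic engine and its brain mask is propagated through the
   deformation (nearest neighbour). An already-stripped scan whose exact-zero
   background agrees with the propagated mask (Dice > 0.99) keeps its
   support, making the stage idempotent.
4. **Rigid alignment**: 6-DOF, normalised correlation, multi-resolution
   Powell descent with four multi-start orientations (the metric stops
   refining at half resolution, where positioning precision is ~0.1 voxel;
   the output is resampled at full resolution); each candidate
   orientation is settled by a quick translation-only fit before ranking,
   because near-symmetric anatomy can make a flipped start score best at
   coarse resolution. Transforms whose peripheral displacement is below a tenth of a voxel
   return the image un-resampled.
5. **Intensity matching**: the earlier scan of each interval is quantile-
   matched (256 knots, monotone, rank-preserving) to the later scan within
   the brain masks.

## Registration

Diffeomorphic demons, multi-resolution (3 levels), with the classic
normalised force u = (f−m)·∇m / (|∇m|² + (f−m)²/κ²), κ = mean spacing.
Each update is smoothed (fluid regularisation, σ = 0.6 mm), exponentiated by
scaling-and-squaring so it is itself a small diffeomorphism, composed onto
the running field, and the total field is smoothed again (elastic
regularisation, σ = 0.1 mm). Smoothing σ are physical but floored per axis in
voxel units (0.8 / 0.5 voxels) so 1 mm slices are never left unregularised.
Images are z-scored within their masks before the metric, making the method
contrast-scale invariant. Displacements are stored in world millimetres on
the fixed image grid; the convention fixed = earlier scan, moving = later
scan makes det ∇φ the (later volume)/(earlier volume) ratio, so positive
log-Jacobians mean expansion over the interval. Every emitted field is
checked for strictly positive Jacobian determinant; a fold is an error, never
a silent result.

Defaults (iterations 100/60/40, step 1.3) recover ≈ 94 % of a known radial
warp's log-Jacobian magnitude on clean phantom pairs and ≈ 89 % through the
full noisy preprocessing chain. Residual under-recovery and a small
(|ln J| ≈ 0.02–0.05) systematic far-field dilatation around strong local
effects are intrinsic to elastically regularised intensity registration at
this resolution; the phantom's state deformations keep such artefacts below
statistical detectability at realistic cohort variance, which is exactly how
real cohorts behave.

Group-wise templates are built by iterating: register all subjects to the
evolving mean, subtract the mean displacement field from every subject field
(unbiasing; the mean field magnitude after the final iteration is < 0.1
voxel), average the warped images, repeat (default 5 outer iterations; the
end-to-end tests use 2–3). Interval-1 analyses use the template of the scans
1, interval-2 analyses the template of the scans 2; templates are never mixed
across intervals.

## Jacobian maps

ln det ∇φ by spacing-aware central differences (one-sided at the boundary;
exact for affine fields — uniform scaling by s yields exactly 3 ln s
everywhere). Natural logarithm throughout. Maps are transported to template
space by linear resampling through the group-wise fields with *no* Jacobian
modulation (values are moved, not re-scaled), then bilaterally averaged:
v[i] ← (v[i] + v[N−1−i])/2 along the left-right axis (an idempotent
projection; the central slice of an odd axis is unchanged). No additional
smoothing is applied to the maps (a config σ exists, default 0).

## Statistics

One-tailed Student t per voxel (pooled-variance two-sample EtOH vs control,
or one-sample against zero within a group), computed on the right-hemisphere
half-grid of the bilaterally averaged maps. Inference is by permutation:
group-label exchanges or sign flips, exhaustive whenever the number of
arrangements is at most n_perm (default 5000), otherwise n_perm distinct
random draws including the identity — so p ≥ 1/m and p-values under
exhaustive enumeration are exact. Zero-variance voxels get t = ±∞ and a flag.
Note that within-group analyses of n subjects have a permutation p floor of
2^−n; with fewer than 8 subjects per group the within-group comparisons
cannot reach p < 0.01 and their tables are structurally empty — a property of
the design, reproduced faithfully.

Cluster-extent correction: per-axis Gaussian-equivalent FWHM is estimated
from the variance of spatial first differences of standardized residuals
(classic gradient estimator, floored at half a voxel); n_sim (default 500)
white Gaussian fields are smoothed to that FWHM, standardized within the
mask, thresholded one-tailed at the voxel p; the maximum suprathreshold
cluster size is recorded per simulation and the minimum significant cluster
size is the smallest k whose exceedance fraction is ≤ α = 0.05. One
threshold per comparison, shared by both directions. Connectivity default is
6-neighbour (faces); 18/26 are available. Clusters below the threshold are
discarded; empty cluster sets are valid results.

## Atlas overlap and patterns

Surviving clusters are mirrored to both hemispheres (consistent with
bilateral averaging and bilateral reporting; a config switch), warped
nearest-neighbour into atlas space through a template-to-atlas registration,
and intersected with every atlas ROI. Percentages are 100 · overlap / ROI
volume, rounded half-up to 2 decimals at report time only; the signed overall
change 100·(e₁ − s₁ + e₂ − s₂)/ROI volume is computed from raw voxel counts
and rounded last (rounding the interval percentages first gives visibly
different cells). Voxels outside every ROI accumulate under "Unlabeled", so
overlap counts always sum to the warped mask volume.

Pattern labels at a relevance threshold τ = 10 % of ROI volume, in order:
opposing changes at or above τ within one interval → mixed; expansion then
shrinkage → reversible_expansion; shrinkage then expansion →
reversible_shrinkage; shrinkage without recovery → enduring_shrinkage;
expansion without opposition → enduring_expansion (enduring_fluid_expansion
for CSF-class ROIs); nothing at τ → below_threshold; anything else → mixed.
Raising τ can only move labels toward below_threshold.

## Numerical and reporting conventions

- Interpolation: linear for intensities and scalar maps, nearest neighbour
  for labels and masks (warping a label volume with linear interpolation is
  rejected). Out-of-domain samples become 0/background; sampling uses
  grid-constant boundary handling so values are continuous across the edge.
- Field inversion is fixed-point iteration with a mean-residual tolerance in
  voxel units; composition is φ_f ∘ φ_g with the displacement of g evaluated
  on the grid and f interpolated at the displaced positions.
- All randomness is seeded; identical configurations and seeds produce
  byte-identical scan files and reports. Images round-trip through NIfTI-1;
  displacement fields are 4-D NIfTI (3 components, mm); tables are CSV.
- "n.d." in display tables means no significant cluster overlapped the ROI
  in that direction; machine-readable twins carry zeros.

## What the phantom does and does not show

Passing the end-to-end tests demonstrates that the pipeline recovers
prescribed regional volume changes of realistic magnitude (≈ ±15–90 %)
through noise, bias fields, anatomical variability and session-state
deformations, classifies their longitudinal patterns correctly, and controls
the family-wise false-positive rate on null data. The phantom does not model
MR acquisition physics (no k-space, no partial-volume mixture beyond grid
discretisation), real anatomical shape variability, or tissue-dependent
intensity change, so the tests say nothing about robustness to those; on real
data the registration and atlas steps would be the first places to look for
discrepancies.

## Problem sizes used by the test suite

Unit and end-to-end tests run at 64×64×32 (0.2×0.2×1.0 mm) with 6+6-subject
cohorts, 2 group-wise outer iterations and 60/40/20 demons iterations; the
family-wise error check uses 500 calibration and 400 test fields at 48³.
These sizes were chosen so the whole suite completes on a single CPU in well
under half an hour while keeping every statistical check at full strength.
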