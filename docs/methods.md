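# Methods

This note documents the models, conventions and numerical choices behind
`discsignal`, in the order the analysis runs.

## Image model and orientation

All geometry assumes a canonical axis order: axis 0 sagittal (slice)
direction, axis 1 anterior → posterior, axis 2 superior → inferior
(NIfTI codes `R, P, I`).  Files are reoriented on load from their affine;
oblique affines whose orientation cannot be reduced to an axis permutation
are rejected rather than resampled — the pipeline consumes
scanner-aligned sagittal acquisitions and their co-registered label maps,
and silent resampling would change intensities.  Voxel indexing is
0-based; all bin intervals are half-open `[lo, hi)` with the last bin
closed, so each voxel belongs to exactly one bin.

Label schemas are data, not code: the default (discs 1–17 cranio-caudal,
CSF 99) matches the phantom generator, and any schema can be supplied for
other segmentation tools.

## Midsagittal slice selection

With E = number of sagittal slices containing a disc: E < 3 excludes the
disc (logged); E = 3 or 4 takes all; odd E takes the three slices centred
on the voxel-count-weighted centre slice (ties resolved to the lower
index, the window clamped inside the extent); even E takes the central
four slices of the extent.  The odd/even reading (3 vs 4 slices) is the
natural centred interpretation of a 3-or-4-slice rule and is
config-overridable in spirit — the selection function is pure and small,
so alternative rules can wrap it.

## Anterior–posterior subregions

Within each selected slice the disc voxels are projected onto an AP axis:

* `principal` (default): first principal direction of the in-slice voxel
  scatter in mm, sign-fixed so its AP component is positive.  Discs at
  the thoracolumbar junction are inclined by 10–15°, and equal-width bins
  along the raw image axis would mix annulus and nucleus tissue there.
* `image`: the image AP axis, for comparison with axis-free
  implementations.

Degenerate masks (fewer than 3 voxels, or collinear) fall back to the
image axis with a warning.  The axis actually used per slice is recorded
in the partition object and in QC exports.

Bin edges are `lo + (hi − lo)·(k/n)` over the `[min, max]` of the
voxel-centre projections (not the bounding box, which can produce empty
edge bins for diagonal masks).  Computing the fractions `k/n` first is
deliberate: `5j/25` and `j/5` round to the same double, so the 25-bin
edges contain the 5-bin edges bitwise and coarse = `ceil(fine/5)` holds
voxel for voxel whether the coarse partition is computed directly or by
grouping.  A mask with zero AP extent puts all voxels in the central bin.
Slices with fewer voxels than bins are skipped for that granularity
(logged).  Because the intervals are half-open, a voxel projecting
exactly onto an edge goes to the posterior bin; mirror symmetry
(anterior↔posterior reflection maps bin k to n+1−k) is exact except for
such edge voxels, which is how the property is tested.

Partitioning is per-slice by default; a `pooled` option projects the
voxels of all selected slices onto one common axis.  Whether the original
method defines bins per slice or on the pooled projection is not
documented anywhere we could verify, so both are available and the choice
is recorded in output metadata.

"Whole region" means the full disc mask within the selected slices.  An
optional 1-voxel in-plane erosion is available for users who want a
conservative inner region; it is off by default because no principled
erosion depth is established.

## Normalization and statistics

Intensities are divided by the mean raw signal over the entire CSF mask
of the image (all slices).  The pipeline is therefore exactly invariant
to global intensity scaling; this is asserted to 1e-12 in the tests.
Per-bin SD is the population SD (divide by N): it is descriptive, not
used for inference.  Empty fine bins propagate as missing values and are
excluded from group medians — never imputed as zeros, which would bias
profiles downward.  Group profiles are the median across subjects of the
per-subject bin means, with the 25th–75th percentile band, computed per
group × disc × fine bin; subjects missing a disc are excluded from that
disc only.

## Mixed model

The long table of per-(subject, disc, subregion) means enters

    mean_signal ~ group + disc + group:disc + (1 | subject)

fitted by REML via `statsmodels` MixedLM.  A random subject intercept
with iid residuals induces compound symmetry within subject: constant
variance σ_b² + σ_e² and non-negative correlation σ_b²/(σ_b² + σ_e²).  A
direct compound-symmetry marginal fit allowing *negative* intra-subject
correlation is intentionally not implemented; with disc profiles the
shared-subject correlation is physiologically non-negative, and the
boundary case σ_b² = 0 is reported with a warning.

Sliced comparisons: per disc level, the LS means of the two groups (model
cell means; equal to raw cell means in balanced data), their SEs, the
control − climber difference with two-sided 95% CI and p-value.  Positive
differences mean controls above climbers.  Per-subregion analysis fits
one model per coarse subregion rather than a three-way interaction model,
matching how per-subregion SEs are conventionally reported; failures in
one subregion are isolated and logged.  No multiple-testing adjustment is
applied (flagged in output metadata) so users can apply their own.

In a balanced complete design the group difference at a fixed disc has
variance 2(σ_b² + σ_e²)/n — the two groups contain different subjects, so
the random intercept does not cancel.  This closed form is the oracle for
the SE in the test suite and is met to machine precision.

### Degrees of freedom

`statsmodels` exposes no small-sample df, so the package computes a
Satterthwaite approximation from its own REML machinery: with
θ = (σ_b², σ_e²), the contrast variance C(θ) = l′(X′V⁻¹X)⁻¹l is
differentiated numerically (central differences, relative step 1e-4), the
observed REML information is obtained by finite differences of the
profiled REML log-likelihood (relative step 1e-3), and
ν = 2C²/(g′Ag) with A the inverse information, clipped to
[1, residual df].  All per-θ quantities are computed once per fitted
model and reused across contrasts.  At the σ_b² = 0 boundary the
approximation degenerates gracefully to the residual-variance-only case;
if the information matrix is not positive definite the residual df is
used with a warning.  `df_method="kenward_roger"` is accepted and served
by the same approximation: for the balanced complete designs this
analysis targets, Kenward–Roger and Satterthwaite coincide, and the
method actually used is recorded in every result row.  The implementation
is cross-checked against `lmerTest` + `emmeans` (Satterthwaite) in the
test suite: estimates agree to 1e-6, df to better than 0.2, p-values to
1e-3.

Calibration measured by the package's own Monte-Carlo study (500 null
cohorts, 8/group, 6 discs, σ_b = 0.03, σ_e = 0.02): pooled per-disc
type-I error 0.044–0.064 across seeds, inside the 0.03–0.07 acceptance
band.  Rejections cluster strongly within cohorts (all discs share one
variance estimate), so the pooled rate over replicates — not the rate of
a single disc — is the meaningful calibration summary.

## Synthetic phantoms

The generator emulates a 12-slice sagittal T2 acquisition from T1 to S1
on a 12 × 96 × 320 grid (3 × 1 × 1 mm; the in-plane resolution and slice
thickness of the source protocol are not published, so clinically typical
values were chosen once).  Seventeen discs are tilted ellipses in the
(AP, SI) plane, identical across slices: half-width 14 → 22 mm and
half-height 2.6 → 4.6 mm growing caudally, tilt 0° → 15° increasing
caudally (exercising the principal-axis path), centred anterior of a
bright CSF stripe, with vertebral bodies between discs.  Disc tissue
follows annulus baseline + Gaussian nucleus bump along the major axis
(baseline 140, amplitude 330, width 0.20 of the AP extent, CSF 1000, so
normalized annulus ≈ 0.15 and nucleus peak ≈ 0.45, matching healthy
profiles).  The bump peaks at fraction 0.62 in thoracic discs and 0.52
from T12-L1 caudally, reproducing the posterior nucleus position of the
thoracic spine.

Cohort structure mirrors the mixed model: a subject intercept
b ~ N(0, σ_b = 0.03) and per-(disc, fine-bin) texture ε ~ N(0, σ_e = 0.02)
on the normalized scale, and a group effect Δ subtracted from climbers on
configured (disc, coarse-bin) cells.  The default Δ template is the
published thoracolumbar signature embedded in `reference.py`: nucleus
bins 2–4 of T10-T11 … L3-L4, magnitudes 0.06–0.17, annulus bins zero.
Noise is Rician (magnitude of two Gaussian channels, σ = 23 ≈ nucleus
SNR 20), because MR magnitude images carry a positive noise floor that
the tests deliberately exercise; the per-voxel Rician mean obtained by
numerical integration is the oracle for the noisy-phantom bias test.
Everything is driven by `numpy.random.default_rng` from explicit seeds:
identical (config, seed) pairs give bit-identical phantoms.

`closed_form_bin_means` integrates the intensity profile against the
elliptic chord weight √(t(1−t)) per bin — the analytic expectation of the
extracted bin means — and is itself verified against 10⁶-sample Monte
Carlo integration.  A faster, image-free cohort generator
(`simulate_signal_table`) draws long tables directly from the model
assumptions for the calibration and power studies in
`discsignal.calibration`.

What the phantom does **not** model: spinal curvature, partial-volume
averaging beyond voxelization, coil shading, k-space artefacts, or
segmentation error.  Passing tests therefore validate the measurement and
inference chain given correct label maps, not robustness to segmentation
failure.

## Numerical error budget

The identity "extracted noise-free bin means = analytic bin means" is a
numerical-convergence property of the voxelization.  Measured maximum
relative error over all 17 discs × 25 fine bins, all randomness off:

| in-plane voxel | max rel. error (25 bins) | (5 bins) |
|---------------:|-------------------------:|---------:|
| 1.0 mm (default grid) | 13.2% | 5.6% |
| 0.5 mm | 5.7% | 3.3% |
| 0.33 mm | 3.0% | 1.7% |
| 0.2 mm | 1.2% | — |

The error is dominated by bin-boundary placement: with ~1.4 voxel columns
per fine bin at 1 mm, which column lands in which bin shifts bin means on
steep nucleus flanks.  The 2% identity check therefore runs on the 0.2 mm
refinement (12 × 480 × 1600), where discretization is below the bound;
at the default clinical-like grid the same comparison is asserted at the
measured resolution-appropriate levels.  Monte-Carlo studies use reduced
problem sizes chosen for precision per CPU-second: 500 null cohorts at
8/group × 6 discs for type-I error, 200 cohorts at 15/group × 17 discs ×
5 subregions for effect recovery.

## Known limitations

* Only non-negative intra-subject correlation (random-intercept CS).
* Kenward–Roger is approximated by Satterthwaite (exact only for
  balanced complete data; slightly liberal for very unbalanced tables).
* No segmentation, registration, or bias-field correction; label maps
  are trusted as given (validated only for shape/spacing/schema).
* Reorientation handles axis permutations/flips only, not oblique
  acquisitions.
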