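# Methods

## The regression problem

Classical morphometry pipelines reconstruct segmentations and cortical
surfaces from a T1-weighted MR volume and only then measure volumes,
thicknesses and curvatures — hours of computation per scan.  `brainmorph`
implements the alternative this package is built around: a single 3-D
convolutional network regresses all 165 morphometric targets directly from a
minimally preprocessed volume, with reference ("silver standard") values
taken from FreeSurfer statistics files.  The targets are

* 29 subcortical/global volumes (mm³) from `aseg.stats`, with the corpus
  callosum reported as the sum of its five sub-regions and the two global
  measures (total gray, cerebral white matter) read from the `# Measure`
  header lines;
* 34 Desikan-Killiany mean thicknesses (mm) and 34 mean curvatures (mm⁻¹)
  per hemisphere from `lh./rh.aparc.stats`.

The target ordering (volumes in roster order, then lh/rh thickness, lh/rh
curvature blocks in atlas file order) is fixed by a versioned registry
constant; its hash is embedded in checkpoints and manifests so that a model
can never be evaluated against a permuted registry.  The 29-name volume
roster is pinned in `targets.ASEG_VOLUME_ROSTER`.

## Preprocessing

Four steps, deliberately minimal: (1) skull-stripping by a supplied binary
brain mask; (2) conforming to the canonical grid — trilinear resampling to
1 mm isotropic spacing followed by a centered crop/pad to 256³ (nearest
neighbour for masks); (3) linear min–max rescaling of intensities onto
[0, 4095], with constant volumes mapped to zero (a constant image carries no
signal and the alternative divides by zero); (4) an integer-voxel shift
placing the intensity-weighted center of mass of the foreground at the grid
center (index 128 per axis, 0-based).  Centering uses whole-voxel shifts so
no interpolation is introduced and later augmentation translations stay in
bounds.  Rescaling is applied after conforming so the [0, 4095] contract is
exact in the network's input; the pipeline order is otherwise immaterial for
the operations involved.

## Architecture

Six kernelled layers — conv(11³, stride 3, 144 filters), maxpool(3³, 2),
conv(5³, 2, 192), maxpool(3³, 2), conv(5³, 1, 192), maxpool(3³, 2) — then
fully connected layers of widths 374 (ReLU), 192 and 165.  The padding
convention is not a free choice: reproducing the published per-layer output
sizes (86, 42, 21, 10, 10, 4) on a 256³ input forces boundary-preserving
(`ceil(n/s)`) convolutions and unpadded (`floor((n−k)/s)+1`) poolings.  The
receptive field after the last pooling layer is 209 voxels per axis.

A plain per-layer parameter count of this table gives 12,956,123 trainable
parameters, ~64% of them convolutional (conv: k³·c_in·c_out + c_out; fc:
n_in·n_out + n_out, with 4³·192 = 12,288 units feeding the first FC).  The
originally reported total of 9,467,877 — of which roughly half was said to
be convolutional — is not reproducible from the table as printed: the
FC-side tally (4,699,931) does match half of that total, suggesting the
convolutions were grouped or otherwise reduced in an unstated way.  We implement the table as printed and
expose the per-layer breakdown (`network.count_parameters`,
`brainmorph describe`); the printed total is documented here rather than
asserted anywhere.

Conv weights are Xavier-uniform; biases are zero.  FC weights are
zero-initialized by default, as published.  Note that with both hidden FC
weight matrices and the output weights at zero, every gradient upstream of
the output bias is identically zero, so training can only move the output
bias; `fc_init="xavier"` is therefore provided (and used by the desk-scale
experiments) to make from-scratch learning possible.

### No deep-learning framework

The network, its backward passes and the Adam optimizer are implemented
in-package on numpy (`_nn.py`): convolutions as im2col + BLAS GEMM with
TF-style SAME padding, pooling with argmax bookkeeping, float32 throughout.
The engine is validated against central-difference numerical gradients in
the test suite.  The first convolution skips its input gradient (there is
nothing upstream), which removes the single most expensive scatter.

### Desk-scale variant

The full 256³ network is far beyond a CPU test budget, so
`network.desk_spec` derives a scaled variant: the same convolution stack and
kernel/stride pattern, filter banks and hidden FC widths scaled by a
multiplier (default ×0.25), and any pooling layer that would collapse the
feature map below 2³ is skipped.  At input edge 48 this keeps
conv(11,3)→16³, pool→7³, conv(5,2)→4³, conv(5,1)→4³ and drops the two late
poolings: collapsing to 1³ via max-pooling destroys the spatial-extent
information that a volume regression needs (max is scale-free; the spatial
pattern of active units is not), and empirically costs most of the held-out
correlation on the volume target.

## Training protocol

Adam on the mean-squared error, batch size 6 (one epoch = ceil(n/6) steps; a
438-sample training set gives 73), best-epoch selection by validation mean
R² evaluated every 20 epochs.  Augmentation: one uniform integer translation
of up to ±15 voxels along a random axis, then three consecutive 90°
rotations about principal axes.  The published description leaves the
rotation-axis convention ambiguous; by default each of the three rotations
draws its own axis (which reaches the full 24-element cubic rotation group
and matches the stated goal of handling arbitrary orientations), and
`single_axis_rotations=True` restores the one-axis (single 270°) reading.
Both operations are pure index permutations/shifts — no interpolation — so a
sample's target vector is never touched.

Targets span mm³ (up to ~10⁵) and mm⁻¹ (~10⁻²); a raw MSE is dominated by
the volumes.  Per-target z-scaling is therefore on by default
(`target_scaling="off"` restores the literal raw-MSE protocol); the scaling
constants are stored on the estimator and inverted in `predict`.

Subject-level splitting assigns all scans of a subject to one side; subjects
with rescans are forced into the primary plan's test set.  Additional
non-exhaustive cross-validation plans have pairwise-disjoint validation and
test sets.

## Phantom generator

Real cohorts cannot be shipped, so the generator emulates the statistical
skeleton of a morphometry study with closed-form geometry:

* a bright **ellipsoid** (nucleus analogue; volume 4/3·π·abc mm³) bound to a
  ventricle-like volume target;
* a concentric spherical **shell** (cortical-band analogue; thickness
  r_out − r_in mm, mid-surface mean curvature 1/r_mid mm⁻¹) bound to one
  thickness and one curvature parcellation;
* voxel-center containment rasterization (a voxel takes a primitive's
  intensity iff its center is inside), which makes brute-force voxel
  counting an exact oracle and converges to the analytic volume as the
  radius grows;
* additive zero-mean Gaussian intensity noise clipped at 0 (sd 5 on
  primitive intensities 80/140 by default) as a crude stand-in for magnitude
  noise.

Cohort structure: ages uniform on 6–84 years (the study age range), 45%
male, a thickness age slope of −0.004 mm/year around a mean of 2.5 mm at the
reference age 40 (2.5 mm is the canonical healthy cortical mean thickness;
−0.004 mm/year the cross-sectional atrophy rate the evaluation must
recover), between-subject thickness sd 0.25 mm, a patient−control group
effect of Cohen's d = +0.3 on the volume target (volume 1150 ± 280 mm³,
ventricle-like), shell mid-radius 16 ± 1 voxels at the default 48³ desk
edge, and optional rescan subjects whose scans share geometry (identical
truth) and differ only in rendering noise.

What the phantoms deliberately do not emulate: folded cortical geometry,
partial-volume effects, bias fields, sequence contrast, anatomy-correlated
target structure.  Passing the recovery suites therefore demonstrates that
the pipeline, losses and statistics are implemented correctly and that the
network can extract geometric size/thickness information from voxel data —
not that the architecture reaches any particular accuracy on clinical MRI.

## Evaluation statistics

* R² per Σ-form (1 − SS_res/SS_tot against the reference mean); Pearson's r.
* ICC(2,1): two-way, absolute-agreement, single-measurement Shrout–Fleiss
  form, (MS_R − MS_E)/(MS_R + (k−1)MS_E + k/n·(MS_C − MS_E)) from the
  two-way ANOVA mean squares, with the F-based 95% CI (Satterthwaite
  degrees of freedom for the MS_C/MS_E mixture).  This is the computation
  performed by the R package `irr` used in the original analysis; a
  published shorthand of the formula omits the (k−1)MS_E term, which we
  treat as a typesetting loss.  Verified against pingouin's ICC(A,1) to
  1e-9 and against an explicit sums-of-squares oracle to 1e-10 in the tests.
  Zero between-subject variance returns NaN with a diagnostic — a low ICC
  can reflect lack of variability rather than disagreement.
* Cicchetti bands: <0.40 poor, 0.40–0.59 fair, 0.60–0.74 good, ≥0.75
  excellent.
* Bland–Altman: mean difference (prediction − reference) and ±1.96·SD limits
  of agreement; SDs use the n−1 denominator throughout the package (the
  published rescan worked example — six right-thalamus volumes with mean
  7,035 mm³ and SD 31 mm³ — reproduces only with n−1).
* Relative deviation: per subject, the mean over a category's targets of
  100·(y−g)/g, then mean ± SD across subjects.
* Group comparison: values residualized on age and a sex indicator by pooled
  least squares, Cohen's d (patient − control, pooled SD) on the residuals,
  one-sided t-test in the configured direction (ventricle-like volumes:
  greater; thickness: less).
* Age trends: polynomial least squares (order 1 or 2); order 1 reports the
  slope in mm/year with SE and CI95, order 2 adds the stationary (peak) age;
  the Bonferroni threshold for the 68 parcellations is 0.05/68 ≈ 7.4e-4.

## Problem sizes and numerical choices

Desk-scale experiments use 48³ phantoms, the ×0.25-filter desk network
(~0.85 M parameters), 120 training / 20 validation / 30 held-out samples,
learning rate 1e-4, dropout 0.2 on the hidden FC layers, Xavier FC
initialization, translation-only augmentation (±4 voxels; shifts beyond
that push shell voxels outside a 48³ grid) and 60 epochs with best-epoch
selection every 10 — sizes chosen so the full suite runs on a single CPU
core.  Two optimization pitfalls found while dimensioning these runs are
worth recording.  First, at learning rate 1e-3 with raw phantom intensities
(~0–150) training intermittently collapses to constant predictions — initial
outputs are orders of magnitude larger than the z-scaled targets, and the
ensuing correction kills ReLUs; either lowering the rate to 1e-4 or
z-scoring the input (``input_scaling="z"``) is a reliable remedy, and the
desk runs use the lower rate because it stays closest to the published
protocol.  Second, the full rotation augmentation slows early learning
drastically at desk scale (the 24-fold orientation burden at n = 120
outweighs its regularization benefit within the epoch budget), so the desk
runs translate only; rotations remain the default for full-scale training.
The statistical recovery analyses (group effect, age slope) run on
truth-only cohorts of n = 400, where rendering is skipped entirely.  Ties
in max-pooling resolve to the first (argmax) element; augmentation draws are
consumed from a single `numpy.random.Generator` stream per run, making
cohorts, augmentation and weight initialization bit-reproducible under a
fixed seed in single-threaded execution.

## Known limitations

* The published parameter total cannot be reconciled with the printed layer
  table (see above); the discrepancy is documented, not hidden.
* The zero-FC initialization is reproduced as printed although it cannot
  train from scratch; desk experiments must opt into Xavier FC init.
* The phantom generator's independence of targets (volume, thickness,
  curvature drawn independently) means cross-target regularities of real
  anatomy are absent; multi-task benefits of the 165-way regression are not
  exercised at desk scale.
* The numpy engine is single-threaded-deterministic but makes no attempt at
  GPU-class performance; the full 256³ configuration is instantiable and
  arithmetic-checked, not trainable in reasonable time here.
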