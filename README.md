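# brainmorph

Direct brain-morphometry regression from T1-weighted MRI.

Quantitative brain morphometry — subcortical volumes, cortical thickness and
curvature — is a key neuroimaging biomarker for neurological and
neurodegenerative disease, but the standard surface-reconstruction pipelines
that produce it (FreeSurfer and kin) take hours per scan. `brainmorph`
implements the alternative: a single 3-D convolutional network that maps a
minimally preprocessed 256³ T1-weighted volume straight to **165
morphometric measures** — 29 subcortical/global volumes (mm³), 68 cortical
mean thicknesses (mm) and 68 mean curvatures (mm⁻¹) over the 34
Desikan-Killiany parcellations per hemisphere — in a single forward pass,
trained against FreeSurfer-derived reference values.

The package covers the full experimental loop:

* **targets** — the fixed 165-target registry and parsers for FreeSurfer
  `aseg.stats` / `?h.aparc.stats` files (corpus callosum = sum of its five
  sub-regions; the pinned 29-name volume roster is
  `targets.ASEG_VOLUME_ROSTER`);
* **preprocess** — skull-strip by mask, conform to 256³ @ 1 mm (trilinear),
  min–max rescale to [0, 4095], integer center-of-mass centering;
* **network** — the six-layer architecture with exact shape inference,
  receptive-field and parameter arithmetic as first-class functions, plus a
  scaled-down desk variant; the trainable model itself runs on an in-package
  numpy engine (im2col convolutions + BLAS, hand-written backprop, Adam);
* **training** — ±15-voxel translation + 90°-rotation augmentation,
  subject-level splits with rescan handling, MSE/Adam loop with mean-R²
  early stopping, wrapped in a scikit-learn-style estimator
  (`CNNMorphometryRegressor`, with `fit`/`predict`/`get_params`);
* **phantom** — synthetic cohorts of geometric phantoms (ellipsoid nuclei,
  spherical-shell cortex analogues) with closed-form morphometry, injectable
  age slopes, group effects and rescans, so everything is testable without
  clinical data;
* **evalstats** — R², Pearson r, ICC(2,1) with F-based 95% CI and Cicchetti
  bands, Bland–Altman limits of agreement, per-category relative deviation,
  age/sex-adjusted Cohen's d, polynomial age trends with Bonferroni
  correction, and scan–rescan reliability.

The agreement metric of record is the intraclass correlation
**ICC(2,1)** (two-way, absolute agreement, single measurement):

    ICC(2,1) = (MS_R − MS_E) / (MS_R + (k−1)·MS_E + (k/n)·(MS_C − MS_E))

computed from the two-way ANOVA mean squares of the n-subject × 2-rater
(prediction, reference) table — unlike Pearson's r, it penalizes a fixed
bias (r = 1 for y = g + 1; ICC < 1).

## Worked example

Architecture bookkeeping (`brainmorph describe`):

```
input: 256^3 x 1
  conv11^3  out   86^3 x 144  params      191,808
   pool3^3  out   42^3 x 144  params            0
   conv5^3  out   21^3 x 192  params    3,456,192
   pool3^3  out   10^3 x 192  params            0
   conv5^3  out   10^3 x 192  params    4,608,192
   pool3^3  out    4^3 x 192  params            0
     fc374  out          374  params    4,596,086
     fc192  out          192  params       72,000
     fc165  out          165  params       31,845
receptive field: 209
total trainable parameters: 12,956,123
```

Each convolution preserves `ceil(n/stride)` spatial extent (boundary
padding), each pooling is unpadded — that convention is forced by the output
sizes above. A unit after the last pooling layer sees 209³ voxels of the
input. (On the parameter total, see the note in `docs/methods.md`.)

Desk-scale training on synthetic phantoms:

```python
import numpy as np
from brainmorph import CohortConfig, generate_cohort, desk_spec, CNNMorphometryRegressor
from brainmorph.evalstats import pearson_r, icc_2_1

samples = generate_cohort(CohortConfig(n_controls=85, n_patients=85, edge=48), seed=1)
order = np.random.default_rng(0).permutation(len(samples))
bound = np.nonzero(samples[0].truth.mask)[0]
X = np.stack([s.volume.data for s in samples]).astype(np.float32)[order]
y = np.stack([s.truth.values[bound] for s in samples])[order]

est = CNNMorphometryRegressor(
    spec=desk_spec(input_edge=48, output_width=y.shape[1]),
    learning_rate=1e-4, max_epochs=60, validation_period_epochs=10,
    dropout=0.2, fc_init="xavier",
    augment=True, rotation_augment=False, max_translation=4, random_state=0,
)
est.fit(X[:120], y[:120], X_val=X[120:140], y_val=y[120:140])  # 20-phantom early stopping
pred = est.predict(X[140:])                                    # 30 held-out phantoms
print("volume    r =", round(pearson_r(pred[:, 0], y[140:, 0]), 3))
print("thickness r =", round(pearson_r(pred[:, 1], y[140:, 1]), 3))
```

which prints (after ~5 CPU-minutes):

```
volume    r = 0.927
thickness r = 0.904
```

— the correlations between the network's predictions and the phantoms'
closed-form ground truth on 30 subjects never seen in training
(`tests/test_acceptance.py` asserts r ≥ 0.8 / ≥ 0.6 for these targets).

The published rescan worked example reproduces exactly: six repeated
right-thalamus volume predictions (7079, 7066, 7028, 7010, 7021, 7003 mm³)
give mean 7,035 mm³ and sample SD 31 mm³:

```python
from brainmorph.evalstats import rescan_sd
rescan_sd([7079, 7066, 7028, 7010, 7021, 7003])   # (7034.5, 30.95…)
```

## CLI

```
brainmorph describe                 # architecture report
brainmorph phantom   --n 10 --seed 1 --out cohort/
brainmorph preprocess --volume t1.nii.gz --mask mask.nii.gz --out conformed.nii.gz
brainmorph ingest    --aseg aseg.stats --lh-aparc lh.aparc.stats \
                     --rh-aparc rh.aparc.stats --out reference.csv
brainmorph train     --cohort cohort/ --out model.pkl
brainmorph predict   --checkpoint model.pkl --volume conformed.nii.gz --out pred.csv
brainmorph evaluate  --predictions pred.csv --references reference.csv --out report.csv
```

Every artifact-producing command writes a manifest JSON (command, config,
seeds, registry hash, timestamp).

## Scope

The package parses FreeSurfer *outputs*; it does not run segmentation or
surface reconstruction. Phantoms emulate the statistical structure of a
morphometry study (known geometry, age slopes, group effects, rescans), not
MR physics. See `docs/methods.md` for the model assumptions, parameter
defaults and known limitations.
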