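# vbmnet

Multitask 3-D convolutional estimation of **age, gender and diagnostic
status** from voxel-based-morphometry (VBM) tissue-density maps, with
SmoothGrad attribution mapped onto a brain atlas.

Structural MRI preprocessed with VBM yields, per subject, co-registered
gray-matter (GM) and white-matter (WM) density volumes on a common template
grid.  `vbmnet` trains a single shared 3-D CNN body with three task heads on
those two channels, under the joint objective

```
L = w1·MSE(age) + w2·BCE(gender) + w3·BCE(diagnosis),   w1 = w2 = w3 = 1
```

using a custom stratified k-fold protocol (train / validation / test per
round), per-task best-checkpoint saving with patience-based early stopping,
validation-chosen ROC operating points, and SmoothGrad saliency (absolute
input gradients averaged over noisy copies) aggregated across folds and
intersected with an integer atlas to rank the regions of interest (ROIs)
driving each prediction.  It is aimed at researchers studying
neurodevelopment in paediatric cohorts, where age, gender and diagnosis are
entangled and per-task attribution matters.

Everything runs on plain CPU: the network, backprop, Adam, batch norm, max
pooling and dropout are implemented in NumPy with numba-compiled
convolution/pooling kernels — no deep-learning framework required.  A
synthetic cohort generator emulates VBM outputs (tissue probabilities in
[0, 1], background −1, smooth fields, injectable regional effects) so the
entire workflow is testable end to end without any imaging download.

## Worked example

```python
from vbmnet import synth
from vbmnet.benchmark import small_model_config, small_train_config
from vbmnet.workflow import MultitaskBrainCNN

# 400 synthetic subjects on a 32^3 grid, with a known age slope
# (-0.02 density/yr in ROI 2) and gender offset (+0.04 in ROI 5)
pairs, phenotypes, atlas = synth.benchmark_cohort(seed=1)

model = MultitaskBrainCNN.from_cohort(
    pairs, phenotypes, atlas,
    model_config=small_model_config(),     # 2 conv blocks, filters (4, 8)
    train_config=small_train_config())     # Adam 5e-3, <=26 epochs, batch 16
results = model.fit(k=3, seed=1)

print(results.summary())
print(results.rank_rois("age", top_k=3, max_examples_per_fold=16))
```

Output (abridged; ~2 minutes on one CPU core):

```
Multitask 3D CNN cross-validation summary
folds: 3   seed: 1
label encoding: gender 1=female, 0=male; diagnosis 1=disorder, 0=healthy control

fold  age_mae  age_r  age_p  age_r2  baseline_age_mae  ...  gender_auc  diagnosis_auc
   0   1.8909 0.9831 0.0000  0.6644            3.5240  ...      1.0000         0.4617
   1   2.0944 0.9901 0.0000  0.6664            3.6613  ...      1.0000         0.5465
   2   1.8619 0.9867 0.0000  0.7219            3.5896  ...      0.9966         0.5873
mean   1.9490 0.9867 0.0000  0.6842            3.5916  ...      0.9989         0.5318
  sd   0.1267 0.0035 0.0000  0.0326            0.0687  ...      0.0020         0.0641

  task  roi_id roi_name statistic     value  rank
0  age       2  ROI_002      mean  0.219241     1
1  age       3  ROI_003      mean  0.036306     2
2  age       5  ROI_005      mean  0.026853     3
```

Reading this: the fitted model predicts held-out age with MAE ≈ 1.9 years
versus 3.6 years for the predict-the-mean baseline (prediction R² ≈ 0.68),
separates genders essentially perfectly (AUC ≈ 1.0 — the injected offset is
strong relative to the noise), leaves the effect-free diagnosis task at
chance (AUC ≈ 0.53), and the SmoothGrad ranking recovers ROI 2 — the region
actually carrying the age effect — as the top age-predictive region by a
wide margin.

The same workflow is scriptable from the shell:

```bash
vbmnet simulate --spec cohort.yaml --outdir cohort/
vbmnet run --config run.yaml --outdir out/ --seed 1
vbmnet report --rundir out/
```

## Layout

| Module | Role |
| --- | --- |
| `vbmnet.synth` | synthetic VBM-like cohorts, atlas generation, effect injection |
| `vbmnet.volume_io` | masking, pad/trim-to-cube, channel stacking, NIfTI + record I/O |
| `vbmnet.nn` | the multitask 3-D CNN, joint loss, numba kernels |
| `vbmnet.folds` | stratified k-fold train/val/test scheme |
| `vbmnet.train` | Adam loop, per-task checkpoints, early stopping, selection |
| `vbmnet.evaluate` | regression/classification metrics, operating points, confound check |
| `vbmnet.saliency` | SmoothGrad, fold aggregation, ROI ranking, NIfTI overlays |
| `vbmnet.workflow` | `MultitaskBrainCNN` / `MultitaskCVResults` facade |
| `vbmnet.benchmark` | canonical recovery and null studies |
| `vbmnet.cli` | `vbmnet` command-line interface |

See `docs/methods.md` for the model, the protocol, the generator's scope and
the package's design decisions.
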