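# histocnn

A compact hybrid-CNN toolkit for two-class histopathology image
classification, built to be fully exercisable on synthetic fixtures with no
dataset download and no GPU. It provides:

- **Two-branch architecture** (`histocnn.network`): a stem + 7 inception
  modules, each followed by a squeeze-excite (SE) channel gate, with residual
  shortcut additions and a 2-way softmax head. The same network is
  instantiated twice: a *global* branch fed the whole downsampled image and a
  *local* branch fed non-overlapping patches. A `width_multiplier` produces
  desk-scale models (the test workhorse is 1/8 widths at 64 px). Everything
  runs on a small numpy layer library with manual backprop
  (`histocnn.nn`) — no deep-learning framework required.
- **SE-statistic channel pruning** (`histocnn.pruning`): channel importance
  is the mean SE activation factor over a sample stream; a geometric
  schedule `X = 1 - (1 - O)^(1/R)` fixes an equal per-loop proportion so R
  prune-retrain loops remove an overall fraction O. Pruning is physical
  surgery: producing filters, BN statistics, SE weight grids and consumer
  inputs are all sliced, mapped through the inception concatenation. A
  mean+std+k threshold rule is included for comparison.
- **Training and fusion** (`histocnn.training`): momentum-SGD branch
  training, per-patch voting (sum/max rules), convex two-branch fusion
  `P = lam*P_L + (1-lam)*P_G` (default 0.6), and a 5-model bagging ensemble.
- **Preprocessing** (`histocnn.stain`, `histocnn.tiling`): statistical color
  normalization in the logarithmic lab opponent space (Reinhard color
  transfer), non-overlapping floor-grid tiling (1120x672 at side 224 gives
  15 patches), bilinear global downsampling, and an 8-fold
  rotation/flip/shear augmentation policy.
- **Cohort bookkeeping** (`histocnn.data`): CSV manifests
  (`path,patient_id,label,split`), patient-level train/test splitting,
  5-fold bagging partitions (a 7625-record pool gives 6100 train / 1525
  validation per model), and augmentation/tiling data-plan arithmetic.
- **Evaluation** (`histocnn.metrics`): patient-level and image-level
  accuracy, PPV, Cohen's Kappa, F1/precision/recall and ROC curves from
  prediction tables; malignant is the positive class.
- **Synthetic fixtures** (`histocnn.synthetic`): seeded histology-like
  cohorts (textured blob fields on a pink base with per-patient effects,
  class separability controlled by one scalar, optional per-image color
  casts) so every stage above is testable offline.

## CLI

```bash
histocnn synth cohort/ --n-patients 25 --images-per-patient 8 --separability 3
histocnn split cohort/manifest.csv --train-fraction 0.7 --seed 0
histocnn folds cohort/manifest.csv --n-folds 5 -o folds.json
histocnn normalize cohort/ normed/ --reference ref.png
histocnn tile image.png patches/ --side 224
histocnn augment image.png aug/ --n 8
histocnn train cohort/manifest.csv --branch global -o global.pkl
histocnn prune cohort/manifest.csv --model global.pkl --target-ratio 0.5 \
    --loops 1 -o pruned.pkl --report prune.json
histocnn predict cohort/manifest.csv --global-model global.pkl \
    --local-model local.pkl --lambda 0.6 -o predictions.csv
histocnn evaluate predictions.csv -o report.json
```

## Conventions

- FLOPs are counted as 2 x multiply-accumulates of conv/FC layers (SE FC
  pair included); BN, pooling and activations are not counted.
- Tiling discards right/bottom remainders; patches are row-major.
- Augmentation outputs replace the original sample; the unmodified image is
  not included among the 8 outputs.
- Undefined metrics (zero denominators) are reported as missing, never 0.
- Fold assignment within the training pool is image-level random; the
  train/test split is always by whole patients.
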