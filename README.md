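# biomeshift

Stacked-ensemble modelling of biome (potential natural vegetation)
distributions, with spatially blocked cross-validation, per-pixel
uncertainty layers, and confidence-filtered biome-transition mapping
between climate scenarios.

The package is aimed at ecologists and biogeographers who classify
vegetation classes (e.g. the 20-class BIOME 6000 pollen-reconstruction
legend) from climatic and topographic covariate rasters, and who then want
to ask *where* the dominant class would change under warmer/drier future
climate — without over-interpreting pixels where the classifier is unsure.

## The method

**Model.** Three base learners — a random forest, gradient-boosted trees
and an L1-regularized multinomial linear model — are each fitted with
out-of-fold prediction over *spatial* folds: points are binned into
100 × 100 km blocks of a sinusoidal equal-area grid and whole blocks are
dealt into k = 5 folds, so spatially autocorrelated neighbours can never
straddle a train/test split. A multinomial logistic meta-learner is then
trained on the concatenated 3K out-of-fold class probabilities (stacked
generalization). Per pixel the model emits a probability vector in percent
(summing to 100), plus two uncertainty layers:

- **SD** — per class, the sample standard deviation (n = 3) of the base
  learners' probabilities (model disagreement);
- **margin of victory (MoV)** — the first minus the second highest class
  probability: 0 = maximal confusion, 100 = one-hot certainty.

**Evaluation.** Fivefold spatial CV repeated five times reports overall
accuracy, the multiclass logloss `LL = −mean log p(true class)` (nats),
and its skill score against the training-prevalence constant predictor

    R²_logloss = 1 − LL(model) / LL(baseline)

(1 = perfect, 0 = no better than prevalence, negative = worse), plus
per-class TPR, F1 and one-vs-rest R²_logloss. The meta-learner is applied
strictly out-of-fold (nested stacking), so reported numbers carry no
stacking leakage.

**Change analysis.** Class probabilities can be aggregated onto a coarser
legend (the bundled scheme maps the 20 BIOME 6000 classes onto the six
terrestrial IUCN biomes T1–T6) by summing mapped probabilities — mass is
conserved exactly. Hard-class maps of two epochs are differenced; a pixel
counts as a transition only where MoV ≥ 50 % on both maps (configurable).
Transition areas are tallied in km² with the exact spherical-zone formula
on the authalic sphere (R = 6371.0072 km), and an agreement map counts how
many scenarios flag each pixel.

A seeded synthetic-data module generates the whole study end-to-end:
smooth autocorrelated covariate fields with a latitudinal temperature
gradient, labels from a recorded nested-threshold rule with geometric
class imbalance, clustered (pollen-site-like) noisy observations, and
future scenario stacks built by additive warming / multiplicative
precipitation scaling.

## Worked example

```python
import numpy as np
from biomeshift import (standard_fixture, assign_blocks, make_spatial_folds,
                        run_spatial_cv, fit_stacked_model,
                        predict_probabilities, margin_of_victory)

fx = standard_fixture(seed=1)           # 128x128 grid, 8 covariates,
blocks = assign_blocks(fx["observations"])   # K=6 skewed classes, 2500 pts

report = run_spatial_cv(fx["X"], fx["y"], blocks, k=5, repeats=1,
                        seed=0, class_list=fx["legend"])
print(report.summary)

folds = make_spatial_folds(blocks, k=5, repeat_index=0, seed=0)
model = fit_stacked_model(fx["X"], fx["y"], folds,
                          feature_names=fx["feature_names"],
                          class_list=fx["legend"], seed=0)
cube, sd = predict_probabilities(model, fx["stack"])
mov = margin_of_victory(cube)
print("MoV range:", np.nanmin(mov), np.nanmax(mov))
```

prints (one repeat of the spatial CV, then the confidence layer range):

```
{'accuracy_mean': 0.8864, 'accuracy_sd': 0.0,
 'logloss_mean': 0.5617277276741146, 'logloss_sd': 0.0,
 'r2_logloss_mean': 0.5070323605744046, 'r2_logloss_sd': 0.0}
MoV range: 0.28549070660952935 96.48440136824601
```

i.e. the stack recovers ~89 % of the noisy rule-generated labels under
*spatial* cross-validation and halves the baseline logloss
(R²_logloss ≈ 0.51); pixel confidence spans nearly the full MoV range, so
the ≥ 50 % transition filter is genuinely selective. The per-class table in
`report.class_table` shows the typical imbalance signature: abundant
classes score TPR/F1 ≈ 0.8–0.99 while the rarest (≈ 0.3 % prevalence)
scores near 0.

The same analysis, end to end with all artifacts written to disk, runs as

```bash
biomeshift demo -o demo_out        # bundled synthetic demo
biomeshift validate my_config.yaml
biomeshift run my_config.yaml
```

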