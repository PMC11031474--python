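# sectorvit

Multimodal prediction of **MGMT promoter methylation** in adult diffuse
glioma with a *sector-split* vision transformer, and identification of the
dominant input modality by **sector-level permutation importance**.

## The problem

Whether a glioma's MGMT promoter is methylated guides chemotherapy decisions,
but determining it requires tissue. Imaging-based prediction is attractive —
yet the available evidence is split across heterogeneous inputs: patient
demographics, hand-engineered radiomic features from several tumor
compartments, and the MR images themselves. Conventional CNNs consume one
image modality at a time and, because they entangle all inputs, make it hard
to ask *which* input actually drives the prediction.

`sectorvit` addresses both problems with one transformer that hosts nine
input **sectors** — 1 demographic (age, sex), 6 radiomic (CE-T1WI and T2WI x
enhancing tumor / necrotic core / peritumoral edema, 64 ANOVA-selected
features each) and 2 image sectors (the 128x128 CE-T1WI and T2WI slices) —
plus a class token. Each sector is tokenized separately (one token per
tabular/radiomic vector, patch tokens per image), encoded by a shared
transformer, and read out by its own logistic head:

    p_s = sigmoid( w_s' · mean(tokens of sector s) + b_s ),   s = 1..9

The total output is the majority vote over the nine sector calls; slice-level
outputs are folded to one prediction per patient by vote (binary) and mean
(probability). All ten heads (incl. the class token) are trained jointly with
binary cross-entropy under Adam (beta1 0.9, beta2 0.999, eps 1e-8, weight
decay 0, AMSGrad off).

The contribution of sector *s* is its **permutation importance**: reassign
sector *s*'s data between patients by a random permutation, re-score the
fixed model, and record the accuracy drop; repeat 100 times, rank sectors by
mean drop and compare them pairwise with the Mann-Whitney U test. Evaluation
ships with the full clinical metric set (accuracy, sensitivity, specificity,
PPV, NPV, F-score, midrank AUC, log loss, Cohen's kappa; percentile-bootstrap
95% CIs) plus McNemar and DeLong tests for paired model comparison.

The transformer, its training loop and the autodiff engine underneath are
implemented in-package on numpy (`sectorvit.autodiff`); gradients are
verified against finite differences in the test suite.

## Worked example

Generate a synthetic cohort with signal planted only in the T2WI edema
radiomic sector, train a small model, evaluate it and recover the planted
sector:

```python
from sectorvit import (SimConfig, generate_cohort, SectorTransformer,
                       ModelConfig, TrainConfig, SECTOR_ORDER)
from sectorvit.cohort import (balance_classes, split_by_patient,
                              select_sector_features, apply_feature_selection,
                              encode_demographics)

effects = {s: 0.0 for s in SECTOR_ORDER}
effects["T2WI-ED"] = 2.0                      # planted dominant sector
cohort, _ = generate_cohort(SimConfig(
    n_patients=60, images_per_patient_mean=8, images_per_patient_sd=2,
    class_prevalence=0.5, sector_effects=effects, seed=1))

cohort = balance_classes(cohort, seed=1)
train_c, test_c = split_by_patient(cohort, test_fraction=0.25, seed=1)
selected = select_sector_features(train_c, k=64)   # ANOVA top-64 per sector
apply_feature_selection(train_c, selected)
apply_feature_selection(test_c, selected)
encode_demographics(train_c, test_c)

model = SectorTransformer(train_c, ModelConfig(
    embed_dim=32, depth=2, n_heads=4, patch_size=32, seed=1))
res = model.fit(TrainConfig(epochs=80, batch_size=16, learning_rate=1e-3, seed=1))

rep = res.evaluate(test_c, level="patient", n_boot=500, seed=1)
print(f"patient accuracy {rep.point['accuracy']:.3f} "
      f"(95% CI {rep.ci_low['accuracy']:.3f}-{rep.ci_high['accuracy']:.3f}), "
      f"AUC {rep.point['auc_roc']:.3f}")

ranking = res.sector_importance(test_c, n_rep=20, base_seed=1)
best = ranking.sectors[0]
print(f"most important sector: {best} "
      f"(mean PI {ranking.results[best].pi_mean:.3f})")
```

Output:

```
patient accuracy 1.000 (95% CI 1.000-1.000), AUC 1.000
most important sector: T2WI-ED (mean PI 0.473)
```

Read: on held-out patients every patient is classified correctly (the
planted per-slice effect d = 2 is strong, and patient-level voting averages
out slice noise), and permuting the T2WI-ED radiomic sector between patients
costs the model ~0.41 of image-level accuracy — far more than any other
sector — so the analysis correctly identifies the planted dominant modality.

A pipeline CLI wraps the same steps (`sectorvit simulate / prepare / train /
evaluate / importance / all --config cfg.yaml --out-dir run/`), reading raw
cohorts as NIfTI volumes + CSV tables and writing metrics JSON, prediction
CSVs and importance summaries with per-stage caching.

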