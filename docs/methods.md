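# Methods

## The model

`sectorvit` implements a *sector-split* vision transformer for predicting
MGMT promoter methylation (methylated vs unmethylated) in adult diffuse
glioma from three heterogeneous input modalities:

- **demographics** — age (z-scored on training statistics) and sex (0/1),
  one sector of length 2;
- **radiomics** — six sectors of 64 features each, one per MR modality
  (contrast-enhanced T1-weighted, T2-weighted) x tumor compartment
  (enhancing tumor ET, necrotic core NCR, peritumoral edema ED);
- **images** — the two 128x128 MR slices themselves.

Each sector is tokenized independently: a tabular or radiomic sector becomes
a single token through a learned affine projection of the whole vector; an
image sector becomes a grid of patch tokens (default 16x16 patches -> 64
tokens) through a per-patch projection.  Learned positional embeddings are
added per token, a learned class token is prepended, and the sequence runs
through a shared pre-norm transformer encoder (multi-head self-attention +
GELU MLP, residual connections, dropout).  Each of the nine data sectors has
its own logistic prediction head applied to the mean of its output tokens;
the class token has a tenth head.  The **total model output** is the majority
vote of the nine data-sector calls (odd count, so no ties); the total
probability is the mean of the voting heads' probabilities.

Per-slice outputs are optionally folded to one prediction per patient
("patient-based analysis"): majority vote for binary calls (ties broken by
whether the mean probability reaches 0.5), arithmetic mean for
probabilities.

### Architecture defaults and why

The detailed architecture of the original model is not fully public, so the
hyperparameters are exposed in `ModelConfig` with conservative ViT-style
defaults: `embed_dim=64, depth=4, n_heads=4, mlp_ratio=2.0, patch_size=16,
dropout=0.1`.  Two genuinely open design points are configuration switches
rather than hard-coded guesses:

- `attention_scope`: `"joint"` (default; one encoder attends across all
  sectors) or `"sector-restricted"` (each sector's tokens attend only within
  the sector, while the class token reads — but is not read by — every
  token).  The restricted mode gives a provable isolation property used in
  the tests: permuting one sector's content cannot change any other sector
  head's output.
- `vote_members`: the nine data sectors by default (odd, tie-free); the
  class-token head can be added to the vote, in which case even-count ties
  break by mean probability.

Tabular and radiomic sectors map to one token each — the simplest faithful
reading of "flatten every array to 1-D, project per sector".  A multi-token
split of long vectors is possible by adjusting the sector specs but is not
the default.

## Training

All ten heads are trained against the same slice-level label with binary
cross-entropy (probabilities clipped to [1e-7, 1-1e-7]); the loss is the
uniform (configurable) weighted mean over heads.  Per-head losses are
required anyway to report per-sector performance.  The optimizer is Adam
with beta1 = 0.9, beta2 = 0.999, eps = 1e-8, weight decay 0, AMSGrad off —
implemented in-package (the whole network runs on a small reverse-mode
autodiff engine over numpy, `sectorvit.autodiff`; gradients are verified
against finite differences in the test suite).  The learning rate is not
fixed by the source setting and defaults to 1e-4; the experiments in this
repository use 1e-3 with batch size 16, which trains the small
(embed 32 / depth 2) configuration to convergence within ~80 epochs on the
synthetic cohorts described below.  Determinism: parameter initialization is
seeded by `ModelConfig.seed`, shuffling and dropout by `TrainConfig.seed`;
two runs with the same seeds agree to floating-point reproducibility on a
single thread.  A non-finite loss aborts training and restores the
parameters from the end of the last finite epoch.

## Cohort construction

Raw inputs are per-patient NIfTI volumes (two modalities plus a BraTS-coded
segmentation: 1 = NCR, 2 = ED, 4 = ET), a manifest CSV and per-slice
radiomic tables.  Processing order:

1. slices whose segmentation covers fewer than 256 pixels are dropped;
2. patient-level exclusions: (i) missing age/sex, (ii) missing MGMT label,
   (iii) any slice with an unextractable radiomic sector, (iv) image count
   outside mean +/- k*SD of the per-patient counts.  k is not stated by the
   source criterion ("far from the standard deviation of the mean number of
   images") and defaults to 2; criterion (iv) is applied before class
   balancing, in the order the criteria are listed;
3. each retained image is cropped to the inclusive bounding box of the
   tumor mask and resized to 128x128 with Pillow's Lanczos kernel;
4. class balancing at the image level: majority-class images are subsampled
   uniformly (seeded) until the two label counts match — individual images
   are removed, not whole patients;
5. patient-level train/test split (no patient straddles the split);
6. per-sector ANOVA feature selection **on the training split only**: for
   each of the six radiomic sectors the 64 candidates with the highest
   two-group F-value are kept (ties break by stable input order) and the
   same selection is applied to the test split;
7. age is z-scored with training-split statistics.

The 105 radiomic feature definitions themselves are out of scope: the
package consumes feature tables produced by an external extractor.

## Permutation importance

For one sector: draw a uniformly random permutation of patient identities
(identity mappings allowed; a derangement mode is available), give every
patient the named sector's data of their assigned donor — cycling the
donor's slices in order when slice counts differ — leave labels and all
other sectors untouched, re-score the *fixed* trained model, and record
original minus permuted accuracy.  This is repeated (default 100 times,
seeds `base_seed + r`) per sector; the summary is the mean with a percentile
CI over repetitions, at either image or patient level.  Sectors are ranked
by mean importance and compared pairwise with the two-sided Mann-Whitney U
test (exact enumeration for small tie-free samples, normal approximation
with tie correction otherwise).

Under a uniform permutation the expected permuted accuracy of a perfect
single-sector model is sum_c (n_c/n)^2 (each patient's donor is marginally
uniform), which the tests verify by exhaustive enumeration on a 4-patient
cohort.

## Evaluation statistics

Accuracy, sensitivity, specificity, PPV, NPV, F-score (harmonic mean of PPV
and sensitivity), Cohen's kappa, midrank (Mann-Whitney) AUC and natural-log
loss (clip 1e-15).  Undefined ratios are reported as missing, never as 0.
The **positive class defaults to unmethylated**: reconstructing the printed
patient-level test matrix (20 methylated / 10 unmethylated, sensitivity
0.600, specificity 0.950) yields integer cells only under that orientation
(tp=6, fn=4, tn=19, fp=1), which also reproduces the published accuracy
0.833, PPV 0.857, NPV 0.826, F 0.706 and kappa 0.595.  Confidence intervals
are percentile bootstrap (1000 resamples, seeded); the CI method is not
named by the source, and the asymmetry of the published intervals is
consistent with resampling.  Paired comparisons: McNemar on discordant
counts (exact two-sided binomial below b+c = 25, chi-square with continuity
correction above) and DeLong's placement-value test for correlated AUCs.

## Synthetic cohorts

The generator emulates the structure the analysis assumes: ~152 patients by
default with a truncated-normal number of slices each (mean 12.86), age ~
N(62, 10) truncated at 18, ~70% male, 72% methylated prevalence — matching
the study population's marginals — plus per-sector class signal.  Radiomic
sectors get a standardized mean shift d on a random informative subset
(8 of 105 features by default); image sectors get an elliptical
three-compartment "tumor" blob (area >= 256 pixels by construction) whose
intensity and speckle contrast shift with the label; demographics shift the
age mean by d standard deviations.  Default effect sizes place the strongest
signal in the T2WI-ED radiomic sector, echoing the finding the importance
analysis is meant to recover.  The generator does **not** model MR physics,
spatial correlation between slices of one patient (slices are conditionally
independent given the label), realistic radiomic covariance, or
scanner/site effects — so passing tests demonstrate correctness of the
machinery and recoverability of planted signal, not clinical performance.

An `excludable` slice mode emits masks with exactly 255 pixels for boundary
tests of the small-mask filter.

## Problem sizes used in the shipped experiments

The acceptance script and the heavier tests run the full pipeline on a
scaled-down cohort — 60 patients with ~8 slices each, balanced prevalence,
a 75/25 patient split, the small model (embed 32, depth 2, patch 32) and
80 training epochs — chosen so the whole analysis runs comfortably on one
CPU while leaving the planted-signal recovery unambiguous.  Held-out
performance is judged at the patient level (vote over a patient's slice
calls), the clinical unit and the primary analysis level of the study design
this follows; image-level metrics and image-level permutation importance are
reported alongside.  Patient-level voting averages out per-slice noise, so
patient-based accuracy runs systematically higher than image-based accuracy
— the same pattern the published tables show.  Published
real-data performance (patient-based accuracy 0.833, AUC 0.840) requires
the external UCSF-PDGM collection and full-scale training and is therefore
represented only by the arithmetic reconstruction of the printed confusion
matrices, not re-estimated.

## Known limitations

- The autodiff engine implements exactly the operations this model needs;
  it is not a general deep-learning framework (no GPU, float64 only).
- Permutation importance is sector-level; within-sector (per-feature)
  attribution is out of scope.
- The exact-vs-asymptotic switches (McNemar at b+c = 25, Mann-Whitney exact
  below n = 20 without ties) follow common practice; near the switch points
  p-values from the two regimes differ slightly.
- Bootstrap CIs resample slices (or patients, at the patient level)
  independently; within-patient correlation of slices is ignored at the
  image level, as in the source analysis.
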