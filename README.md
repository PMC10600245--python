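# radrepeat

Perturbation-based radiomic feature repeatability and model reliability
analysis for 3D medical images.

## The problem

Radiomic models predict clinical endpoints (here: a binary treatment
response) from hundreds of quantitative descriptors extracted from an
image inside a tumor segmentation. Many of those descriptors are not
*repeatable*: rescan the same patient, or redraw the contour, and the
value changes. Models built on non-repeatable features generalize
poorly and give unstable predictions. The gold standard for measuring
repeatability — test–retest imaging — is rarely available, so this
package implements the alternative: **image perturbation**, which
manufactures pseudo-retest data by applying small random rigid
transforms and contour randomizations to a single scan, and then
quantifies both feature- and model-level reliability.

The pipeline, end to end:

1. **Perturbation** — per subject, *n* random combinations of an
   in-plane rotation θ ∈ {−5°, 0°, 5°} about the axial axis through the
   mask bounding-box centre, a per-axis sub-voxel translation with
   magnitude from {0, 0.2, …, 0.8} px, and a contour randomization that
   warps the mask with a smooth random displacement field (uniform(−1,1)
   draws, slice-constant z-component, per-dimension RMS normalized to a
   physical intensity, Gaussian-smoothed).
2. **Feature extraction** — IBSI-style shape (14), first-order (18) and
   texture (GLCM 24, GLRLM 16, GLSZM 16, GLDM 14, NGTDM 5) features from
   the original image, five Laplacian-of-Gaussian scales (1–5 mm) and
   eight coiflet-1 undecimated wavelet decompositions, after 1 mm
   isotropic resampling and 32-bin fixed-bin-number discretization:
   14 + 14 × 93 = **1316 features** per subject.
3. **Repeatability** — per-feature one-way random-effects ICC,

   ICC(1) = (MS_R − MS_W) / (MS_R + (k − 1)·MS_W),

   with McGraw–Wong F-based 95% CIs, computed from the perturbed repeats
   and (when available) test–retest pairs.
4. **Modelling** — remove volume-dependent features (|r| > 0.6 with mesh
   volume), keep features with ICC ≥ a threshold ∈ {0, 0.5, 0.75, 0.9,
   0.95}, rank by mRMR (mutual-information difference), train an
   easy-ensemble (majority-class down-sampling, 500 rounds by default)
   of logistic-regression / SVM / random-forest / Gaussian-naive-Bayes
   members, predict by averaging member probabilities.
5. **Reliability** — internal generalizability as train/test AUC with
   1000-iteration subject bootstrap CIs and permutation comparisons;
   robustness as the ICC of predicted probabilities across perturbed
   and retest inputs (prediction ICC); segmentation similarity as Dice
   and Hausdorff distance.

A synthetic-cohort generator (ellipsoidal tumors with smooth random
boundaries and band-limited internal texture, a logistic outcome linked
to two latent tumor properties, and retest pairs with realistic
segmentation variation) makes every stage testable without clinical
data.

## Worked example

```python
from radrepeat import CohortConfig, generate_cohort
from radrepeat.modeling import ModelConfig
from radrepeat.perturbation import PerturbationSpace
from radrepeat.reliability import run_comparison

cohort = generate_cohort(CohortConfig(seed=11))          # 60 subjects, 32^3, 1 mm
report = run_comparison(
    cohort,
    thresholds=(0.0, 0.5, 0.9),
    model_configs=(ModelConfig("logistic_regression", 5, 50, 0),),
    space=PerturbationSpace(n_perturbations=10),
    n_bootstrap=200, n_permutation=200, seed=11,
)
print(report.rows[["source", "threshold", "train_auc", "test_auc",
                   "icc_train_perturb", "icc_test_perturb", "icc_retest"]]
      .to_string(index=False))
```

prints (about four minutes on one CPU):

```
      source  threshold  train_auc  test_auc  icc_train_perturb  icc_test_perturb  icc_retest
perturbation        0.0   0.976923  0.722222           0.516800          0.529994    0.105677
perturbation        0.5   0.980769  0.759259           0.809717          0.885527    0.181799
perturbation        0.9   0.942308  0.722222           0.980236          0.959754    0.901556
 test_retest        0.0   0.961538  0.759259           0.968143          0.958148    0.441461
 test_retest        0.5   0.969231  0.648148           0.964859          0.942700    0.739920
```

Reading it: each row is one model, trained on features that survived
the volume filter and the ICC threshold for that repeatability source.
Raising the threshold from 0 to 0.9 leaves discrimination intact
(test AUC ≈ 0.72–0.76) while the model's prediction repeatability
climbs steeply — e.g. the ICC of predicted probabilities under
test–retest rises from 0.11 to 0.90. The test-retest source at
threshold 0.9 is absent because only 2 features survived, fewer than
the 5 the model needs; the skip is recorded in `report.skipped`.

## Command line

```bash
radrepeat simulate config.yaml   # write a synthetic cohort (NIfTI + CSV)
radrepeat extract  config.yaml   # extract + cache the feature tables
radrepeat icc      config.yaml   # per-feature ICC tables for both sources
radrepeat run-all  config.yaml   # the full comparison + report
```

`config.yaml` holds a `cohort:` section (or `input_dir:` pointing at
NIfTI files), perturbation/preprocessing settings, thresholds and
classifier kinds; `run-all --icc-k-plus-1` switches the ICC
denominator to the (k + 1) audit variant.

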