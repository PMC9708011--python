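# cinempca

Prognostic machine learning for time-resolved cardiac cine MRI.

Pulmonary arterial hypertension (PAH) carries high untreated mortality, and
cardiac MRI sees far more than the volumetric indices usually extracted
from it. This package implements an interpretable pipeline that predicts
1-year mortality directly from registered 2D+time cine image stacks — a
mid-chamber short-axis (SA) and a four-chamber (4Ch) view per subject —
and maps the learned evidence back onto the images, so the prognostic
anatomy can be read off frame by frame across the cardiac cycle. It is
aimed at imaging researchers who want a transparent (non-deep-learning)
baseline for survival prediction from cine MRI, complete with a synthetic
cohort generator that makes every stage testable without patient data.

## The model

Each preprocessed study is a tensor **X** ∈ R^(S×S×T) (space × space ×
cardiac phase). Multilinear PCA finds per-mode orthonormal bases
U⁽¹⁾, U⁽²⁾, U⁽³⁾ maximizing captured scatter and projects

    Z = (X − X̄) ×₁ U⁽¹⁾ᵀ ×₂ U⁽²⁾ᵀ ×₃ U⁽³⁾ᵀ,

keeping spatial–temporal structure a vectorized PCA would destroy. Core
entries are ranked by Fisher's discriminant ratio
(μ₁−μ₀)²/(σ₁²+σ₀²), a stepwise search against a held-out tuning set
(~50 cases) picks the feature count, and a linear SVM with Platt-calibrated
probabilities scores mortality per view; a dual-scan SVM fuses the two
views. Development uses repeated stratified cross-validation (10×10 by
default) with MPCA, ranking and selection refit inside each fold's training
portion. Evaluation is survival-native: Cox proportional hazards (Efron
ties), Harrell's c-index, AIC, likelihood-ratio tests between nested
models, Kaplan–Meier curves split at the median training probability with
log-rank p, 1-year ROC/AUC, and scaled-Schoenfeld proportional-hazards
checks. Because the classifier is linear, its evidence back-projects
through the MPCA bases into a signed voxel map (positive = mortality
evidence, negative = survival evidence), which is thresholded, cleaned by
morphological closing with a radius-2 sphere over (x, y, t), and reduced to
clusters and per-frame regional profiles.

## Worked example

```python
from cinempca import RunConfig, SyntheticConfig, run_full_study

config = RunConfig(
    out_dir="out", image_size=64, cv_rounds=1, cv_folds=5, seed=17,
    synthetic=SyntheticConfig(n_subjects=500, image_size=64, seed=17),
)
report = run_full_study(config)
for key in ("SA_validation_auc_1yr", "combined_validation_c_index",
            "combined_cox_hr_per_sd", "lrt_p_add_mpca", "SA_saliency_dice"):
    print(key, round(report.metrics[key], 3))
```

prints

```
SA_validation_auc_1yr 0.891
combined_validation_c_index 0.704
combined_cox_hr_per_sd 1.682
lrt_p_add_mpca 0.021
SA_saliency_dice 0.889
```

Read: on a 500-subject synthetic cohort with a septal end-systolic lesion
tied to a latent risk (10% 1-year mortality), the short-axis model reaches
a validation AUC of 0.89 for 1-year death; the fused probability carries a
hazard ratio of 1.68 per SD with a validation c-index of 0.70; adding it to
a clinical-score-only Cox model is a significant improvement (LRT p =
0.021); and the largest positive saliency cluster overlaps the planted
lesion with Dice 0.89. A `report.json` with all metrics, the cohort split,
and the provenance audit lands in `out/`.

The same flow is scriptable from the shell:

```bash
cinempca simulate --n-subjects 200 --seed 1 --out cohort/
cinempca preprocess --cohort cohort/ --view SA --size 64 --out prep/
cinempca run-all --n-subjects 200 --seed 1 --out out/
```

## Layout

| Module | Contents |
| --- | --- |
| `cinempca.synthetic` | cohort generator: heart template, planted signal, proportional-hazards outcomes |
| `cinempca.preprocess` | z-scoring, Procrustes reference, rigid registration, elliptical mask, downsampling |
| `cinempca.mpca` | MPCA fit / project / reconstruct |
| `cinempca.selection` | Fisher ranking, stepwise selection, SVM + calibration, cross-validation, dual-scan fusion |
| `cinempca.survival` | Cox, c-index, AIC, LRT, Kaplan–Meier/log-rank, 1-year ROC, Schoenfeld checks |
| `cinempca.saliency` | back-projection, thresholding + morphology, clusters, regional profiles, overlays |
| `cinempca.pipeline` | cohort split, orchestration, provenance audit |
| `cinempca.cli` | `cinempca` command-line interface |

See `docs/methods.md` for the full statistical account and design
rationale.
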