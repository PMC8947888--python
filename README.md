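# pneumotex

Wavelet-entropy texture analysis for pneumoconiosis screening on chest
images.

Occupational pneumoconiosis shows up on radiographs as diffuse small
nodular shadows of varying size, density and distribution — a *texture*
change rather than a focal lesion. `pneumotex` implements a complete,
reproducible texture-diagnosis pipeline for this setting, aimed at medical
image-analysis researchers who want a tested reference implementation and a
synthetic test bed:

1. **Synthetic cohorts** — seeded chest-like images (two bright elliptical
   lung fields, correlated background texture) with stage-dependent nodular
   opacities (stage I < II < III in count and contrast), so every downstream
   stage is testable without clinical data.
2. **Lung-field segmentation** — global histogram equalization, maximum
   between-class variance (Otsu) thresholding, and morphological-
   reconstruction cleanup (opening-by-reconstruction, hole filling, two
   largest components).
3. **Wavelet-entropy features** — 8-level 2D discrete wavelet transform
   (Daubechies db7). For level *i* with detail coefficients {S_ik}:

       E_i = Σ_k S_ik²,   p_i = E_i / Σ_j E_j,   H_i = −p_i ln p_i,
       T_i = ln H_i

   giving the feature vectors H = [H₁…H₈] and T = [T₁…T₈].
4. **Feature selection** — a C4.5-lineage decision tree (binary splits on
   continuous attributes, gain-ratio criterion); the features tested at the
   tree's internal nodes form the selected subset.
5. **Classification** — soft-margin SVM with linear, polynomial
   ((x·y + 1)^q, q = 3) and Gaussian (exp(−‖x−y‖²/2σ²), σ² = 0.1) kernels,
   solved by a deterministic SMO; decision values are Platt-calibrated to a
   score C ∈ (0, 1), with C ≥ 0.5 read as "patient".
6. **Evaluation** — stratified 5-fold cross-validation with pooled scores,
   accuracy / sensitivity / specificity, ROC and trapezoidal AUC.
7. **Staging agreement** — Cohen's kappa with conventional interpretation
   bands, per-stage detection rates against an expert gold standard, exact
   McNemar and Pearson chi-square tests for paired modality comparison.

The learned components are sklearn-style estimators (`GainRatioTree`,
`GainRatioTreeSelector`, `KernelSVC`, `WaveletEntropyExtractor`) and compose
with sklearn pipelines and model selection.

## Worked example

```python
from pneumotex import (DEFAULT_STAGE_SPECS, KernelSVC, apply_mask,
                       confusion_metrics, cross_validate, enhance,
                       entropy_vector, generate_image, roc_auc,
                       segment_lung_fields)
import numpy as np

# one synthetic stage-III exam
img = generate_image(DEFAULT_STAGE_SPECS["III"], 256, 256, seed=2)
mask = segment_lung_fields(enhance(img))
fv = entropy_vector(apply_mask(img, mask), mask=mask)
print(np.round(fv.log_features, 3))
```

```
[-2.818 -2.446 -2.109 -1.974 -1.754 -1.626 -1.022 -1.021]
```

T₃ = −2.109 is the log wavelet entropy of decomposition level 3 (detail
scale ≈ 8 px, the nodule scale); the disease-free render of the same seed
gives T₃ = −2.246. Nodular opacities concentrate extra energy — and hence
relative-energy entropy — at their own scale, and over a cohort this shift
at levels 3–4 is what the classifier exploits (single images vary; the
group-level separation is what the tests assert).

On a full 60 + 60 cohort the whole pipeline can be run from one config:

```bash
pneumotex run --config run.toml      # or: python -m pneumotex.cli
```

which writes `manifest.csv`, `masks/`, `features.csv`, `tree.json`,
`report/metrics.csv` (accuracy/sensitivity/specificity/AUC per kernel ×
feature-set condition) and a `run.json` reproducibility record. Identical
configs reproduce every artifact byte-for-byte.

For the staging-agreement side:

```python
from pneumotex import cohen_kappa, cross_table
import pandas as pd
staging = pd.read_csv("staging.csv", dtype=str)   # case_id,gold,stage_a,stage_b
print(cohen_kappa(cross_table(staging)))
```

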