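# ptsscore

Quantitative peri-tumoral stroma (PTS) scoring of H&E colon-cancer
histology, and the statistics that relate the score to lymph-node
metastasis (LNM).

Tumor-associated stroma near the invasive front is a prognostic feature of
colorectal cancer, but manual tumor–stroma assessment is slow and poorly
reproducible. This package implements a fully computational alternative
aimed at computational-pathology researchers: segment a slide into seven
tissue classes (colon cancer epithelium, stroma, lymphocytes, mucus,
adipose, smooth muscle, normal mucosa), delineate the *tumor region* by
morphological closing of the cancer-epithelium mask, and score the stroma
captured inside that region:

```
PTS score = |{stroma pixels inside close(tumor mask, SE)}| / |tumor mask|
```

where `close(·, SE)` is binary dilation followed by erosion with a
structuring element SE (default: disk of radius 64 px at 0.5 µm/px). The
score is a dimensionless ratio ≥ 0 and may exceed 1 on stroma-rich slides.
At the cohort level, the score enters unadjusted logistic regressions of
LNM and of extramural invasion flags (lymphatic LI, venous VI, perineural
PI, any of the three AnyI), with Wald odds-ratio confidence intervals,
ROC AUC with a DeLong-style interval, Student's t / Pearson chi-square
descriptives, and a T-stage-stratified subgroup analysis (T0–T2 vs T3–T4).

The pipeline stages:

1. **stain normalization** — Macenko stain-vector estimation (SVD of the
   optical-density cloud, angular-percentile extremes) and remapping to a
   reference H&E basis, then per-channel histogram rescale to [0, 255];
2. **segmentation** — a U-Net (implemented directly on numpy: im2col
   convolutions, batch norm, transposed-conv upsampling, Adam) trained on
   224 px patches reflect-padded to the network input, with an 80/10/10
   stratified split and early stopping when the validation mean Dice
   similarity coefficient (DSC) stops improving by ≥ 0.1 % for 10 epochs;
3. **morphology** — closing-based tumor-region delineation and PTS scoring;
4. **cohort analysis** — the statistical layer above.

Because the original whole-slide archives are not redistributable, a
first-class synthetic-data module generates color-separable labeled tiles,
whole-slide label maps with *analytically known* PTS scores, and patient
cohorts in which logit P(LNM) is linear in the PTS score — so every stage
is testable end to end with exact ground truth.

## Worked example

Score a synthetic slide whose ground truth is known exactly — a
100×100 px tumor square containing a 20×20 px stroma island:

```python
from ptsscore import (StructuringElement, WsiGeometrySpec,
                      compute_pts, make_wsi_labelmap)

spec = WsiGeometrySpec(canvas=(130, 130), tumor_box=(10, 10, 100, 100),
                       holes=((50, 50, 20, 20),))
labels, truth = make_wsi_labelmap(spec)
result = compute_pts(labels, StructuringElement.disk(15))
print(result)
```

prints

```
PtsResult(tumor_area=9600, pts_area=400, score=0.041666666666666664, se_name='disk(r=15)')
```

The tumor area is 100·100 − 400 = 9600 px (the island is not tumor), the
closing fills the 20 px gap so all 400 stroma pixels fall inside the tumor
region, and the score equals the analytic 400/9600 exactly. The same is
available from a shell:

```sh
ptsscore pts --labels slide_labels.png --se-radius 15
# {"tumor_area": 9600, "pts_area": 400, "score": 0.0416..., "structuring_element": "disk(r=15)"}
```

A full synthetic run — tile synthesis, U-Net training, slide segmentation,
PTS scoring, cohort statistics, with a checksum manifest proving rerun
determinism:

```sh
ptsscore run --out pts_run --seed 11
```

On the default desk-scale configuration this trains to a test overall mean
DSC of 1.0 on held-out zero-noise tiles and recovers per-slide PTS scores
within 0.02 of each slide's analytic expectation (see
`pts_run/S*_pts.json`).

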