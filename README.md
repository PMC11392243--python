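# echoflow

Detection of **regional wall motion abnormality (RWMA)** — the early
echocardiographic signature of myocardial infarction — from multi-view
(apical two-chamber + four-chamber) grayscale echo loops, using motion-field
features rather than hand-picked displacement peaks.

The pipeline has three phases:

1. **Cardiac structure segmentation.** A U-shaped encoder–decoder network
   (23 convolutional layers at the default depth) predicts the left
   ventricular wall mask per frame; frames are background-zeroed with the
   mask so later stages see only wall tissue.
2. **Motion feature engineering.** Dense optical flow
   `E_t(u, v) = F(I_t, I_{t+1}; θ_F)` is computed between every pair of
   consecutive masked frames under brightness-constancy + smoothness
   assumptions, and stored as 8-bit horizontal/vertical flow-frame pairs.
   A temporal-segment ConvNet scores `k = 7` sparsely sampled snippets
   (each a 224×224×10 stack of 5 consecutive flow pairs) with shared
   weights `W`,

   TSN(T₁…T_k) = H( g( F(T₁;W), …, F(T_k;W) ) ),

   where the segmental consensus `g` is the element-wise average and `H`
   the softmax; training minimises the consensus cross-entropy
   L(y, G) = −Σᵢ yᵢ (Gᵢ − log Σⱼ e^{Gⱼ}).  The layer feeding the
   classification head — the flattened 4×4×64 last max-pool output — is the
   1024-dimensional per-view motion feature.
3. **RWMA detection.** The A2C and A4C features are concatenated into a
   2048-vector and classified by a bank of KNN / decision-tree / random
   forest / SVM / MLP models, each grid-searched on the training fold and
   evaluated under stratified 5-fold cross-validation with the standard
   confusion-matrix metrics (TPR, FPR, SPE, precision, F1, ACC) and ROC AUC.

Because clinical recordings cannot ship with a package, everything is
exercised end to end on **synthetic beating-heart phantoms**: a U-shaped
bright wall contracting radially with a known per-segment amplitude,
controllable territorial hypokinesia, material-anchored speckle, and paired
ground-truth masks.  A contour-kinematics module (arc-length partition of
the wall into the apical 1/7 and three 2/7 segments per arm, displacement
curves vs the first frame) closes the loop between generated and measured
motion.

Networks are implemented on a compact numpy layer library with explicit
backpropagation (`echoflow.nn`), sized for CPU training at phantom scale.

## Worked example

```python
from echoflow import PhantomConfig, PipelineConfig, run_pipeline

cfg = PipelineConfig(
    workdir="run",
    n_rwma=20, n_normal=20,          # detection cohort
    phantom=PhantomConfig(image_size=64, frames_per_cycle=25, n_cycles=2,
                          hypokinesia_factor=0.3),
)
res = run_pipeline(cfg)
for name, r in res.results.items():
    print(name, r.aggregates["accuracy"]["mean"], round(r.mean_auc, 3))
```

Output from this exact configuration (about 7 minutes on one CPU core):

```
KNN 95.0 0.975
DT 100.0 1.0
RF 97.5 1.0
SVM 95.0 0.988
MLP 92.5 0.938
```

Each line is one classifier's mean out-of-fold accuracy (percent, over the
5 folds) and mean ROC AUC on the 40-subject phantom cohort: with a
hypokinesia factor of 0.3 (affected territories move at 30 % of normal
amplitude) every classifier separates abnormal from normal wall motion well
above chance, and a label-permutation rerun collapses AUC to ≈ 0.5.  The run
directory contains `features.csv` (2048-d fused features), `predictions.csv`
(out-of-fold predictions per classifier), `report.json` and `run.log`.

A CLI mirrors the stages: `echoflow generate | segment | flow | detect |
run-all` (see `echoflow --help`).

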