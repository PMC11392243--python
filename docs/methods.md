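# Methods

## The model

RWMA detection is framed as binary classification of a subject from the
*motion field* of the left-ventricular wall observed in two apical views
(A2C, A4C) over several cardiac cycles, rather than from displacement-curve
peaks in one selected cycle.  The three stages and their contracts:

**Segmentation.** A U-shaped encoder–decoder: per resolution level two 3×3
convolutions + ReLU, 2×2 stride-2 max pooling down, 2×2 up-convolutions with
skip concatenation up, and a final 1×1 class-score convolution — 23
convolutional layers at the default depth of 5.  We use *same*-padded
convolutions so the predicted mask has the frame's size with no cropping
bookkeeping (the textbook description uses unpadded convolutions; the
downstream pipeline needs mask = frame geometry, so padding is the cleaner
contract).  Binarisation threshold is 0.5 on the foreground softmax score,
followed by a largest-connected-component filter to suppress speckle
islands.  Segmentation is binary wall-vs-background: only the LV wall feeds
the flow stage.

**Flow.** Dense optical flow between consecutive masked frames under
brightness constancy + local smoothness, computed with a coarse-to-fine
iterative Lucas–Kanade scheme (`skimage.registration.optical_flow_ilk`,
Gaussian window, radius 7, 10 warps).  Conventions: `u` positive rightward,
`v` positive downward, origin top-left, px/frame, forward motion (frame t →
t+1).  Flow is zeroed where both frames are blank: brightness constancy
carries no information on the masked-out background, and the pyramid would
otherwise extrapolate wall motion into it.  Fields are stored as 8-bit
pairs: components clipped to ±clip and mapped affinely to [0, 255] (zero ↦
128, worst-case round-trip error clip/255).  For phantom studies clip
defaults to 10× the analytic peak endocardial speed `A·π/T`; the generic
default is 20 px/frame.

**Temporal-segment features.** The flow-pair sequence is cut into `k = 7`
equal-duration segments; one snippet of 5 consecutive (x, y) pairs — a
10-channel image — is drawn per segment (random offset in training, central
offset at inference, so inference is deterministic).  A compact residual
ConvNet (conv 10→16 stride 2, two residual blocks, widths 16/32/64, max-pool
to 4×4) scores all snippets with shared weights; the consensus is the
element-wise average of snippet scores, and the video prediction its
softmax.  Training minimises the consensus softmax cross-entropy with one
optimisation step per loop (each snippet receiving 1/k of the consensus
gradient).  The per-view motion feature is the consensus average of the
flattened 4×4×64 last-max-pool activations — exactly 1024 values.
Sequences shorter than k×5 pairs are rejected, not padded.  A full
2048-d-backbone variant with a learned projection is not provided: the
package targets CPU-scale training, and the compact backbone already
realises the 1024-d feature contract.

**Detection.** Per-subject features of the two views are concatenated (A2C
block first; 2048 values; missing views are an error, never imputed) and
classified by KNN, decision tree, random forest, SVM and MLP under
stratified 5-fold cross-validation.  Default grids: KNN k∈{3,5,7,9}; DT
depth∈{3,5,10,None}; RF trees∈{100,300}; SVM kernel∈{RBF,linear},
C∈{0.1,1,10}; MLP hidden∈{128,256}.  Model selection is by mean inner-CV
accuracy on the training fold only, ties broken by first-in-grid order.
Features are standardised with train-fold statistics for the
distance/margin models (KNN, SVM, MLP).  Fold assignment, inner CV and
classifier initialisation use independent named seeds.

**Evaluation.** The abnormal class is positive.  TPR = TP/(TP+FN), FPR =
FP/(FP+TN), SPE = TN/(TN+FP), P = TP/(TP+FP), F1 = 2TP/(2TP+FP+FN), ACC =
(TP+TN)/n, all as percentages; AUC is the rank statistic (ties ½) via
trapezoidal ROC integration, reported as a fraction.  Metrics with zero
denominators are reported as NaN with a warning — not coerced to 0 — and
fold aggregation (max/mean/min) skips them.  Rounding (half-up, 2 decimals)
happens only at reporting time.  Multi-view label fusion is the OR rule: a
subject is positive if either view is labelled abnormal.

## Contour kinematics

The wall mask's inner (endocardial) edge is traced by polar unwrapping
about the mask centroid; the largest angular gap is the basal aperture, and
the open curve runs left base → apex → right base.  The apex is the
arc-length midpoint (the split is otherwise under-determined), giving arms
L and R; each arm is tiled base→apex by three spans of 2/7 and an apical
cap of 1/7 of its length.  Displacement of frame t vs frame 0 is the mean
distance between corresponding boundary points within each span, with the
per-segment maximum as the amplitude summary.

Correspondence is by **polar angle about the centroid**, not by normalised
arc length.  For predominantly radial wall motion angle matching is exact
and strictly local, whereas arc-length matching aliases a strongly
contracting region's length change into tangential pseudo-motion of distant
segments — on graded-hypokinesia phantoms this demonstrably scrambles the
rank order of segment amplitudes, which angle matching preserves.  Both
schemes are deterministic and tracking-free; translation equivariance holds
for both (the centroid moves with the mask).

## The phantom generator

The phantom emulates the salient properties of clinical apical echo
recordings: ~25 frames per cardiac cycle, multi-beat loops, two apical
views per subject, 224×224 frames, binary per-subject labels.  Concretely: a U-shaped bright
wall (60° basal aperture) of thickness 0.08·size around an inner radius
0.30·size, contracting radially as A(θ)·(1−cos 2πt/T)/2 with base amplitude
A = 0.045·size (≈ 10 px at 224 — a realistic fractional endocardial
excursion); per-sector amplitudes are smoothed across sector boundaries
(σ = 4°) so the motion field is continuous.  Sector order matches the
kinematics partition (left base→apex 0–3, right base→apex 4–7).
Hypokinesia scales chosen sectors' amplitude by a factor in [0, 1];
cohort generation draws *contiguous* 2–4-sector territories, since infarcts
follow coronary territories.  Speckle is multiplicative Rayleigh noise
anchored to material coordinates (angle, depth-into-wall) — ultrasound
speckle is interference from scatterers fixed in tissue, so the pattern
advects with the wall — plus a small (σ = 0.01) per-frame additive sensor
term.  A deterministic material texture makes motion recoverable from
brightness.  All randomness flows from one integer seed.

What the phantom does **not** model: chamber anatomy beyond the LV wall,
probe artefacts (shadowing, dropout), out-of-plane motion, valve motion,
through-plane speckle decorrelation, and inter-view anatomical differences
beyond texture/geometry jitter.  Passing tests therefore demonstrate that
the pipeline recovers known regional motion deficits under controlled
conditions — not clinical-grade performance on real recordings.

## Study conditions and problem sizes

Phantom defaults are the full-scale clinical conditions (224×224, 25
frames/cycle, 3-beat loops).  The heavier study fixtures run at 64×64 with 2 cycles — the
package's chosen desk scale; all architectural contracts (1024/2048-d
features, 23 layers, 224×224×10 snippet stacks) are still asserted at full
size.  The end-to-end study uses 40 detection subjects (20 RWMA at
hypokinesia factor 0.3, 20 normal) plus 28 disjoint fine-tune subjects for
the segmenter and the two per-view backbones — so network training stays disjoint from the classifier cohort and
out-of-fold estimates remain honest.  Training budgets: 8
epochs for the segmenter (Adam, 2·10⁻³), 25 epochs for the backbones
(Adam, 10⁻³).

The kinematics rank-recovery fixture uses a noiseless 128-px phantom with
graded, well-separated per-segment factors (differences ≥ 0.1, i.e. ≥ 0.6 px
of amplitude): segment amplitudes that differ by less than the ~0.3 px
boundary-quantisation noise of a discrete mask cannot be ranked by any
measurement, so rank equality is only a well-posed requirement above that
resolution.

## Numerical choices and degenerate inputs

* All network tensors are float32; parameter init is He-scaled from a
  seeded generator; results are reproducible given fixed BLAS threading.
* Non-finite flow solver output maps to zero (the field contract is
  finiteness).
* Empty or multi-component masks fail contour extraction loudly with the
  frame index; closed annuli (no aperture) are rejected.
* Grid points that cannot be scored at a given n (e.g. KNN neighbours
  exceeding the inner-fold size) are skipped; if no point is scorable the
  first grid point is used.
* Frame files must be numbered uniquely and gap-free; anything else is
  rejected rather than silently reordered.
* AVI I/O requires an imageio video backend; numbered PNG/TIFF sequences
  are the canonical lossless interchange and are what the tests use.

## Known limitations

* The numpy conv-net library is minimal by design: no batch norm, no GPU,
  no autodiff; it supports exactly the two architectures shipped.
* Phantom realism bounds what green tests mean (see above); in particular
  segmentation Dice ≈ 0.95+ on phantoms says nothing about real-echo Dice.
* Angle-based contour correspondence assumes the wall is star-shaped about
  its centroid — true for apical LV masks, not for arbitrary shapes.
* The classifier bank with n = 40 subjects has wide fold-to-fold variance;
  aggregates report max/mean/min rather than a single headline number.
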