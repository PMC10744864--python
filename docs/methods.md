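# Methods

`octmargin` implements a patch-based deep-learning pipeline for visualizing
suspicious regions in wide-field OCT (WF-OCT) scans of lumpectomy margins:
synthetic phantoms with known ground truth, overlapping-patch decomposition,
a parameter-budgeted grayscale CNN, two-tier confidence thresholding,
density-based clustering of detections, key-thumbnail selection, Grad-CAM
explanations, and an imbalance-aware evaluation suite. This note records the
models, the parameters that matter, and the design decisions taken where the
design was genuinely open.

## The phantom generator

A margin scan is an ordered stack of grayscale B-scans (depth × lateral
position). The phantom reproduces the *statistical structure* that the
downstream stages depend on, not OCT physics:

* **Background** — a smooth horizontal layer profile (piecewise-constant
  depth intensities around a base of 105, layer contrast σ = 15,
  Gaussian-blurred over σ = 12 rows) modulated by spatially correlated
  multiplicative speckle (Gaussian field, σ = 1.5 px, relative strength
  0.22) plus additive sensor noise (σ = 4 intensity units at 8 bit). Layer
  levels are drawn per margin, so margins differ the way subjects differ;
  the layer/speckle amplitudes are deliberately kept below the lesion
  contrast so the lesion remains the dominant brightness structure — the
  "hyper-contrast" contract the downstream classifier depends on.
* **Lesions** — elliptical hyper-intense foci with high-frequency granular
  texture (25% relative grain), mean contrast +80 (8-bit units) over the
  local background. Each lesion spans a contiguous run of ≥ 2 B-scans at
  overlapping column intervals — the interval wobbles by at most ±12 px per
  B-scan (bounded below half the minimum lesion width, so pairwise overlap
  is guaranteed), which both mimics imperfect cross-sectional alignment and
  supplies the lateral-offset diversity a translation-robust classifier
  needs. One suspicious annotation box is emitted per lesion per B-scan.
  Generation is slice-by-slice, so clinical-size volumes stay within ~2 GiB
  of memory.

Defaults mirror a clinical margin (400 B-scans of 420 × 2400 at 8 bit); all
geometry, contrast and texture parameters are configurable, and a fixed seed
makes generation bit-reproducible.

What the phantom does **not** emulate: interferometric speckle statistics,
depth-dependent attenuation, real benign-mimic morphologies (hyperplasia,
duct ectasia), or annotation noise from human readers. Passing the
end-to-end tests therefore demonstrates that the pipeline's machinery is
correct and that the classifier can learn a localized texture/contrast
signal under realistic imbalance — not clinical-grade discrimination.

## Patch decomposition and labeling

B-scans are cut into full-height 420 × 188 windows sliding laterally at a
half-width stride, rounded to integer pixels: stride = round(0.5 × 188) =
94 px (≈ 25 windows on a 2400-column scan under the `align_last` border
policy, which appends a final window flush with the right border; `pad`
zero-fills an overhanging on-grid window instead, and `drop` leaves the
border uncovered). A patch
is labeled positive when it overlaps a suspicious box by at least half the
box width — the label rule is interval arithmetic on columns only, since
patches span the full B-scan height. Around every suspicious annotation,
five extra translated patches are extracted at one fifth of the stride
(19 px), symmetric about the annotation center and clipped to the valid
range; this annotation-dense augmentation is the only class-balance
mechanism enabled by default.

## The classifier

A VGG-style stack fixed at five 3 × 3 convolutions (each followed by ReLU
and 2 × 2 max-pooling) and three fully connected layers on 1-channel
420 × 188 input. Layer widths are free; the defaults
`conv_channels = (4, 8, 16, 32, 32)`, `fc_sizes = (705, 150, 2)` put the
trainable parameter count at **1,588,699** — within 0.02% of the ~1.589 M
budget of an edge-deployable model — while keeping the forward pass around
50 MFLOP/patch, dominated by the wide shallow early stages. The narrow
first stage is deliberate: at 420 × 188 the first feature map dominates
memory traffic, and four first-stage filters are ample for the
bright-granular-blob signal the task presents.

The engine is a compact numpy implementation (im2col / shifted-product BLAS
convolutions, exact backpropagation, Adam) with persistent per-layer scratch
buffers; gradients are verified against central finite differences in
float64 in the test suite. One numerical subtlety: ReLU'(0) = 0 is used, so
finite-difference checks must not sit parameters exactly on the kink.

**Input normalization.** Patches are scaled to [0, 1] by the dtype maximum
and then standardized per patch (zero mean, unit variance). The centering
half of this is load-bearing: with purely non-negative inputs the ReLU
stack reliably collapses to the majority class (verified on a separable toy
problem — AUROC 0.14 uncentered vs 1.0 centered, identical seeds and
budgets). The variance half removes margin-to-margin brightness offsets so
features learned on one scan transfer to another.

**Training.** Softmax cross-entropy, Adam at lr 1e-3, batch 32, ~10 epochs,
with inverted dropout (rate 0.5, the VGG-canonical value) before the two
hidden FC layers — without it the 1.5 M-parameter FC head simply memorizes
the few hundred positive patches a desk-scale phantom corpus provides.
Optional inverse-frequency class weighting is off by default — augmentation
carries the balance. Checkpoint selection: the epoch with the lowest
validation loss, ties broken toward higher validation accuracy and then the
earlier epoch. Training is deterministic under a fixed seed and thread
configuration.

## Two-tier detection and clustering

Per-patch probabilities are thresholded at two nested operating points —
a sensitive tier (0.75) and a selective tier (0.925); a tier-2 detection is
by construction also a tier-1 detection. Detections live on the integer
(B-scan, grid-column) lattice. Clustering is DBSCAN with Chebyshev metric,
eps = 1 and min_samples = 2, which on this lattice is exactly 8-connected
components with singletons discarded as noise (property-tested against a
brute-force BFS oracle). Isolated detections are therefore never shown —
genuine DCIS/IDC manifests across adjacent B-scans at the chosen scan
density, so a single unsupported detection is treated as noise.

One invariant worth stating precisely: raising the sensitive threshold is
monotone for the number of detections and the number of *clustered
detections*, but not for the cluster count itself — removing a bridging
detection can split one cluster into two.

**Key thumbnails (MA_MAX).** Within a cluster ordered along the scan axis,
the contiguous window of 3 members with the highest mean probability is
located (ties → earliest window) and the window's maximum-probability member
becomes the key thumbnail (ties → earliest). Clusters no larger than the
window take their plain maximum. The rule operates on probabilities; the
188 × 188 bilinear resize of the winning patch is the display substrate.
Clusters are ranked for display by key-thumbnail confidence, then size,
then scan position.

## Evaluation

All confusion arithmetic is authored here: sensitivity, specificity,
PPV/NPV, per-class and macro-averaged F1, MCC
(`(TN·TP − FN·FP)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN))`, defined as 0 when a
marginal total vanishes), and likelihood ratios PLR = sens/(1−spec),
NLR = (1−sens)/spec. Undefined ratios are reported as absent (`None`/`-`),
never silently zero. The printed F1 of the reference operating table is
macro-averaged over both classes — reconstruction from the printed rates
matches every row only under that reading, so `f1_macro` is the headline
field and the positive-class F1 is exported alongside. AUROC/AUPRC use
trapezoidal and step (average-precision) integration respectively; the
AUPRC baseline of a label-independent scorer equals the positive
prevalence, which for the clinical test set's 3736/255,682 is 0.0146.

Margin-level reports aggregate detections per tier into the fields a
clinical reader sees: margins identified (≥ 1 cluster), true-positive key
thumbnails, patch-level confusion counts with percentages that recompute
exactly from their own counts, discarded singles split by ground truth, and
average detections/clusters per positive vs negative margin.

**Splitting.** Subject-disjoint holdout: margins of one subject may appear
in both train and val, but test subjects are excluded from both entirely.
Positive margins are placed in every split whenever at least three positive
subjects exist; otherwise stratification degrades gracefully toward train.

## Grad-CAM

Gradient of the target-class logit w.r.t. the post-ReLU feature maps of the
fifth convolution (26 × 11 at default geometry), globally average-pooled
into channel weights; the rectified weighted sum is upsampled bilinearly to
patch resolution and max-normalized. The overlay blends a jet colormap at
α = 0.4 over the grayscale patch. Verified against a hand-computed
single-filter oracle (scipy correlation + explicit chain rule).

## The end-to-end synthetic experiment

`pipeline.run_demo` fixes the study conditions: 12 phantom margins (6 with
2 lesions each) of 24 B-scans × 940 columns — 9 grid windows per B-scan,
2,592 grid patches in total (4.9% positive) — lesions spanning 3–5
B-scans at 120–180 px width. The split is subject-disjoint (6/2/4
margins); model fitting sees ≈ 1.9 k patches (grid + ~300 augmented) over
10 epochs. A clinical-size phantom (400 × 420 × 2400) at the same lesion
density has a 0.3% positive patch fraction — the extreme-imbalance regime
— but is too large to train against routinely on one core, so the
experiment trades margin size for wall time and reports the imbalance it
actually has. The margin sizes are scaled down from clinical scans so the whole
experiment — generation, training, inference over all margins, two-tier
post-processing, reporting — completes in a few minutes on one CPU core;
patch geometry, stride, architecture, thresholds and clustering are exactly
the clinical-scale settings.

## Known limitations

* The CNN engine is single-core numpy; it is adequate for the desk-scale
  experiments here, not for 1.9 M-patch clinical margins.
* Phantom realism is statistical (geometry, adjacency, imbalance,
  contrast); no claim is made about OCT visual fidelity, and benign
  confounders are absent, so synthetic metrics overstate clinical ones.
* The end-to-end experiment is stochastic: with only ~18 synthetic lesions
  the held-out AUROC varies noticeably across seeds. The test suite checks
  the pre-registered experiment seed; the acceptance script recomputes the
  experiment at whatever seed it is given and reports what it measures.
* DBSCAN's eps/min-samples on the device are not public; the defaults here
  (Chebyshev eps 1, min cluster size 2) are the simplest reading of
  "adjacent detections" and are exposed in `TierConfig`.
* The MA_MAX description could alternatively be read as averaging pixel
  content of resized thumbnails; the probability-averaging reading is
  implemented, matching the explicit description of window averages of
  classification probabilities.
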