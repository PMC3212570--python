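# Methods

This note documents the models, parameter choices and numerical decisions
behind `multicellseg`, and what the synthetic validation does and does not
establish.

## The segmentation model

### Patch features

The unit of classification is a square patch, 20×20 px by default. Images
are reflect-padded on the bottom/right to the next patch multiple so that
narrow marginal background regions are not truncated; windows are half-open,
0-based, row-major. Five feature sets are extracted per patch:

| set | content | length | notes |
|-----|---------|--------|-------|
| F1 | intensity histogram on [0, 1] | 16 | L1-normalized |
| F2 | gradient-magnitude histogram | 16 | central differences, bins on [0, √2/2] (max magnitude of a unit-range image); L1-normalized |
| F3 | gradient-orientation histogram, magnitude-weighted | 8 | zero-gradient patches fall back to the uniform histogram so normalization never fails |
| F4 | sample SD after Gaussian smoothing at σ ∈ {0, 1, 2, 4} px | 4 | multi-scale texture energy |
| F5 | edge-pixel fraction, mean |Laplacian| | 2 | edge level = image-global Otsu threshold of pooled gradient magnitudes |

Gradients, smoothing and the Laplacian are computed per patch with reflect
boundaries, so a constant patch has exactly zero texture response regardless
of its surroundings. Bin edges are fixed (not data-driven) so features are
comparable across images; F2–F5 are invariant to intensity shifts. The
feature configuration is a parameter (`FeatureConfig`) and alternative sets
can be swapped in.

### SVM cascade

One linear SVM per feature set (features standardized per set), then a
combiner linear SVM over the 5-vector of stage-one signed distances. The
combiner is trained on *out-of-fold* stage-one scores (2-fold stratified
cross-fitting): feeding it in-sample scores would present an optimistically
separated input and overfit the stack. Scores are signed Euclidean distances
to the hyperplane, hence invariant to rescaling of (w, b); positive means
background. Patch labels for training come from the truth mask by majority:
a patch is background iff more than 50% of its pixels are (threshold
configurable).

SVMs are unweighted by default (`class_weight=None`). Balanced class
weighting was evaluated and rejected: with background patches in the
minority it systematically displaces the decision boundary into the cellular
side (~2 px per wound edge, a ≈ +870 px² area bias on 200×200 fixtures),
which both lowers final pixel accuracy (0.973 vs 0.982) and biases healing
slopes. Unweighted hinge loss places the boundary where mixed edge patches
split evenly, keeping measured wound areas unbiased — the property the
downstream kinetics depend on. The region classifier (below) *does* use
balanced weighting, because there the veto class is intrinsically rare and
missing it is the costly error.

The automatic threshold on confidence scores is Otsu's criterion on the
score histogram, clamped to the SVM's native 0 when the scores are
single-class (all one sign with a dip-free histogram — kernel-smoothed, dips
under 2% of the peak ignored as sampling noise), where Otsu would split a
unimodal cluster in half. `svm-zero` thresholding is available as a
fallback.

### Region reclassification

Connected components (4-connectivity on the patch grid; 8 would merge
diagonal speckle into genuine wounds) of background-labeled patches are
scored by a separate linear SVM over 25 region features: log patch-area,
mean/min confidence, fraction of member patches above the image's median
background score, a pooled 16-bin gradient-magnitude histogram over the
component's pixel support, pooled multi-scale SDs (σ ∈ {0, 1, 2, 4}), and
convex solidity on the patch grid. Components classified cellular are
relabeled; filtering is monotone (it never creates background).

Natural training components are scarce — a well-segmented training image
yields roughly one genuine wound component and no misclassified ones — far
too few for a stable hyperplane; early versions trained this way were seed-
sensitive and occasionally vetoed genuine wounds. Training is therefore
augmented with planted exemplars of both classes: random blocks (1–4 × 1–4
patches) inside truly-cellular patches as hard negatives and inside
truth-background patches as positives, eight of each per training image,
seeded.

### Graph-cut refinement

Patch confidences are bilinearly upsampled to pixels and calibrated with a
logistic (scale 1.0) into p(background); unary costs are −log p and
−log(1−p) with p clipped to [1e−6, 1−1e−6]. Pixels one patch deep inside a
baseline (region-filtered) label region — square erosion of radius half a
patch — become hard seeds: sentinel cost 1e4 for the opposing label. The
pairwise term is contrast-sensitive Potts, w = λ·exp(−(Iᵢ−Iⱼ)²/(2σ²)) on the
4-neighbor graph (8-neighbor optional, diagonal weights scaled by 1/√2),
with σ² the image's mean squared neighbor difference, floored at 1e−6 for
constant images; λ defaults to 1.0. All weights are non-negative, so the
energy is submodular and max-flow/min-cut yields the exact global minimum.

The solver quantizes capacities adaptively so the largest capacity fills the
int32 range (the underlying max-flow implementation wraps larger integers);
the finest resolvable energy gap is therefore max-capacity/2³¹ ≈ 5e−6 in
units of the seed cost, far below any gap the tests exercise. The labeling
is recovered from residual-graph reachability, so ties are resolved by the
max-flow solution itself, deterministically.

## Synthetic data

The generator emulates the statistics that make bright-field segmentation
hard and texture-based classification possible: cellular regions carry
band-limited texture (smoothed Gaussian noise at 2–4 px correlation length
modulated by a coarser granule field), background carries only a smooth
illumination ramp (10% of dynamic range) plus white sensor noise
(SD 0.02); wound boundaries are displaced by a sinusoid plus low-frequency
noise (amplitude ≈ 5% of image width, zero-mean so target area fractions are
preserved), never a straight learnable line. Wound series keep the scratch
geometry fixed per well while the texture realization varies per frame;
areas shrink linearly at the configured closure rate. Scatter images place
few large compact colonies (non-scattered) or many small dispersed blobs
with finer, stronger texture (scattered) at the same total cellular area, so
classification cannot rest on confluence.

It does **not** simulate DIC shading/relief artifacts, defocus, stage drift,
debris, vignetting, individual cell shapes, mitosis or density gradients at
the wound margin. Passing the synthetic studies therefore demonstrates that
the pipeline's machinery is correct and recovers known truth under realistic
texture statistics — not that the shipped default models transfer to any
particular microscope; on real data the intended protocol is the paper-style
one of training on a handful of manually tagged images from the experiment
at hand.

## Study designs and problem sizes

Problem sizes were chosen so the full validation runs comfortably on a
single CPU while leaving each stage enough signal to fail informatively.

* **Segmentation study.** Five training fixtures, 200×200 px, spanning
  wound-area fractions 0.08–0.45 — a training set drawn across healing
  stages, like manually tagged images sampled over an assay. (Training on a
  single wide-wound fraction leaves the region classifier blind to narrow
  late-stage wounds, which it then vetoes.) Twenty fresh fixtures at
  fractions 0.12–0.40 for evaluation: mean pixel-level AUC of the confidence
  map, mean accuracy of the patch stage and of the final mask (the final
  mask should win on average).
* **Wound kinetics.** Closure rates {0.05, 0.1, 0.2} per frame, 6 frames,
  8 replicate wells each, segmented with the model above. Series are
  truncated at the first frame with zero measured background (the analysis
  window ends when opposing fronts touch). The per-rate recovery is judged
  on the median |slope| across the 8 wells — the arm-level estimate that
  `compare_treatments` consumes. A single well at the shallow 0.05 rate has
  a slope standard error near 10% of the truth (±1–2 px of boundary-
  localization noise per frame on a ~400 px perimeter), so well-level slopes
  scatter accordingly while every well's |Pearson r| stays above 0.98.
  Fold-change between arms at rates 0.2 vs 0.1 uses the median across wells
  (robust to a failed well); the mean-based fold is reported alongside.
* **Scatter study.** 22 non-scattered + 10 scattered images, 384×384 px at
  2.5 µm/px, resampled to 5 µm/px before everything else. The designated
  segmentation model is trained on four of the images (two per class) with
  10 px patches — at 5 µm/px a dissociated-cell blob spans only a few
  pixels, and 20 px patches would average it away. Scoring: leave-one-out
  confidences at decision threshold 0, 100 random equal-size splits
  constrained to more than 3 scattered images in training, the reduced
  {6, 7, 9}-bin descriptor, and a shuffled-label baseline (which must fall
  to chance; with a 22:10 class ratio "chance" sits between 0.5 and the
  majority rate, so the band around 0.5 is wide).

## Numerical and convention details

* Masks: `True`/255 = background, matching the positive sign of confidence.
* LBP: rotation-invariant uniform, P=8, R=1 — the only standard variant with
  exactly 10 codes; ties (neighbor == center) count as 1, which makes the
  constant image deterministic (one-hot at bin 8); border pixels without a
  full neighborhood are skipped; descriptors are L1-normalized. Descriptor
  standardization before the SVM is on by default (flag to disable).
* ROC: background is the positive class; every distinct confidence value is
  a threshold; AUC by trapezoid; dataset curves are averaged vertically on a
  fixed FPR grid (step 0.01). Matched-TPR comparison picks the smallest
  achievable TPR ≥ the reference.
* Rank-sum test: exact enumeration for combined n ≤ 12 without ties,
  tie-corrected normal approximation otherwise. Degenerate paired t-test
  (zero-variance differences) reports p = 1.0 with a flag; a constant area
  series reports r = 0 with a flag.
* Determinism: every stochastic step (generators, fold splits, planted
  exemplars, split resampling) is seeded; models serialize to JSON with
  full float round-trip, and identical seeds reproduce identical outputs
  byte-for-byte.

## Known limitations

* The default feature sets and region features are reasonable engineering
  choices for bright-field texture, exposed as configuration; they are not a
  reconstruction of any particular historical implementation.
* The stacking combiner cannot beat a stage-one SVM that is already perfect
  on a given test set; on easy fixtures it ties the best single feature set
  to within ~1e−3 AUC rather than strictly exceeding it.
* Wound-area measurement is unbiased but not noiseless; slope estimates at
  shallow closure rates should always be made from replicate wells.
* `wound_area_series` measures total background area; it does not separate
  multiple simultaneous wounds, and truncation-at-zero stands in for
  explicit opposing-front contact detection.
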