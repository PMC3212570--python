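# multicellseg

Segmentation and quantification of **multi-cellular regions in bright-field /
DIC microscopy images**, for labs that analyze wound-healing (scratch) and
cell-scatter assays without fluorescent labels.

Bright-field images of dense cell populations have almost no intensity
contrast between the monolayer and the cell-free background — what separates
them is *texture*. `multicellseg` turns that observation into a
classification-based segmentation pipeline plus two quantitative assays built
on top of it:

1. **Segmentation (MultiCellSeg).** The image is tiled into patches
   (default 20×20 px). Five texture feature sets are extracted per patch
   (intensity histogram, gradient-magnitude and gradient-orientation
   histograms, multi-scale variation, edge density / Laplacian energy); five
   linear SVMs score them, and a combiner SVM stacks the five scores into a
   per-patch confidence (positive = background, magnitude = signed distance
   to the separating hyperplane). An automatic (Otsu) threshold gives an
   initial labeling; a **region classifier** scores every connected
   component of background-labeled patches and vetoes those whose pooled
   texture looks cellular; finally a **graph cut** minimizes

   E(x) = Σ_p U_p(x_p) + λ Σ_{p~q} exp(−(I_p−I_q)²/2σ²) · [x_p ≠ x_q]

   over per-pixel labels x ∈ {cellular, background}, with unaries U_p from a
   logistic calibration of the upsampled confidence and hard seeds inside
   confidently labeled regions. The pairwise term is submodular, so
   max-flow/min-cut returns the *exact* global optimum.

2. **Wound-healing kinetics.** Per-frame background areas of a time-lapse,
   normalized to the first frame, are fit by least squares; the Pearson r of
   the fit quantifies linearity of healing, and treatment arms are compared
   by the fold-change of median healing slopes with a Wilcoxon rank-sum test.

3. **Scatter-assay scoring.** Images are resampled to 5 µm/px, segmented,
   and summarized by the 10-bin histogram of rotation-invariant uniform
   local binary patterns (LBP, P=8, R=1) over cellular pixels; a linear SVM
   on this descriptor separates scattered from non-scattered phenotypes,
   validated by leave-one-out and 100 constrained train/test splits.

A seeded synthetic-image generator with exact ground truth (textured cellular
regions, linearly closing wounds, clustered vs. dispersed colony layouts)
makes every stage trainable and testable without real microscopy data.

## Worked example

```python
import numpy as np
from multicellseg import MultiCellSeg, SynthParams, generate_wound_image, pixel_accuracy

params = SynthParams(image_size=(200, 200))
train = [generate_wound_image(params.replace(rng_seed=i, wound_area_fraction=f))
         for i, f in enumerate((0.08, 0.15, 0.25, 0.35, 0.45))]
model = MultiCellSeg(random_state=0).fit([p.image for p in train],
                                         [p.mask for p in train])

test = generate_wound_image(params.replace(rng_seed=99, wound_area_fraction=0.3))
result = model.segment(test.image)
print(f"patch-stage accuracy: {pixel_accuracy(result.patch_mask, test.mask):.3f}")
print(f"final accuracy:       {pixel_accuracy(result.final_mask, test.mask):.3f}")
print(f"wound area fraction:  {result.final_mask.mean():.3f} (truth {test.mask.mean():.3f})")
```

prints

```
patch-stage accuracy: 0.939
final accuracy:       0.988
wound area fraction:  0.290 (truth 0.300)
```

The patch stage alone labels 93.9% of pixels correctly; region filtering and
graph-cut refinement lift this to 98.8%, and the measured wound area is
within a percentage point of the ground truth — the quantity the
wound-healing kinetics are built on.

A command-line interface mirrors the library
(`multicellseg synth|train|segment|evaluate|wound|scatter`); every run writes
a `run_log.json` with the configuration hash and seed so outputs are
reproducible byte-for-byte.

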