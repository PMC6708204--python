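# gliopix

Automatic glioma segmentation for 2D T2-weighted MRI slices, built on
adaptive superpixels.

## The problem

Gliomas appear bright on T2-weighted MRI, but their infiltrative growth
leaves no sharp boundary, and manual delineation is slow and poorly
reproducible. A robust middle ground is to over-segment the slice into
*superpixels* — connected clusters of similar intensity — and classify
each superpixel as tumor or non-tumor. The catch is that the quality of
this approach hinges on the number of superpixels K: too few and tumor
and tissue share regions, too many and each region loses its statistical
identity.

`gliopix` implements that pipeline end to end, for researchers working
with 2D T2 slices (e.g. BraTS-style data) or anyone who wants a fully
testable, dependency-light reference implementation:

1. **ASLIC0 — adaptive superpixel count.** SLIC0 clustering with the
   distance D = √(d_c² + (d_s/S)²·C²), where d_c is the gray distance,
   d_s the spatial distance, S = √(N/K) the grid interval and C a
   per-cluster compactness adapted to the observed gray range. K itself
   is predicted per slice by a 5-tree random-forest regression from two
   asymmetry descriptors:
   - **TAR** (tumor area ratio): the slice is aligned to its own midline,
     cut into a 16×16 grid of 15 px cells, and each left cell is
     Pearson-correlated with its mirrored right twin; cells with
     r < 0.81 are suspected tumor, TAR = n/256.
   - **TC** (boundary complexity): boundary pixels / area pixels of the
     suspected region.
2. **69 features per superpixel**: 17 first-order intensity statistics;
   13 Haralick measures on each of GLCM (original image), GLGCM (Roberts
   gradient map) and GLCCM (Prewitt curvature map), averaged over 4
   directions and 4 quantizations {8, 16, 32, 64}; mean surface
   curvature; and 12 fractal measures (area, brightness, box-counting
   dimension of 4 multi-Otsu intensity channels).
3. **RBF-SVM** over standardized features classifies superpixels; the
   union of tumor-predicted superpixels is the mask. Evaluation reports
   Dice, Hausdorff distance, sensitivity and specificity.

A synthetic phantom generator (symmetric head, bright irregular blob in
one hemisphere, 12-bit intensities, background < 5) makes every stage
testable without any imaging data.

## Worked example

```python
import numpy as np
import gliopix as gp

# 20 phantoms: a seeded cohort of (slice, ground-truth) pairs
rng = np.random.default_rng(42)
pairs = [
    gp.generate_tumor_phantom(gp.PhantomSpec(
        seed=int(rng.integers(0, 2**31 - 1)),
        tumor_radius=float(rng.uniform(18, 32)),
        irregularity=float(rng.uniform(0.1, 0.5)),
    ))
    for _ in range(20)
]

cfg = gp.PipelineConfig(seed=7)
k_model, svm_model, manifest = gp.train_all(pairs, config=cfg)   # 16/4 split

img, gt = pairs[manifest["test_indices"][0]]
res = gp.segment_slice(img, k_model, svm_model, config=cfg, gt=gt)
print(res.k_predicted, res.metrics)
```

prints (trained as above):

```
340 EvalMetrics(dice=0.9978719288063456, hd=2.23606797749979,
                sensitivity=99.92251065478497, specificity=99.98364201457679)
```

i.e. the model predicted K = 340 superpixels for this slice and the
assembled mask overlaps the ground truth with Dice 0.998, its boundary
never strays more than 2.24 px from the true boundary, and 99.92% of
tumor / 99.98% of non-tumor pixels are correctly classified. High-contrast
phantoms are an easy cohort — real T2 slices have far weaker
tumor/edema contrast — but the run exercises every stage of the method.

The same flow is available from the shell:

```bash
gliopix make-fixtures --out fixtures --n 20 --seed 1
gliopix train-all --data fixtures --out models --seed 7
gliopix segment --image fixtures/slice_000.png --kmodel models/k_model.json \
                --svm models/svm_model.json --out mask.png --gt fixtures/mask_000.png
gliopix evaluate --pred preds/ --gt fixtures/ --out report.tsv
```

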