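# brainmr

Detection and delineation of brain tumors in 2-D MR slices, for researchers
who need a fully self-contained, reproducible reference pipeline:
skull-stripping by separability thresholding and morphology, seeded
geometric augmentation, a lightweight (~0.35 M parameter) convolutional
network for normal/abnormal classification, and a fast-linking modified
spiking cortical model (FL-MSCM) for tumor segmentation.  A synthetic
phantom generator with exact ground-truth masks makes every stage testable
without any image download.

## The models in brief

**Skull-stripping.**  The slice is split at Otsu's threshold into regions
R1, R2 with means m₁, m₂ and population variances s₁², s₂²; the
separability H = (m₁−m₂)²/(s₁²+s₂²) sets the binarization level
T_opt = clamp((H + min I)/2 / 255, 0, 1).  Area opening, hole filling,
disk erosion and largest-component selection then isolate the brain.

**Lightweight CNN.**  Four blocks of ConvNet cells (conv → batch norm →
softplus): 5×5/32 s2 | 3×3/48 s2, 3×3/48, 1×1/48 | ×64 | ×128, each
3-cell block closing with a point-to-point add and 2×2 average pooling,
then global average pooling, a 2-unit dense layer and softmax.  With a
224×224×3 input: 349,458 parameters (347,954 trainable + 1,504 batch-norm
statistics), counted exactly, layer by layer.  Training (cross-entropy,
batch 64, stratified 5-fold CV, seven selectable optimizers at α = 0.001)
runs on a hand-written numpy engine.

**FL-MSCM.**  Each pixel is a spiking neuron: linking L(n) = m_L·(W ∗
Y(n−1)) with a 7×7 Gaussian kernel, activity U(n) = f·U(n−1) +
S·(1 + β·L(n)), pulse Y = [U > E], and a linearly decaying threshold
E(n) = E(n−1) − Δ + h·Y(n).  β is a sigmoid of the local gradient, h
guarantees each neuron fires at most once, and the iteration budget N is
derived from Otsu's threshold of the slice.  Fast linking iterates L, U, Y
to convergence within each threshold step so similar regions fire in one
synchronous wave; the first wave of a skull-stripped T2 slice is the tumor.

**Metrics.**  TPR, TNR, PPV, F-score, accuracy, Dice coefficient and the
balanced AUC = (TPR + TNR)/2, reported in percent with mean ± SD across
folds.

## Worked example

```python
import brainmr as bm

# an abnormal synthetic T2 phantom with exact ground truth
sample = bm.make_phantom(bm.PhantomConfig(size=(128, 128), noise_sigma=3.0,
                                          seed=3))

# 1. skull-strip
strip = bm.skull_strip(sample.image)
print(f"Topt={strip.report.Topt:.4f}  brain DSC="
      f"{bm.dsc(strip.brain_mask, sample.brain_mask):.3f}")

# 2. segment the stripped slice with the FL-MSCM
seg = bm.run_fl_mscm(bm.rescale_range(strip.stripped, (0, 1)))
print(f"N={seg.params.N}  n_used={seg.n_used}  tumor DSC="
      f"{bm.dsc(seg.tumor_mask, sample.tumor_mask):.3f}")

# 3. architecture accounting of the classifier
pb = bm.count_params(bm.build_architecture())
print(f"params: total={pb.total}  trainable={pb.trainable_total}")
```

prints

```
Topt=0.0165  brain DSC=0.953
N=43  n_used=43  tumor DSC=1.000
params: total=349458  trainable=347954
```

`Topt` is the normalized separability threshold (low here because the
phantom's head region is broad); the brain-mask Dice is bounded by the
erosion radius of the refinement; the segmenter ran its full automatic
budget of 43 iterations and the first firing wave recovered the tumor
exactly.  The same stages are scriptable from the shell (`brainmr phantom`,
`brainmr skullstrip`, `brainmr segment`, `brainmr train`, `brainmr
run-all`; see `brainmr --help`).

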