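# Methods

`brainmr` implements a three-phase desk-scale pipeline for 2-D brain MR
slices: skull-stripping, two-class (normal/abnormal) classification with a
lightweight convolutional network, and tumor segmentation with a
fast-linking modified spiking cortical model (FL-MSCM).  This note records
the models, the parameters that matter, the numerical choices, and what the
synthetic phantoms do and do not establish.

## Skull-stripping

The slice (on the [0, 255] scale) is split at Otsu's threshold `t` into a
dark region R1 and a bright region R2 with means `m1, m2` and *population*
variances `s1², s2²`.  Their separability

    H = (m1 − m2)² / (s1² + s2² + ε),      ε = 1e−6

sets the binarization level `Topt = clamp((H + min(I))/2 / 255, 0, 1)`.
The head mask (`I/255 > Topt`) is refined by, in order: area opening
(8-connected components below `min_area` removed), hole filling
(8-connected), erosion by a disk of radius `se_radius`, and selection of
the largest remaining component.  Defaults `se_radius = 5`,
`min_area = 300` are calibrated to 256×256 slices and scale with image
area (`min_area` linearly, `se_radius` with its square root).  Design
choices made where the procedure is under-determined:

- the R1/R2 split uses Otsu's 256-bin threshold — deterministic and already
  required by the segmenter's iteration rule;
- `ε` guards the zero-variance case (two pure intensity levels), where the
  ratio would otherwise diverge; `Topt` is clamped because the separability
  of well-separated regions can exceed the intensity scale;
- largest-component selection makes "eliminate small objects" deterministic;
- `min(I)` is taken over all pixels, including background zeros.

The mechanism that removes the skull is topological: the bright ring is
separated from the parenchyma by a dark rim, so after binarization it is a
different connected component and largest-component selection drops it.
Erosion additionally trims rim remnants; the cost is a brain mask eroded by
`se_radius` pixels, which bounds the achievable brain-mask Dice score
(≈ 0.94 for a 40 px disc eroded by 2).

## Geometric augmentation

Each image yields `per_image` outputs (default 9: the original plus eight
warps).  Warp parameters are drawn uniformly per output: rotation in
[−30°, 30°], per-axis translation in [−10, 10] px, per-axis reflection with
probability 0.5, uniform scale in [0.5, 4], per-axis shear in [0°, 30°].
The operators compose in the fixed order reflect → rotate → shear → scale →
translate about the image center; a `single_op` switch instead applies
exactly one operator per output.  Warps are bilinear with zero fill, and
the whole expansion is reproducible from one seed.  Augmentation is applied
*inside* training folds only, and all variants of one original share the
original's fold (group-aware splitting), so augmented copies can never
leak across the train/test boundary.

## Lightweight CNN

Four blocks of "ConvNet" cells (convolution → batch norm → softplus), all
valid-padded with output size `floor((in − k)/stride) + 1`:

| block | cells | pooling |
|---|---|---|
| 1 | 5×5/32 s2 | — |
| 2 | 3×3/48 s2, 3×3/48, 1×1/48 | add, 2×2 avg s2 |
| 3 | 3×3/64, 3×3/64, 1×1/64 | add, 2×2 avg s2 |
| 4 | 3×3/128, 3×3/128, 1×1/128 | add, 2×2 avg s2 |

then global average pooling, a 2-unit dense layer, and softmax.  The add
junction sums the outputs of the 2nd and 3rd cells of a block — the only
shape-compatible pair, since the 1×1 cell preserves the 3×3 cell's
geometry; a `use_add` switch disables it.  At 224×224×3 input the exact
accounting gives 349,458 parameters: 347,954 trainable (convolutions
`k²·c_in·c_out + c_out`, batch-norm scale/shift `2c`, dense `128·2+2`) and
1,504 non-trainable (batch-norm running mean/variance, `2c` per layer).
Grayscale slices are replicated to three channels at the network boundary.
Valid padding is the only convention consistent with the layer geometry
(e.g. 224 → 110 under k=5, s=2), and the architecture admits inputs down
to 144×144 before the final pooling stage collapses.

### Training engine

The engine is a self-contained numpy implementation: im2col convolutions
with analytic backprop, average/global pooling, softplus
(`log1p(e^x)` computed overflow-safely; gradient is the logistic sigmoid),
and softmax cross-entropy with max-subtraction.  Seven first-order
optimizers are provided — SGDM (momentum 0.9), Adam, AdaMax and Nadam
(β₁ = 0.9, β₂ = 0.999), Adagrad, Adadelta (ρ = 0.95), RMSProp (ρ = 0.9) —
all at learning rate α = 0.001 with ε = 1e−6 by default.  Weights use He
initialization; arithmetic is float32.

Batch normalization uses mini-batch population statistics in training.  For
inference statistics the layer keeps debiased exponential moving averages
(momentum 0.9, divided by `1 − m^t`), and after training the harness runs
one additional pass over the training set to replace them with exact
population moments ("precise BN": batch moments combined by the law of
total variance).  This matters at desk scale: after only tens of optimizer
steps a raw moving average is still dominated by its initialization, which
shifts the inference-time decision threshold even when the learned features
separate the classes perfectly.

### Cross-validation harness

Stratified 5-fold splitting is hand-rolled (per-class shuffle, round-robin
assignment with a rotating offset so fold totals differ by at most one) and
group-aware.  The protocol defaults are batch 64, 30 epochs, cross-entropy
loss; the smoke-scale runs in the test suite use batch 16 and 2 epochs on a
185-phantom cohort — sized so a single CPU finishes a 5-fold run in a few
minutes — which is already sufficient for the separable phantom task.
Non-finite loss aborts with an error naming the optimizer.  Class imbalance
(60 vs 125) is left unweighted.

## FL-MSCM segmenter

Each pixel is a neuron with feeding input `S` (the intensity on [0, 1]),
linking `L`, activity `U`, threshold `E` and pulse `Y`:

    L(n) = mL · (W ∗ Y(n−1))        7×7 Gaussian weights (σ = 1), zero-padded
    U(n) = f·U(n−1) + S·(1 + β·L)   leaky modulation, f = 0.2
    Y(n) = [U(n) > E(n)]            strict inequality; ties do not fire
    E(n) = E(n−1) − Δ + h·Y(n)      linear decay, Δ = 0.02

with `U = Y = 0`, `E = 1` initially and `mL = 1`.  The linear threshold
decay (rather than an exponential one) makes the first-fire iteration an
affine function of intensity for an uncoupled neuron, so the first-fire map
orders regions by brightness.  Automatic parameter setting:

- `β = 1/(1 + e^−G)` per pixel, `G` the central-difference gradient
  magnitude on a replicate-padded image — edges link more strongly;
- `h = (max S − min S)/(1 − f) + max S·(1 + β·ΣW)` exceeds any attainable
  activity, so no neuron fires twice (verified as a property test);
- `N = ceil((max S − T_S)/Δ + 1)` with `T_S = T_G/(1 − f)` and `T_G` Otsu's
  threshold: the iteration budget lets exactly the Otsu-foreground
  intensity range fire; `N = 1` when `T_S ≥ max S`.

Fast linking re-runs the L/U/Y update within one threshold step until the
firing map stops changing; `U` is always recomputed from the activity
carried over from the previous outer iteration.  A neuron that fires in any
inner pass latches `Y = 1` for the iteration and receives its `+h`
reinforcement immediately, so the fired set grows monotonically and the
inner loop terminates in at most one pass per pixel (a configurable cap,
default 64, guards pathological chains and logs a warning when hit).  The
threshold decay `−Δ` is applied once per outer iteration, not per inner
pass.  Design choices: the Gaussian kernel is normalized to sum 1 and keeps
its center weight (harmless under single-fire); `β` enters `h` per pixel,
with `mean`/`max` scalar reductions available as a config switch; Otsu ties
break toward the lower threshold.

The tumor mask is extracted from the first-fire map: the default
*first-wave* rule takes the pixels sharing the earliest positive firing
iteration — on a skull-stripped T2 slice the synchronized hyperintense
region, i.e. the tumor; a *k-waves* rule unions the k earliest waves.  The
extraction rule is this package's choice; the pulse dynamics themselves do
not prescribe one.

## Phantoms

The generator paints, on a dark background: an elliptical brain disc
(intensity 110), a bright skull ring (230) separated from the brain by a
dark rim (3 % of the frame) and opened over a 30° sector (a foramen-like
gap, so the ring is not a closed curve), and, for abnormal samples, a
hyperintense elliptical tumor (200) strictly interior to the brain.
Geometry jitters uniformly by ±10 % per sample; Gaussian noise (default
σ = 3 on the 0–255 scale) is added after painting and clipped, so the
skull/brain/tumor masks stay exact by construction.  Default frames are
256×256; the test suite uses 128×128 for speed.

The phantoms reproduce what the pipeline relies on — the T2 intensity
ordering (tumor brighter than parenchyma, skull brightest), the ring/disc
topology, and a class difference carried by the tumor mode — and none of
real MR's anatomy, texture, bias fields, partial-volume effects or Rician
noise.  Tests passing on phantoms therefore establish the correctness of
the implemented mechanisms, not clinical performance.

## Numerical and degenerate-input policy

Constant images are rejected wherever a threshold or split is required
(separability threshold, Otsu, automatic iteration count); a refinement
that empties the brain mask raises rather than returning an empty result.
Metrics with zero denominators are carried as undefined (`None`), never
silently zero, and are excluded from fold means with a logged count; the
summary standard deviation is the sample (n−1) form.  Reported rates live
on the 0–100 scale; display rounding is 2 decimals, half-up.  All
randomness flows through explicit integer seeds (numpy `default_rng`), and
every harness output is reproducible bit-for-bit from (inputs, config,
seed) on a fixed platform.

## Known limitations

- The skull-stripping mechanism presumes a dark rim separating skull and
  parenchyma; slices where the ring touches the brain would need the
  erosion radius tuned up.
- First-wave extraction assumes the tumor is the brightest coherent region
  of the stripped slice; hypointense lesions would need the k-waves rule or
  an inverted intensity convention.
- The CNN harness is single-threaded numpy; it is sized for desk-scale
  cohorts, not for training on large clinical datasets.
- 3-D volumes, DICOM ingestion, bias-field correction and multi-class
  grading are out of scope.
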