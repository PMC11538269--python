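# Methods

This note documents the models, the synthetic-data design, the numerical
choices and the known limitations of `retinapair`.  It states no empirical
result beyond what the test suite and `scripts/acceptance.py` compute.

## Problem setting

Every clinical OCT acquisition yields a paired 2D fundus image **x** and 3D
OCT volume **y** of the same eye at the same visit.  Contrastive
pre-training of two encoders `h_x`, `h_y` on such pairs produces (i) a
cross-modal retrieval system and (ii) transferable representations for
downstream clinical prediction, without any annotation.  The package
implements this pipeline end to end at a scale where every stage runs and is
testable on one CPU.

## Objectives

Embeddings are l2-normalized before every contrastive loss and before
retrieval (cosine-similarity convention).

* **InfoNCE (CLIP).** With `S = U Vᵀ` on unit rows, the loss is the mean of
  row-wise and column-wise cross-entropies of `softmax(S/τ)` against the
  diagonal.  It is bounded below by 0 and sits at `log N` for uninformative
  embeddings.  τ is a learnable log-inverse-temperature initialized at
  `log(1/0.07)`, inverse clamped at 100.
* **InfoLOOB.** The leave-one-out bound excludes the positive from the
  denominator: `−log[ exp(aᵢ·bᵢ/τ) / Σ_{j≠i} exp(aᵢ·bⱼ/τ) ]`, symmetrized
  over directions.  It has no `log N` floor and can go negative.
* **CLOOB.** InfoLOOB applied to Hopfield-retrieved embeddings
  `H_M(q) = normalize(Mᵀ softmax(β M q))`, with each modality's batch
  serving once as the memory `M`, summed over the two directions.
* **Uni-modal baselines.** NT-Xent (2n-anchor softmax cross-entropy over
  concatenated augmented views), BYOL (`2 − 2cos` between online
  predictions and an exponential-moving-average target network, momentum
  0.996, target gradient-free), and VICReg (invariance MSE + variance hinge
  at std 1 with a 1e-4 variance epsilon + off-diagonal covariance penalty;
  coefficients 25/25/1).

All losses are implemented on a small in-repo reverse-mode autodiff engine
over float64 numpy arrays; finite-difference gradient checks in the test
suite pin their gradients to 1e-4 relative error.

## Encoders

Stacks of non-overlapping strided convolutions (patch embeddings) with
leaky-ReLU (slope 0.1) and a final linear map to the shared d-dimensional
space.  `tiny` (32×32 fundus; 8×96×32 OCT) trains end-to-end on CPU in
seconds per epoch; `small` accepts the full 224×224 / 20×224×224
preprocessing output.  Linear layers use Kaiming-uniform weights and zero
biases: a shared bias direction would make all freshly initialized,
l2-normalized embeddings nearly collinear, which freezes cosine-based
objectives from epoch 0.  The shipping embedding default is d = 512; the
desk-scale demo and tests use d = 32.

## Preprocessing

Grayscale (ITU-R 601 weights), bilinear resize with half-pixel centers and
edge clamping (implemented directly so a brute-force oracle can verify it),
uniform ordered B-scan subsampling `round(linspace(0, n−1, 20))`, and
whole-image/volume standardization `(x − mean)/max(sd, eps)`.
Augmentations (uni-modal pre-training): centered crop (scale 0.8–1.0,
resized back) and horizontal flip at p = 0.5, Gaussian blur (σ 0.1–2.0) and
contrast (0.6–1.4) at p = 0.3; volumes are transformed slice-coherently.

Multi-modal training uses per-step Gaussian input jitter (sd 0.3–0.4)
instead of the geometric stack: with only 200 training pairs the
contrastive loops otherwise memorize the cohort (training loss collapses
while validation loss rises), and crops corrupt the thickness-coded OCT
signal that carries the shared information.

## Synthetic cohort design

The generator's purpose is to emulate the *structure* of a paired retinal
cohort — two modalities rendering one latent anatomy, plus clinically
shaped labels — not its appearance.

Latents: `z ~ N(0, I₈)` per eye, per-visit drift `N(0, 0.1² I)`.  Fundus:
a disc background plus one Gaussian blob per component on a ring, blob
amplitude affine in its component (the CST-driving component gets the
largest slope — the most visible pathology analog).  OCT: one horizontal
band per component whose **thickness** is affine in that component; the
central band's thickness is the CST label, and visual function (BCVA) is a
noisy linear functional of z dominated by that component.

Band brightness deliberately carries no information: bands are
mass-conserving (amplitude ∝ 1/thickness), and each scan draws per-band
lognormal gains (σ = 0.6), vertical position jitter (thin bands ±1 row,
central band ±3.5), a lateral gain tilt (±0.5) and per-slice brightness
wobble (sd 0.08), plus a smooth illumination field and i.i.d. noise that
are independent between the modalities.  This nuisance battery is what
makes the task scientifically meaningful at desk scale: a linear readout of
raw voxels (or of a randomly initialized encoder's features) gains little,
while the latent remains fully recoverable from rendered *structure* — blob
amplitudes on the fundus side, band thicknesses (measured as band mass over
peak amplitude, exact for the anti-aliased bands) on the OCT side, each
giving per-component OLS R² above 0.9 on noiseless renders.  A
voxel-correlation analysis during design located the residual linear
leakage at band edges; its total information scales inversely with the
position jitter, which fixed the jitter magnitudes.

Labels: fluid ~ Bernoulli(σ(1.8 z₃)), rendered as a dark ellipsoid in the
central slices; disease class by argmax of five fixed linear logits;
injection count ~ Poisson(exp(1.8 + 0.6 z₁)) clipped to [0, 30], with
treatment need *high* at ≥16 and *low* at ≤5 injections; conversion ~
Bernoulli(σ(0.9 z₄ − 0.4)).  All coefficients are module constants.
Vendors contribute additive intensity offsets (round-robin assignment);
native sizes vary (21–40 B-scans by default, within the clinically observed
21–256 range).

What passing tests do **not** show: robustness to real anatomical
variability, vendor domain shift beyond additive offsets, registration
error, or pathology appearance — none of which the generator attempts.

## Desk-scale study conditions

The canonical demo (and the end-to-end acceptance check) uses 400 patients
split 50/10/40 at patient level — exactly 200 training pairs, with a
160-pair evaluation pool chosen to keep hold-out estimates stable (test-R²
noise is ±0.06 at n = 160 versus ±0.13 at n = 57).  Both multi-modal
objectives train 30 epochs on one pair per patient per epoch:

* CLIP: batch 16, lr 3e-3, input jitter 0.4, learnable τ.  The tiny
  patch-embedding encoders need a larger step than ResNet-scale backbones;
  3e-3 sits above the conventional [1e-6, 1e-3] search interval, which
  remains the default elsewhere.
* CLOOB: batch 32, lr 1e-3, input jitter 0.3, Hopfield β = 2, and a
  5-epoch InfoNCE warm-up blended linearly into the InfoLOOB objective over
  5 more epochs.  Two desk-scale facts force these choices: β must match
  the cosine-similarity spread at d = 32 (β = 8 is calibrated to d = 512,
  where similarities concentrate ~4× tighter), and small-batch InfoLOOB has
  an attractive collapse fixed point — at exact collapse the gradient
  vanishes identically — that a hard objective switch can fall into.

Margins at these conditions are modest and somewhat seed-sensitive; the
suite pins the documented master seed, and retrieval margins are the most
robust of the bundle.

## Downstream protocol

Single affine head; task losses MSE / BCE / CE; AdamW with weight decay
0.1; head learning rate selected from {1e-5, 1e-4, 1e-3} on validation
loss; minibatches of 16; reduce-on-plateau (factor 0.5, patience 2); early
stopping after 5 non-improving validation epochs within a 100-epoch cap;
best-validation weights restored.  The head standardizes its input features
(and regression targets) with training-split statistics — a fixed affine
input layer, without which the learning-rate-bounded optimizer cannot reach
targets with large offsets (the BCVA analog is centered near 70).  Probing
uses unnormalized encoder outputs (a flag enables l2-normalized probing).
Metrics: R² (negative allowed — worse than predicting the mean) and RMSE;
support-weighted one-vs-rest AUROC and average precision for
classification.  Bootstrap variance uses 1000 scan-level resamples by
default; retrieval confidence intervals are exact Clopper–Pearson.
Modality interchange feeds fundus embeddings into the OCT-trained
linear-probe head and reports relative decay `(source − swapped)/source`.

## Numerical choices

* Similarity ties in retrieval rank break by lowest candidate index
  (measure-zero for float cosines).
* `logsumexp` guards all-(−inf) rows; InfoLOOB masks its diagonal with −inf.
* The Hopfield retrieval re-normalizes output rows (unit norm to 1e-6).
* Split allocation uses per-stratum shuffling with largest-remainder
  rounding, so realized proportions sit within one patient of targets;
  strata smaller than 3 patients go to train with a warning.
* Epoch sampling seeds derive deterministically from the master seed
  (wall-clock seeding is deliberately not reproduced).
* BYOL's closed-form cases hold to ~1e-12 (l2-normalization epsilon).

## Limitations

The renderer is a stand-in, not a retina; absolute metric values have no
clinical meaning.  Full-scale ResNet-family backbones are out of scope —
the encoder registry is the tiny/small numpy family, and the training loops
are single-process CPU (no distributed or reduced-precision execution).
Temporal modeling, vendor domain-shift correction and cross-validation are
out of scope by design.
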