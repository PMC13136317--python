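# Methods

## The model

`adsaf` implements an adaptive dual-stream classifier for lung images. Two
feature extractors run in parallel on a preprocessed image `I ∈ [0,1]^{H×W}`:

* a **convolutional stream** `F_CNN = f_CNN(I; θ_CNN)` — a stack of
  stride-`s` conv + ReLU blocks capturing fine local texture;
* a **vision-transformer stream** — the image is split into non-overlapping
  `p×p` patches, linearly embedded, given a learned positional table
  (`X = Embed(I) + P`), and passed through pre-norm transformer blocks whose
  self-attention is `Attention(Q,K,V) = softmax(QKᵀ/√d_k)V`. The token grid
  is projected to the common channel width and bilinearly resampled onto the
  CNN grid (`F_ViT`).

A two-layer **fusion gate** computes one weight per image from the pooled,
concatenated streams,

    α = σ(W₂ φ(W₁ [GAP(F_CNN) ⊕ GAP(F_ViT)] + b₁) + b₂) ∈ [0,1],

and the fused map is the convex combination

    F_fusion = α·F_CNN + (1−α)·F_ViT.

The gate is regularized by the batch-mean binary entropy of α,

    L_fusion = −E[α ln α + (1−α) ln(1−α)],

so minimizing the joint objective `L_total = L_CE + λ·L_fusion` pushes each
image's gate toward a confident choice of stream. A **self-attention
refinement module** (SARM) then modulates the fused map with channel
attention `A_c` (squeeze-excitation: GAP → C/r bottleneck → sigmoid) and
spatial attention `A_s` (channel mean/max maps → k×k conv → sigmoid):

    F_ref = A_c ⊗ A_s ⊗ F_fusion,

and a linear head on the pooled refined map produces class probabilities.
Five variants are provided for ablation: `cnn_only`, `vit_only`,
`static_concat` (channel concatenation + 1×1 projection, no gate),
`adaptive_no_sarm`, and `full_adsaf`.

### Assumptions and conventions

* α is a **per-image scalar** (the sigmoid of a scalar logit), not a
  per-channel vector; the gate consumes globally pooled features, which
  resolves the dimensional ambiguity of concatenating two maps and keeps the
  gate cheap.
* The entropy expectation is the **batch mean** (the standard SGD surrogate
  of the dataset expectation).
* The head pools `F_ref` spatially before the linear map, a dimensional
  necessity for arbitrary grid sizes.
* `cnn_only`/`vit_only` route the single stream straight to the head, with
  λ forced to 0 (no gate exists); `static_concat` projects 2C→C before the
  head so parameter counts stay comparable.

## Compute engine

The network is expressed as pure functions of a nested dict of numpy arrays
and differentiated end to end with `autograd` (reverse mode). Convolution is
im2col + matmul; attention, layer norm, bilinear resampling and both
attention branches of SARM are likewise composed from differentiable
primitives. Optimization is a hand-rolled Adam over the flattened parameter
pytree. Everything is float64 and seeded, which makes training runs
bit-reproducible on a single CPU — a property the determinism tests assert
at byte level on history CSVs and dataset manifests.

## Design choices where the design was open

* **Stream alignment and scale.** "Alignment" is reshape → 1×1 projection →
  bilinear resize, followed by per-sample RMS normalization of *both* maps.
  The normalization matters: without it the randomly initialized ViT map is
  several times larger in magnitude than the CNN map, and the head's
  cheapest descent direction is to silence the noisier stream via the gate —
  α collapses to 1 regardless of the data. On a common scale the gate
  arbitrates content, not amplitude.
* **Circular convolution padding.** The CNN stream pads convolutions
  circularly, making it exactly (cyclically) translation-covariant. With
  zero same-padding, border effects inject absolute position into small
  feature maps, which lets a pooled CNN head solve globally-arranged layout
  tasks it has no business solving and blurs the local/global division of
  labor between the streams.
* **Gate initialization.** The gate's output layer starts at exactly zero,
  so α begins at 0.5 — the stationary point of the binary entropy. The
  classification loss must commit the gate in some direction before entropy
  pressure can amplify it; this prevents premature convergence to a trivial
  dominance while neither stream has learned anything.
* **SARM initialization.** Both attention branches start with bias +2
  (sigmoid ≈ 0.88), so refinement opens near the identity and learns to
  *suppress*. With zero-init biases the double sigmoid attenuates the fused
  map fourfold and measurably delays early learning.
* **λ (entropy weight).** Default 0.1, with {0, 0.01, 0.1, 0.5} exposed in
  config. λ is held constant within a run but chosen per task: on
  single-regime tasks 0.1 sharpens the gate reliably; on the mixed-regime
  task (both signal types present) the ablation uses 0.01, because stronger
  pressure saturates the gate toward whichever stream learns first and
  starves the other — the underfitting risk that makes λ a quantity to
  control empirically rather than fix universally.
* **Entropy numerics.** α is folded to `0.5 + |α − 0.5|` and clamped at
  `1 − 1e−7` before the logs; the fold makes the symmetry H(α) = H(1−α)
  exact in floating point and endpoints contribute ≈0 (convention
  0·ln 0 = 0).
* **Mixed training monitors.** The LR scheduler watches validation *loss*
  (total, including λ·L_fusion); early stopping watches validation
  *accuracy*. "No improvement" means no change beyond 1e−4. Dominance and
  entropy statistics are reported from the *final* epoch's parameters — the
  converged gate state — while the returned checkpoint holds the
  best-validation-accuracy snapshot.

## The synthetic benchmark

The generator emulates the clinical dichotomy the gate is meant to resolve:
focal, texture-defined disease versus diffuse, layout-defined disease.

* **local** regime: class 1 receives a small (default 9 px) zero-mean,
  band-limited speckle lesion — high-pass-filtered noise under a
  raised-cosine taper — placed inside an elliptical lung field. Zero mean
  means no brightness cue: detection requires local texture-energy
  sensitivity (a rectifying conv stream has it; a linear patch embedding
  largely does not).
* **global** regime: classes differ only in a smoothed diagonal
  quadrant-parity field (±0.15 peak, class 0 bright in TL/BR). The field is
  cyclically smooth and has zero row, column and border sums, and the two
  classes are cyclic translations of each other — so the pooled features of
  an exactly translation-covariant CNN carry *no* class information, while
  positionally-encoded tokens separate the classes trivially. (A simpler
  top-vs-bottom gradient would not work: any net hemifield difference is
  linearly recoverable from a derivative filter plus pooling, and a CNN
  solves it immediately.)
* **mixed** regime: each image carries one of the two signal types at a
  configurable fraction; the correct gate behaviour is *image-specific*
  dominance, visible as mean α near 0.5 with low mean entropy (a bimodal
  gate).
* Per-subject constant intensity offsets (σ = 0.02) give subject-wise
  splitting real structure; background is base level 0.45 plus a smooth
  random field (σ = 0.02) and pixel noise (σ = 0.03). All images are clipped
  to [0,1], and the whole dataset is a pure function of the spec (seed
  included).

What the generator does **not** emulate: anatomy (ribs, mediastinum,
projection geometry), scanner characteristics, label noise, class imbalance,
or lesion variety. Passing the synthetic suite therefore demonstrates that
the fusion mechanism behaves as designed — not that the architecture reaches
any particular accuracy on real radiographs.

Separability is asserted before any model enters the picture: a midpoint
threshold on the designed statistic (global high-pass energy for the local
regime; diagonal quadrant contrast for the global regime) classifies 500
generated images at >90%, so downstream training failures are attributable
to the model, not the data.

## Study conditions for the behavioural experiments

All behavioural experiments run at desk scale on one CPU: 32 px images; CNN
blocks (16,2),(32,2),(32,2) → C = 32 on a 4×4 grid; ViT patch 8, embed 32,
2 heads, 2 layers; gate hidden width 16; SARM r = 8, k = 3. Training follows
the standard protocol (batch 32, Adam 1e−3, LR ×0.1 after a 5-epoch
validation-loss plateau, early stop after 7 non-improving accuracy epochs)
with augmentation disabled — the diagonal layout signal is not invariant
under flips or rotations, so geometric augmentation would corrupt labels.

* *Dominance recovery*: 240 images (24 subjects × 10) per regime, 3 seeds,
  ≤30 epochs; final mean validation α ≥ 0.6 (local) / ≤ 0.4 (global) in at
  least 2 of 3 seeds.
* *Entropy pressure*: identically seeded λ = 0.5 vs λ = 0 twins on the
  600-image mixed task; the regularized twin must end ≥ 0.1 nat lower in
  mean gate entropy.
* *Learning sanity*: full model reaches ≥ 90% validation accuracy on 600
  mixed images within 30 epochs.
* *Ablation & robustness*: static_concat / adaptive_no_sarm / full_adsaf on
  shared seeded splits of the mixed task (3 seeds, λ = 0.01 for the gated
  variants); validation accuracy must be non-decreasing along that order
  within 0.03, and under σ = 0.05 Gaussian test noise the full model's
  paired accuracy drop must not exceed the static baseline's.
* *Localization*: on a trained local-regime model, the SARM spatial map's
  mass inside the lesion footprint exceeds the lesion's area fraction, and
  the fused Grad-CAM's mass exceeds it by ≥ 1.5×.

## Evaluation conventions

Binary metrics take class 1 as positive: sensitivity TP/(TP+FN),
specificity TN/(TN+FP), F-score = F1. An all-positive predictor on balanced
data scores specificity 0. Multi-class reports are macro averages with
one-vs-rest specificity. ROC curves sweep unique score thresholds with
trapezoidal AUC (equal to the Mann–Whitney pairwise concordance, asserted to
1e−9 in tests). Test-time corruption adds Gaussian noise (mean 0, σ = 0.05)
*after* normalization and clips back to [0,1]; domain shift is simulated as
a gamma contrast warp plus altered noise statistics, applied to the same
test set. Noise is test-time only; training is always on clean images.

## Grad-CAM

For branch feature grid `F` (cnn: last conv map; vit: aligned token grid;
fused: the refined map) and class `c`, channel weights are the spatial means
of `∂logit_c/∂F_k`; the map `ReLU(Σ_k w_k F_k)` is bilinearly upsampled to
the input and min-max normalized (an exactly constant map returns zeros).
Branch gradients are taken with the other stream's features held fixed, so
the cnn/vit heatmaps isolate each branch's pathway through gate, fusion and
refinement.

## Known limitations

* The spatial-attention grid is coarse (4×4 at desk scale), so its lesion
  concentration margin is modest; Grad-CAM localization is much sharper.
* Early stopping on a 0.5-accuracy plateau can abort a run just before the
  ViT stream "clicks" on layout tasks; the dominance experiment absorbs
  this through its 2-of-3 majority design.
* Circular padding is the right inductive bias for the translation
  experiments here but is unconventional for real radiographs, where
  absolute position is diagnostic; for real data a user may prefer zero
  padding (one config switch away, `pad_mode` in the conv op).
* λ requires per-task control on strongly heterogeneous data; no schedule
  is implemented.
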