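# adsaf — adaptive dual-stream attention fusion for lung-image classification

Chest radiograph pathologies split roughly into two visual families: focal,
texture-defined findings (nodules, early infiltrates) and diffuse,
layout-defined ones (ground-glass opacity patterns, widespread involvement).
Convolutional networks excel at the first, vision transformers at the
second, and fixed hybrid schemes (concatenation, constant-weight averaging)
force one trade-off onto every image. `adsaf` implements an architecture
that learns an **image-specific** arbitration between the two: a CNN stream
and a ViT stream are aligned onto a common feature grid and combined by a
learned convex gate

    F_fusion = α·F_CNN + (1−α)·F_ViT,
    α = σ(W₂ φ(W₁ [GAP(F_CNN) ⊕ GAP(F_ViT)] + b₁) + b₂) ∈ [0,1],

whose batch-mean binary entropy `L_fusion = −E[α ln α + (1−α) ln(1−α)]` is
penalized in the joint objective `L_total = L_CE + λ·L_fusion` — so the
gate is pushed toward a *confident*, per-image choice of stream. A
channel/spatial attention module (SARM) refines the fused map
(`F_ref = A_c ⊗ A_s ⊗ F_fusion`) before a linear softmax head.

The package is a library + CLI containing:

* the five-variant model family (`cnn_only`, `vit_only`, `static_concat`,
  `adaptive_no_sarm`, `full_adsaf`) on a pure numpy/autograd compute engine
  (no GPU framework needed; training is deterministic on one CPU);
* a seeded synthetic lung-image generator whose class signal is
  controllably **local** (a zero-mean speckle lesion in an elliptical lung
  field), **global** (a diffuse quadrant-parity layout), or **mixed** — the
  test-bed that makes the gate's dominance behaviour falsifiable;
* the training protocol (subject-wise 70/20/10 splits, Adam, plateau LR
  decay, accuracy-based early stopping, flip/rotate/zoom/shift
  augmentation), evaluation metrics (accuracy, F1, sensitivity,
  specificity, ROC/AUC), Gaussian-noise and domain-shift robustness
  harnesses, and Grad-CAM explainability for the CNN, ViT and fused
  branches.

Real chest X-ray folders (PNG/JPEG + CSV manifest) are supported as inputs;
nothing in the build or tests requires them.

## Worked example: dominance recovery

Train the full model on a purely *local*-signal task and on a purely
*global*-signal task, and watch where the gate converges:

```python
from adsaf.experiments import train_on_regime, mean_alpha_on_split

for regime in ("local", "global"):
    ckpt, history, ds = train_on_regime(regime, "full_adsaf", seed=0,
                                        max_epochs=30)
    alpha = mean_alpha_on_split(ckpt, ds, "val")
    print(f"{regime:6s}  best val acc {ckpt['val_accuracy']:.3f}  "
          f"final mean alpha {alpha:.3f}")
```

```
local   best val acc 1.000  final mean alpha 0.775
global  best val acc 0.500  final mean alpha 0.500
```

On the local task the gate ends CNN-dominant (α → 0.78 here; other seeds
reach 0.97+). The global task is the hard direction — position-blind CNN
features are useless for it, and on this seed the run early-stops before
the ViT stream clicks (accuracy 0.5, gate still undecided); seeds 1 and 2
finish at α = 0.38 and 0.09 with perfect accuracy, i.e. ViT-dominant. That
variability is exactly why the dominance experiment uses a 2-of-3 majority
across seeds. On *mixed* data the trained gate becomes bimodal: mean α
near 0.5 with mean entropy far below ln 2 — per-image dominance rather
than indecision.

## CLI

```bash
adsaf generate config.yaml   # synthetic dataset -> PNG dir + manifest.csv
adsaf train config.yaml      # -> checkpoint.{npz,json} + history.csv
adsaf eval  config.yaml --checkpoint out/checkpoint   # clean/noisy/shifted metrics
adsaf ablate config.yaml     # all five variants on identical splits -> ablation.csv
adsaf explain out/checkpoint img.png --branch fused --out cam.png
```

Every command is reproducible from the YAML config alone (seed included)
and writes a config-hash manifest next to its outputs. Exit codes: 0
success, 2 config error, 3 runtime error.

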