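# CellSage

A lightweight attention-augmented convolutional classifier for benign vs.
malignant histopathology image patches, implemented entirely on NumPy/SciPy
(no deep-learning framework required), together with its full experimental
machinery:

- **Model** — a multi-scale convolutional feature extractor (parallel
  7×7 / 5×5 / 3×3 branches, concatenated), a depthwise-separable
  convolution stack, a CBAM refinement stage (channel attention with a
  shared bottleneck MLP, then 7×7 spatial attention), and a single-logit
  sigmoid head. Forward *and* backward passes are hand-written, so
  training, ablations, and Grad-CAM all work on one CPU.
- **Profiling** — analytic per-layer parameter and multiply-accumulate
  accounting, exact against the instantiated network's enumerated weights.
  The frozen reference configuration (`src/cellsage/reference_config.yaml`,
  stage widths 128/224/544/1472) is calibrated to the published efficiency
  budgets: **3.8 M parameters, 0.49 G MACs** at 224×224. The same counters
  reproduce standard MobileNetV2 (3.4 M params) and EfficientNet-B0
  (0.39 G FLOPs) from analytic architecture descriptions.
- **Preprocessing** — Reinhard-style reference-stain color mapping in
  CIELAB, rescaling/standardization with the fixed ImageNet channel
  statistics, and the seeded training-time augmentation policy (±30°
  rotation, flips, 0.8–1.2 zoom, ≤20 px shifts, color jitter).
- **Data pipeline** — CSV manifest indexing with per-patient label
  consistency checks, leakage-free patient-wise 60/20/20 splitting
  (82 patients → 50/16/16), 5-fold patient-stratified cross-validation,
  and inverse-frequency class rebalancing weights.
- **Synthetic data** — a two-class histology-like patch generator
  (Poisson nuclei for benign, clustered Thomas-process nuclei for
  malignant, per-patient density/size/stain effects) so every module is
  testable without downloading anything.
- **Training / evaluation** — Adam with cosine annealing and warm
  restarts, weighted BCE-with-logits, early stopping with best-epoch
  restoration, accuracy/F1/AUC with fold aggregation, and Grad-CAM
  heat-map overlays (blue = low, red = high attention).

## Command line

```bash
cellsage profile --input-size 224              # per-layer params/MACs table
cellsage synthesize --out data/ --seed 0       # synthetic PNGs + manifest.csv
cellsage split --manifest data/manifest.csv --scheme holdout --seed 0 --out plan/
cellsage train --manifest data/manifest.csv --split plan/ --out run/ \
    --input-size 64 --max-epochs 20
cellsage evaluate --run run/ --manifest data/manifest.csv --split plan/ \
    --report report.json
cellsage gradcam --run run/ --image data/images/M001_000.png --out overlay.png
cellsage normalize --in data/images --out normalized/
```

## Notes on conventions

- One MAC is reported as one FLOP; only convolutions and linear layers are
  counted (batch norm, pooling, activations and the element-wise attention
  products are excluded).
- Headline parameter figures follow the lightweight-CNN literature
  convention: convolution + linear weights (normalization affine excluded),
  truncated at one decimal in millions — the convention under which
  standard MobileNetV2 (3,470,760 such weights) is printed as 3.4 M.
- Stain normalization, augmentation, synthesis, and training are all
  deterministic functions of their seeds.
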