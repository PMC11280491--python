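# dentseg

Binary segmentation of 2-D panoramic dental radiographs with a
dual-pathway encoder–decoder network, implemented entirely in numpy on a
small built-in reverse-mode autodiff engine (no deep-learning framework
required), together with:

* a synthetic **phantom generator** that emulates the hard properties of
  panoramic X-rays (elongated overlapping tooth shapes, low-contrast
  root/bone boundaries, additive noise) so every component is testable
  on CPU with no external data;
* the **composite loss** (soft Dice + binary cross-entropy);
* a **six-metric evaluation suite** (Dice, HD95, IoU, accuracy, Cohen's
  kappa, MCC), each backed by an independent brute-force oracle in the
  tests.

## Architecture

* `dentseg.nn` — minimal autodiff engine (`Tensor`), layer library
  (conv / transposed conv / layer & batch norm / MLP / DropPath), Adam
  and a reduce-on-plateau scheduler.  Heavy ops (im2col, bilinear
  gathers with coordinate gradients, the selective scan) have
  hand-derived backward passes verified against finite differences.
* `dentseg.deformable_pathway` — stem + four stages of residual blocks
  whose core operator is a grouped deformable convolution: per-pixel
  learned offsets and softmax-normalised modulation over K sampled
  points; emits a stride-4/8/16/32 feature pyramid.
* `dentseg.ssm_pathway` — 7×7/stride-2/48-channel stem and four units of
  {stride-2 subsampling → gated spatial convolution → tri-directional
  selective scan → MLP}, channel-matched to the deformable pyramid.
* `dentseg.semantic_enhance` — fuses the two deepest encoder outputs
  (7×7 Conv-BN-ReLU) and enriches them with a per-pixel MLP branch and a
  learnable-codebook branch (soft assignment → residual sigmoid gate).
* `dentseg.hierarchical_decoder` — four decoder levels; each upsamples
  ×2 and blends the two encoder skips through a sigmoid attention gate
  (a pixelwise convex combination) before refinement; a 1×1 head emits
  full-resolution logits.  Three gated fusion sites by default.
* `dentseg.phantom_io` — phantom generation, PNG/manifest I/O, the
  augmentation suite (brightness, gamma, noise, scale, mirror, affine),
  deterministic 9:1 splitting.
* `dentseg.losses_metrics`, `dentseg.runtime` — losses/metrics and the
  glue: model assembly (with structural ablation flags), training loop,
  checkpointing, padding/prediction.

## CLI

```bash
dentseg synth --n 16 --height 64 --width 128 --seed 0 --out-dir data/
dentseg train --config cfg.yaml --data-dir data/ --out-dir run/
dentseg eval  --pred-dir preds/ --true-dir masks/ --out report.csv
dentseg predict --checkpoint run/best.npz --image img.png --out mask.png
```

Training defaults follow the reference settings (Adam, lr 1e-5, 50
epochs, batch 2, reduce-on-plateau); the YAML config can override any
model/training block, and `model: {small: true}` selects a CPU-scale
footprint.

## Notes

* Masks on disk are 8-bit PNG with values {0, 255}; binarisation
  threshold is 127.  Coordinates are (row, col), 0-based, top-left.
* Images of arbitrary size are reflect-padded to multiples of 32 inside
  `predict` and cropped back exactly.
* HD95 uses 8-connected boundary pixels and the pooled 95th-percentile
  convention; it is undefined (and excluded from aggregation) when a
  mask is empty.
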