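# sthma

A hybrid state-space / attention classifier for multichannel EEG emotion
decoding, implemented as a tested library plus CLI. The pipeline:

1. **Preprocessing** — polyphase resampling (default 200 Hz), optional
   zero-phase 0.3–75 Hz Butterworth band-pass, segmentation into
   non-overlapping patches, and subject-/trial-ordered train/val/test splits.
2. **Dual-domain embedding** — a depthwise-separable temporal convolution
   stream (GroupNorm + GELU + pooling) fused additively with a log-magnitude
   rFFT spectral stream and a learnable positional table over the
   channel × patch grid.
3. **Backbone** — a stack of gated selective-scan (Mamba2-style SSD) blocks.
   Each layer re-serializes the latent channel×time grid either
   *spatial-first* (channels in the inner loop) or *temporal-first* (patches
   in the inner loop), alternating by default, and scans bidirectionally
   (forward plus flipped scan with shared weights).
4. **Head** — global multi-head self-attention recalibration over all
   channel-time tokens (pre-norm + residual), then a three-layer ELU/dropout
   MLP trained with label-smoothing cross-entropy under AdamW.

Because no deep-learning framework is assumed, the network runs on a small
numpy reverse-mode autodiff engine (`sthma/_autograd.py`); the selective
scan has a hand-derived backward pass verified against finite differences,
and a chunked evaluation path verified against the sequential reference.

A synthetic-data module generates labeled EEG-like datasets (1/f^α
background plus class-conditional band-limited oscillations with randomized
phase) so the whole pipeline is testable without any external recordings.
Minimal EDF read/write is included for interoperability.

## CLI

```bash
sthma simulate --channels 32 --classes 9 --sfreq 250 --duration 10 \
    --effect 3.0 --trials-per-class 20 --seed 7 --out fixtures/train.npz
sthma preprocess --in raw.npz --target-sfreq 200 --band 0.3 75 \
    --patch 200 --out patched.npz
sthma train --data fixtures/train.npz --val-data fixtures/val.npz \
    --preset faced --epochs 30 --out runs/exp1
sthma evaluate --ckpt runs/exp1/best.npz --data fixtures/test.npz
sthma ablate --variant no_spectral_stream --data fixtures/train.npz \
    --val-data fixtures/val.npz --preset faced
sthma presets
```

Two presets ship with the package: `faced` (32 channels, 9 classes, no
band-pass) and `seedv` (62 channels, 5 classes, 0.3–75 Hz band-pass); both
carry the reference training recipe (AdamW, lr 1e-4, weight decay 1e-4,
batch 32, 200 epochs) in their `train:` section.

Ablation variants: `full`, `no_temporal_stream`, `no_spectral_stream`,
`no_dual_domain` (linear patch projection), `no_backbone`
(embedding → attention → head) and `pure_mamba2`
(embedding → backbone → head).

## Layout

```
src/sthma/
  _autograd.py      numpy reverse-mode autodiff engine
  nn.py             layers (Linear, LayerNorm/GroupNorm, MHSA, AdamW, ...)
  synthetic_data.py synthetic EEG generator + fixture archive I/O
  preprocessing.py  resample / band-pass / patching / splits
  edf.py            minimal EDF reader/writer
  embedding.py      dual-domain patch embedding
  backbone.py       SSD scan (reference + chunked), un/fold, Mamba blocks
  head.py           attention recalibration, MLP head, smoothed CE
  model.py          full model, presets, checkpoints
  training_eval.py  training loop, metrics, ablations, result export
  cli.py            typer CLI (`sthma`)
```
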