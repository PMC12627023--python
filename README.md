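# cadffnet

Dual-view convolutional regression of leaf moisture content, plus a
synthetic dual-view leaf benchmark.

The model processes paired front/back RGB leaf images with two independent
residual-network branches (depths 18/34/50/101). Shared channel-attention
blocks (global pooling → adaptive-kernel 1-D convolution → sigmoid) reweight
both branches after the intermediate stages, the final stage-5 features are
fused by a multi-scale module (parallel 3×3/5×5 convolutions with
softmax-weighted per-channel competition and a residual connection), and a
pooled affine head regresses moisture content in percent.

Because no public dataset of paired leaf images exists, the package ships a
deterministic synthetic renderer whose image statistics (lamina green shift,
inward curl, abaxial vein contrast) are monotone in a latent moisture label.
Its `split` mode gives each view an independent latent whose average is the
label, so any single-view predictor is information-capped at half the label
variance — the benchmark for the dual-view advantage.

Everything runs on a NumPy-only compute stack: the layer library in
`cadffnet.nn` implements forward and backward passes (im2col convolutions,
batch norm, pooling, Adam) without any deep-learning framework, and every
fusion module is verified against independent loop/`scipy` oracles in the
test suite.

## CLI

```sh
# render a synthetic dataset (PNG pairs + manifest CSV)
cadffnet synth --n 200 --out data/ --seed 1 --mode joint --side 64 --noise-sd 0.02

# seeded cross-validation folds
cadffnet folds --manifest data/manifest.csv --k 5 --seed 1 --out folds.json

# train / evaluate / cross-validate / ablation grids
cadffnet train --manifest data/manifest.csv --config config.yaml --out run/
cadffnet eval --ckpt run/checkpoint.npz --manifest data/manifest.csv --side 64
cadffnet cv --manifest data/manifest.csv --config config.yaml --k 5
cadffnet ablate --manifest data/manifest.csv --grid table2 --config config.yaml
```

A config file mirrors the dataclass fields:

```yaml
side_px: 64
model:
  depth: 18
  base_width: 16
  branch_mode: dual
  deca_stages: [2, 3, 4]
  mscff_enabled: true
train:
  learning_rate: 1.0e-4
  batch_size: 16
  epochs: 30
```

## Layout

- `cadffnet.nn` — NumPy layers/optimizer with hand-written backprop
- `cadffnet.io_manifest` — manifest CSV I/O, moisture labels, CV folds
- `cadffnet.synth_leaves` — deterministic synthetic dual-view renderer
- `cadffnet.backbone` — residual branches with per-stage interrupt/resume
- `cadffnet.deca` — dual efficient channel attention (functional + trainable)
- `cadffnet.mscff` — multi-scale fusion (functional + trainable)
- `cadffnet.model` — full network assembly, loss, parameter accounting
- `cadffnet.evalkit` — metrics, training loop, cross-validation, ablation grids
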