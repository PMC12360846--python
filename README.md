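# mapgan

A volumetric GAN toolkit for density maps: simulate a 3D density map from an
atomic model with a Gaussian point-spread kernel, curate experimental-like
training targets, train a nested-U-Net (U-Net++) generator against a 3D
convolutional discriminator to translate simulated maps into
experimental-like maps tile by tile, and score map pairs with four
similarity metrics (SSIM, correlation, correlation about mean, PCC).

The deep-learning stack is self-contained: a small numpy reverse-mode
autograd engine (`mapgan.nn`) provides 3D convolution, max-pooling,
trilinear upsampling, instance normalization, PReLU, and an NAdam
optimizer, so nothing beyond scientific Python is required.

## Layout

| Module | Role |
| --- | --- |
| `mapgan.volume_io` | MRC2014 read/write, PDB/mmCIF models, resampling, min-max normalization |
| `mapgan.simulator` | Gaussian point-spread simulation from atomic models |
| `mapgan.curation` | Boxing/resampling raw maps into training targets; stochastic augmentation |
| `mapgan.tiling` | 32³ tiling with exact center-20³ reassembly |
| `mapgan.gan_core` | U-Net++ generator, discriminator, losses, training, inference |
| `mapgan.metrics` | SSIM / correlation / correlation-about-mean / PCC with grid alignment |
| `mapgan.synthetic_fixtures` | Seeded paired (sim, pseudo-experimental) fixtures for offline testing |
| `mapgan.cli` | Umbrella `mapgan` command |

## CLI

```bash
mapgan simulate --model in.pdb --out sim.mrc --resolution 2.0 --voxel 1.0
mapgan curate   --raw raw.mrc --model in.pdb --out expmap.mrc --margin 5
mapgan augment  --in sim.mrc --out aug.mrc --seed 7
mapgan tile     --in map.mrc --out tiles.npz
mapgan untile   --in tiles.npz --out map.mrc
mapgan train    --config run.yaml --train-tiles train.npz --val-tiles val.npz --out ckpt/
mapgan generate --model in.pdb --checkpoint ckpt/ --out genmap.mrc
mapgan evaluate --a gen.mrc --b exp.mrc --json report.json
mapgan fixtures --n 8 --seed 7 --out-dir fixtures/
```

`train` reads tile pairs from an `.npz` with arrays `sim` and `exp` of
shape `(n, 32, 32, 32)`; a YAML config mirrors the `GanConfig` fields
(widths, `alpha`, learning rate, batch size, epochs, seed, ablation
switches). Checkpoints are directories holding `config.json`,
`weights.npz`, and `optimizer.npz`.

## Defaults worth knowing

- Simulation: resolution 2 Å, `sigma_factor = 1/(π√2)` (the molmap
  convention), Gaussian truncated at 5 σ, heavy atoms only.
- Generator: U-Net++ widths (18, 36, 72, 144, 352), 2 convs per block,
  instance norm + PReLU, trilinear ×2 upsampling — 10.3 M parameters.
- Discriminator: stride-2 convs (32, 64, 128, 256) → adaptive average pool
  → FC (256, 128, 64, 1) with sigmoid — 1.2 M parameters.
- Losses: generator = SmoothL1 + α·(−log D(fake)) with α = 0.01;
  discriminator = −(log D(real) + log(1 − D(fake))); NAdam, lr 1e-4.
- Tiling: 32³ tiles, stride 20, center-20³ reassembly (exact partition).
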