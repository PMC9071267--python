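# dreamgan

Three-phase wake–sleep adversarial representation learning for 32×32 RGB
images, in pure NumPy (custom reverse-mode autodiff — no deep-learning
framework required), together with a complete representation-quality
evaluation suite and sleep-pathology ablations.

Each training cycle processes one mini-batch through three phases:

- **Wake** — encode real images, reconstruct them through the generator, and
  train on the sum of image reconstruction loss, a batch-statistics KL
  regularizer pulling latents toward N(0, I), and a binary cross-entropy term
  teaching the discriminator head to classify the images as real.  The latent
  batch is stored in a two-slot episodic buffer.
- **NREM** — replay the stored latents through the generator, occlude the
  generated images with random gray patches, and train only the encoder to
  recover the stored latents.
- **REM** — generate from a convex combination of the current and previous
  latent batches plus Gaussian noise, then play an adversarial game on the
  fake-classification loss: the encoder/discriminator descends it while the
  generator *ascends* it (a sign switch of the generator's update).

The encoder is four stride-2 4×4 convolutions (64/128/256/latent channels at
reference scale); a scalar sigmoid discriminator head branches from the third
layer, so both heads share the trunk.  The generator mirrors the encoder with
transposed convolutions ending in tanh.  No normalization layers are used.

## CLI

```bash
dreamgan train    --config config.yaml [--pathology wo_rem] [--seed 0]
dreamgan evaluate --checkpoint run/checkpoint.npz --config config.yaml
dreamgan ablate   --config config.yaml --conditions full,wo_rem,wo_nrem,wo_mix
dreamgan synth    --out data/ --num-classes 4 --n-per-class 100
dreamgan dream    --checkpoint run/checkpoint.npz --output dreams/
dreamgan masks    --out masks.png
```

The YAML config has `dataset`, `training` and `evaluation` sections (see
`dreamgan.cli.DEFAULT_CONFIG` for all keys and defaults); unknown keys are
rejected, and every run writes its resolved config next to its outputs.
Datasets are either the built-in procedural shape generator (no downloads) or
local copies of the CIFAR-10 binary batches / SVHN cropped-digit MAT files.

Pathology conditions: `full`, `wo_rem` (no REM; noisy wake reconstruction and
NREM loss halved), `wo_nrem`, `wo_mix` (REM from a single memory),
`noise_only_rem`, `swapped_order`.

## Evaluation suite

`dreamgan.evaluation` implements: a linear softmax readout trained by SGD on
frozen latents (lr 0.2, 20 epochs, batch 64); test-set linear separability and
its occlusion-robustness curve (size-4 squares, intensities 0–100%); a 2-D PCA
projection; intra/inter-class and clean/occluded latent distance ratios; and
the Fréchet distance between feature statistics of real and generated images
with a pluggable feature extractor (desk-scale default: block-averaged
pixels; an Inception-style embedding can be injected as a callable).

## Desk-scale notes

Two small-scale adaptations keep the narrow test networks in the same dynamic
regime as the full-width reference setup (both are exposed as parameters and
default to the reference values at full width):

- `init_std`: the DCGAN-style fixed 0.02 weight init yields vanishing latent
  scales in narrow stacks, which destabilizes the NREM latent-replay loop;
  desk-scale runs use a width-aware value (0.15 at 8/16/32 channels).
- the desk-scale experiment uses learning rate 1e-4 (instead of 2e-4) for the
  same stability reason; all loss definitions and update rules are unchanged.
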