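# Methods

## Model

The package implements an adversarial segmentation model for grayscale
radiograph-like images.  Two networks are trained in alternation:

* **Generator** `G`: a noise vector `z ~ N(0, I_100)` is projected to a
  small base feature map (4×4 at full scale) and upsampled by *generator
  blocks*, each a pointwise (1×1) convolution that reduces channel width
  followed by two 4×4 fractionally strided convolutions with stride 2 (so a
  block multiplies resolution by 4).  Instance normalization and
  LeakyReLU(0.2) sit between layers; the output is a tanh rescaled to
  [0, 1].  With the pointwise reduction off, nothing reduces channel width,
  so all feature maps stay at the base width — the expensive reference
  design against which the ~10× parameter saving is measured (1.35×10⁷ vs
  1.36×10⁸ at 1,024² output with the default schedule 1024→512→256→128→64).
* **Discriminator** `D`: a U-shaped encoder–decoder that maps an image to a
  per-pixel probability distribution over three labels — lung, background,
  fake — via a channel softmax.  There is no explicit "real" output;
  real-ness is `1 − P(fake)`.  Grayscale input is replicated to three
  channels (an RGB-native encoder contract).  Encoders: a ResNet-50-layout
  stack (bottleneck blocks, stages 3/4/6/3, total stride 32) or a four-stage
  small CNN (total stride 16) for CPU-scale work.  The decoder mirrors the
  encoder with one ×2 upsampling block per encoder downsampling — each
  block is a 3×3 convolution, a 1×1 connector, and a 4×4 fractionally
  strided convolution — with skip connections concatenating encoder
  features into the matching decoder stage, so output resolution always
  equals input resolution.

Losses (flat arithmetic means over every pixel in a batch):

```
L_l = mean[ −log D(y|x) ]            annotated pixels, y the true class
L_u = mean[ −log(1 − D(x)_fake) ]    unannotated / target-domain pixels
L_g = mean[ −log D(G(z))_fake ]      generated pixels
L_D = L_l + L_u + L_g                (unweighted)
L_G = mean[ +log D(G(z))_fake ]      generator objective (saturating)
```

Annotated images contribute only through `L_l` (they are not double-counted
in `L_u`; raising `D(y|x)` already lowers `D(x)_fake` through the softmax).
A non-saturating generator variant (`−log(1 − D_fake)`) is available behind
a flag, off by default.  The classic-GAN ablation arm (`mode="original_gan"`)
gives the decoder two classes only and adds a whole-image real/fake head
(global average pool + dense + sigmoid) trained with image-level binary
cross-entropy.

Unsupervised domain adaptation is the same optimization with source images
in the annotated role and target images in the unannotated role; nothing
else changes.

## Numerical conventions

* Logarithms are clamped: `log(max(p, 1e-8))`, with zero gradient in the
  clamped region, so one-hot maps from hard-trained networks never produce
  NaN/Inf.
* Convolutions that feed a normalization layer carry no bias; instance
  normalization is non-affine with epsilon 1e-5.  (These conventions are
  what make the generator parameter counts come out at 1.35×10⁷ and
  1.36×10⁸.)
* Weights are initialized N(0, 0.02); Adam uses betas (0.9, 0.999).
* FLOP counting: only multiply–accumulate layers are counted, one MAC = 2
  operations, a bias add = 1 per output element; normalizations and
  activations are free.  Reported FLOP totals are therefore convention-
  dependent and are not comparable across tools.
* Inference: per-pixel argmax over the two *real* classes only (the fake
  channel is a training device); ties go to background.
* Dice and Jaccard are computed per image and then averaged; when both
  masks are empty both metrics are defined as 1.
* All layers are implemented in numpy (float64) with hand-written backward
  passes, verified against central finite differences to ~1e-9 in the test
  suite.  With a fixed seed, runs are bitwise reproducible on CPU, and a
  checkpoint (weights, Adam moments, RNG state, loss history) resumes to
  the identical trajectory.

## Training schedule

The published protocol is 500 epochs of Adam with generator/discriminator
learning rates 0.001/0.0001, both ×0.1 after epoch 200, at 1,024² with a
pretrained ResNet-50 encoder; that remains available as the full-scale
preset (`TrainConfig.full_scale()`), with the caveat that no pretrained
weights ship with the package — `encoder="resnet50-pretrained"` requires a
user-supplied `.npz`, while `resnet50-random` trains the same layout from
scratch.  An epoch is one shuffled pass over the larger pool, with the
smaller pool and the noise batch resampled each iteration; one
discriminator step and one generator step per iteration; in supervised mode
the generator is disabled and only `L_l` is optimized.  When
`lr_decay_epoch` is unset it defaults to 40% of the schedule, the published
200-of-500 proportion.

## Phantom data

The generator of synthetic study data emulates the statistics the method
assumes: square images with two non-overlapping dark elliptical "lung
fields" (lungs are radiolucent) on a brighter background with horizontal
sinusoidal "rib" texture and i.i.d. Gaussian noise, clipped to [0, 1]; the
mask is exactly the rasterized ellipse interiors.  Defaults: background
0.65, lungs 0.30, noise sd 0.08, rib amplitude 0.08 at 6 cycles per image
height, total lung area 15–30% of the image, vertical/horizontal axis ratio
1.4–2.2.  Domain shift is intensity-only (gamma curve, contrast scale,
smooth random bias field, optional extra noise) so ground-truth masks carry
over unchanged; spatial shift is deliberately excluded because it would
invalidate the masks.

What phantoms do **not** model: anatomy (mediastinum, clavicles, costophrenic
angles), scanner-specific texture, pathology, and inter-observer mask
uncertainty.  Passing the desk-scale studies therefore demonstrates the
*mechanics* of the pixel-level adversarial losses and the direction of the
published comparisons, not clinical-grade absolute accuracy.

## Desk-scale study conditions

All comparative studies run at: resolution 32², 100 phantoms per domain,
80/20 (or 7:1:2) splits, 25% of the training pool annotated, batch 8,
30 epochs, small-CNN encoder with stage widths (12, 24, 36, 48) and decoder
widths (48, 36, 24, 16), three seeds.  Two deliberate departures from the
full-scale protocol, both consequences of compressing ~6,000 discriminator
steps into ~300:

* the discriminator trains at the generator's published rate 1e-3 (at the
  full-scale 1e-4 the desk-schedule discriminator never leaves the
  near-uniform regime, and every downstream comparison would measure noise);
* the encoder is sized so the two-domain adaptation model is not
  capacity-starved relative to the single-domain baseline.

The adaptation studies use a gamma-2.0 + bias-field shift with bias
amplitude 0.2 — about half the lung/background contrast, severe enough to
visibly degrade an unadapted source model while leaving every target region
recoverable in principle.

## Known limitations

* The desk-scale semi-supervised margin is small (a few 0.01 Dice), matching
  the small published effect; with easy phantoms and converged supervised
  baselines individual seeds can tie or invert.
* Adversarial training at 32² with batch 8 is noisy; adaptation gains vary
  by a few 0.01 Dice across seeds, and the adapted model can cede some
  source-domain Dice at this capacity, a trade-off the full-capacity
  published result does not show.
* The FLOP figures of the printed architecture comparison are not
  reproducible from any stated convention and are reported here only under
  the package's own documented convention.
* Masks are strictly binary (single foreground class); DICOM ingestion and
  data augmentation are out of scope.
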