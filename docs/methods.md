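# Methods

## Problem and model

Agricultural phenotyping pipelines extract leaf shape, posture and colour
from field photographs; water haze destroys exactly the texture detail
those measurements need, and a field cannot be photographed hazy and clear
at the same moment, so supervised (paired) dehazing is not an option.
`hazecycle` learns the hazy → clear mapping from *unpaired* image sets by
combining three ingredients:

1. **Atmospheric scattering model.** Haze formation is
   `I(x) = J(x) t(x) + A (1 − t(x))` with scene radiance `J`, observed
   image `I`, per-pixel transmission `t ∈ (0, 1]` and global atmospheric
   light `A`.  Under homogeneous haze `t = exp(−β · depth)` with
   extinction coefficient `β`.
2. **Cycle-consistent adversarial training.** Two translation cycles
   (hazy → clear → hazy and clear → hazy → clear) with mean-L1
   cycle-consistency, so the unpaired mapping preserves scene content.
3. **Dual discriminators per domain.** A shallow *detail* critic emits a
   spatial patch-score map (texture sensitivity); a deeper *structure*
   critic reduces the whole image to a 4×4 score block (global layout).
   Their adversarial losses are combined with equal weight — the
   combination rule is an open design point and the mean is the least
   informative choice.

The dehazing generators output both a haze-free estimate `J_hat` (sigmoid
head) and a transmission map `t_hat` (sigmoid rescaled to `[0.05, 1]`)
from a shared encoder with two U-net decoders.  The **haze-consistency
loss** recomposes `J_hat · t_hat + A(1 − t_hat)` and penalises its mean L1
distance to the actual hazy input; this anchors the adversarially-learned
mapping to the physics and is applied to both dehazing-direction
generators.  `A` is the brightest BT.601 gray level of the generator's
input, treated as a constant (no gradient).  Since `J_hat`, `t_hat` and
`A` all lie in `[0, 1]` the recomposition is a convex combination and
never needs clipping.

### Total objective

```
L = L_adv(clear domain) + L_adv(hazy domain)
  + λ (L_cyc(hazy cycle) + L_cyc(clear cycle))
  + w_haze · L_haze
```

with `λ = 10` (the usual cycle-GAN weighting) and `w_haze = 10` (chosen so
the physics term enters at the same order as the cycle term; neither
weight has a reference value).  The generator's adversarial view is
non-saturating (`−log D(G(x))`) by default because the literal minimax
term vanishes when the discriminator wins early; the saturating form is
available via `LossWeights(saturating=True)`.

## Architecture

Channel progression 64–128–256–[512 residual trunk]–256–128–64, scaled by
`width_multiplier` (1.0 reproduces the full model; small multipliers give
desk-scale models).  7×7 stems/heads with reflection padding, 3×3
stride-2 down-convolutions, residual blocks at the trunk width entered
and exited by 3×3 transition convolutions, stride-2 transposed
convolutions mirrored back up, and U-net skip concatenations at every
encoder resolution.  Generators use instance normalisation (the style
transfer convention); discriminators use batch normalisation with
leaky-ReLU (slope 0.2), 4×4 kernels on the stride-2 stages.  The detail
discriminator is four Conv–BN–LeakyReLU stages (strides 2,2,2,1) plus a
1×1 sigmoid scoring convolution; the structure discriminator downsamples
by stride-2 stages until the map is 4×4 (six stages at 256×256, adapting
for other power-of-two sizes) plus one stride-1 stage and the 1×1 scoring
convolution.

Training uses Adam with betas (0.5, 0.999), batch size 1, update order
generators-then-discriminators once each per iteration, hard 1/0 labels,
no replay buffer and no identity loss.  The learning rate is held at its
base value for the first half of the run and decayed linearly to exactly
zero at the end.

### The numerics underneath

No pre-installed package provides trainable convolutional networks, so
the package carries a minimal reverse-mode autodiff engine
(`_autodiff.py`): float32 NCHW tensors, im2col convolution lowered to
BLAS matrix products, transposed convolution composed from zero-dilation
+ padding + valid correlation (its backward pass then falls out of the
primitives), and manually derived backward rules for the normalisation
layers.  Every primitive is verified against central finite differences
in the test suite.  The training graph is float32 for speed; the loss
functions additionally provide a float64 fast path for plain-array inputs
so that metric-grade evaluations are double precision.  Discriminator
scores are clamped to `[1e−7, 1 − 1e−7]` before any logarithm.

## Synthetic benchmark

The generator emulates the features of foliage field imagery that matter
to dehazing: overlapping elliptical leaves with per-leaf green hues,
centre-to-edge shading, a dark mid-rib with oblique lateral veins (sharp
edges → high gradient energy), over a smooth soil-toned background.  Haze
is synthesized through the same scattering model the network assumes:
per-image `A ~ U(0.7, 1.0)`, `β ~ U(0.6, 2.5)` and a Gaussian-smoothed
white-noise pseudo-depth field (sigma 0.25 of the image side).  This
makes recovery well-posed and the benchmark fully self-contained.

Unpairedness is structural: clear-domain scenes use even derived seeds,
hazy-domain scenes odd ones, so no training image has its counterpart in
the other domain.  The manifest records every scene seed and the haze
parameters of every hazy file, which lets evaluation regenerate the
*withheld* paired ground truth of hazy test images; training never reads
it.  Default dataset sizes are 407/479 train and 51/49 test images,
matching the field study the benchmark stands in for.

What the benchmark does **not** model: real water-haze microphysics
(wavelength-dependent scattering, non-smooth transmission), sensor noise,
exposure variation, and true plant morphology.  Passing the recovery test
therefore shows the *system* works end to end on scattering-model haze —
it does not certify performance on natural field haze.

## Scaled-down study protocol

Full-scale training (256×256, width 1.0, 10 000 iterations) takes GPU
days; the package's reference experiment (`desk_config`) runs in minutes
on one CPU: 64×64 images, width multiplier 0.125, 3 residual blocks,
24 + 24 unpaired training images, 20 held-out hazy test images, 200
iterations, base learning rate 5e−4 (raised from the full-scale 1e−4
because the narrow model and short schedule need proportionally larger
steps), three seeds.  Recovery is scored per held-out hazy image: is the
dehazed output's EGF strictly higher than the hazy input's, and is its L1
distance to the withheld clear ground truth strictly lower?  The package
requires both to hold on ≥ 80 % of test images as a 3-seed median, and
the no-physics ablation (translation-only generators, `w_haze = 0`) must
not beat the physics arm on either metric under identical seeds.

## Evaluation indices

* **EGF** (energy gradient function): the image is converted to 8-bit
  scale BT.601 grayscale and the squared forward differences in x and y
  are summed and divided by `H·W` (the 256×256 normaliser of the
  reference formulation generalised to the actual size); boundary
  differences that would leave the image are omitted.  Scales
  quadratically with contrast and strictly decreases under blur.
* **FID**: Gaussians are fitted to feature embeddings of the two image
  sets (sample means, unbiased covariances) and the squared Wasserstein-2
  distance `‖μx − μz‖² + Tr(Σx + Σz − 2(ΣxΣz)^{1/2})` is reported.  The
  matrix square root uses an eigendecomposition of the product with
  negative eigenvalues clamped at zero and imaginary residue discarded;
  the result is floored at 0.  The default extractor is a fixed-seed
  random-weight convnet with global average pooling (`random64`, d = 64):
  fully deterministic and dependency-free.  FID values are comparable
  only within one extractor, which every report records; numbers from
  `random64` are *not* comparable with Inception-based FIDs.

## Numerical choices and degenerate inputs

* Transmission is clamped to `t ≥ 0.05` before any division, bounding
  inversion amplification at 20×; the scattering round-trip identity is
  exact wherever the forward model did not clip (which, for inputs in
  `[0, 1]`, is everywhere).
* `A` is a single scalar per image (the formulation names one brightest
  value); a per-channel variant was considered and rejected as a larger
  departure.
* Images are floats in `[0, 1]` internally; 8-bit quantisation happens
  only at file I/O (round-trip error ≤ 1/255).
* Generator inputs not divisible by the total stride 4 are
  reflection-padded up and cropped back, never rejected.
* Checkpoints are self-describing (config + parameters + Adam moments +
  sampler state), so resuming reproduces the uninterrupted trajectory
  bitwise; loading re-checks the stored config.
* A non-finite loss raises a divergence error naming the term and the
  iteration rather than training on.

## Known limitations

* The engine is CPU-only and unbatched in practice (batch size 1); the
  full-scale configuration is supported but slow.
* The adversarial game at desk scale is short; the recovery experiment
  demonstrates direction and magnitude of improvement, not convergence to
  a Nash equilibrium.
* The `random64` FID extractor captures colour/contrast/texture
  statistics but not semantics; it orders distributions sensibly on this
  benchmark (hazy sets score far from clear sets, dehazed sets closer)
  without claiming comparability to Inception FID.
* The benchmark's haze is generated by the very model the physics branch
  assumes — deliberately, to make recovery well-posed — so it cannot
  detect model misspecification under real haze.
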