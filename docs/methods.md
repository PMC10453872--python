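# Methods

`lesiongan` implements a semi-supervised deep convolutional GAN for
dermoscopy-style image synthesis and benign/malignant classification,
together with the image-preprocessing pipeline and the evaluation stack
around it. This note records the model, the defaults and the reasoning
behind the choices that were genuinely open.

## The adversarial model

A generator G(z; W_g) maps a latent vector z ~ N(0, I) of length 100
through five fractional-stride (transposed) convolution stages —
4×4×512 → 8×8×256 → 16×16×128 → 32×32×64 → 64×64×3 — with batch
normalization and ReLU on the hidden stages and a Tanh output, so generated
images live strictly inside (−1, 1). A discriminator D(x; W_d) mirrors the
tower with five convolutional layers (LeakyReLU, slope 0.2) whose head has
N+1 = 3 softmax units: the two real classes (benign, malignant) plus a
*fake* class. The probability that an input is real is 1 − p(fake), and
class prediction renormalizes the two real-class probabilities. The two
networks play the minimax game

    min_G max_D  V(G, D) = E_{x~p_data} log D(x) + E_{z~p_z} log(1 − D(G(z))),

whose inner optimum is D*(x) = p_data(x) / (p_data(x) + p_g(x)); when the
generator matches the data distribution, D* ≡ 1/2 and V = −2·log 2. The
`gan_core.theory` module evaluates these quantities exactly on finite
discrete distributions and serves as the analytic oracle for the learning
code.

Kernel geometry is 4×4, stride 2, padding 1 for all intermediate stages;
the generator's first stage maps the latent vector to 4×4×512 with a
stride-1, no-padding transposed convolution, and the discriminator's final
stage is a 4×4 valid convolution onto the three logits. Batch norm is
placed on all generator stages except the output and all discriminator
stages except input and output — the placement that keeps the output
distribution and the raw input unnormalized, as is conventional for this
architecture family.

## Losses and optimization

* Adversarial discriminator loss: `d_loss = d_real_loss + d_fake_loss`
  with `d_real_loss = mean −log P(real|x_real)` and
  `d_fake_loss = mean −log(1 − P(real|G(z)))`.
* Supervised loss: mean cross-entropy −log p(true class) over the *labeled*
  real samples of the minibatch (a configurable fraction of training
  records is marked unlabeled and contributes only adversarially).
* Generator loss: the saturating minimax form `mean log(1 − D(G(z)))` by
  default, with the standard non-saturating `−log D(G(z))` variant as an
  option for runs where the discriminator races ahead early.
* Optimizer: classical-momentum SGD (v ← m·v − lr·g, w ← w + v), defaults
  learning rate 0.01, momentum 0.5, minibatch 64. All convolution weights
  are initialized from N(0, 0.02²), biases at zero.

Probabilities are clamped at ε = 1e-7 before logarithms. Gradients at the
softmax head are implemented in algebraically simplified, bounded form: the
naive chain-rule factor p_fake/(1 − p_fake) for the −log P(real) terms
overflows once the discriminator saturates, while the simplified form has
every entry in [−1, 1]. This matters in practice — with the naive form a
saturated discriminator feeds the generator astronomically large steps and
the game never recovers.

Each minibatch takes one discriminator step (real batch, then generated
batch, one combined optimizer update, with the supervised term folded into
the real-batch pass) and one generator step with the discriminator frozen.
Real and generated batches are normalized by their own batch statistics
(separate forward passes); only the *real* batches update the running
statistics used at evaluation time, since the deployed classifier sees
real images — letting generated batches pollute the running estimates
demonstrably destroys eval-mode accuracy while leaving train-mode accuracy
intact.

The whole network stack is implemented in numpy with explicit
backpropagation: convolutions lower to a single (C·k·k) × (N·L) GEMM per
layer via im2col, and the transposed convolution is the exact adjoint of
the strided convolution (verified by adjoint identities and central finite
differences in the test suite).

## Preprocessing pipeline

Stages run in a fixed order, each individually toggleable:

1. **Bicubic rescaling** — Keys cubic-convolution kernel with a = −0.5,
   pixel-center alignment, edge clamping: each output pixel is a weighted
   average of its 16 nearest source pixels. (The B-spline "bicubic" of
   generic resize routines is a different kernel; this one is implemented
   directly so the 16-neighbor contract holds exactly.)
2. **Normalization** to [0, 1] (divide by 255 when the input is 8-bit).
3. **Histogram equalization** on the CIELAB L channel (256 levels,
   mapping out(v) = round((cdf(v) − cdf_min)/(1 − cdf_min)·255), half-up
   rounding), chroma untouched so hue is preserved; constant images are
   returned unchanged (the mapping is 0/0 there).
4. **Combined sharpening** — spatial unsharp masking
   (out = clip(img + amount·(img − blur_σ(img))), σ = 1, amount = 1) and
   frequency-domain Gaussian high-pass filtering
   (H = 1 − exp(−D²/2D0²), D0 = 0.05 cycles/pixel = 0.1 × Nyquist,
   gain = 1), blended 0.5/0.5. The blend weights have no published value;
   equal weighting is the package default and configurable.
5. **CIELAB color balance** — each LAB channel is shifted/scaled to target
   mean and standard deviation (defaults μ = (50, 0, 0), σ = (25, 10, 10)
   LAB units — a mid-lightness chroma-neutral reference; these targets are
   package conventions, not published values). Zero-variance channels are
   re-centered, not scaled.
6. **Median filtering** — per-channel k×k window, k = 3, reflect padding.

Noise models (salt & pepper, Gaussian, speckle, Poisson with a 255-photon
budget) are provided for denoising evaluation together with MSE, PSNR
(10·log10(MAX²/MSE), MAX from the declared intensity range) and SSIM
(canonical 11×11 Gaussian window, σ = 1.5, K1 = 0.01, K2 = 0.03, on
luminance). Reported MSE/PSNR/SSIM triples for this pipeline in the
source literature are mutually inconsistent under the PSNR definition, so
the package treats only the definitions, not those triples, as normative.

## Synthetic data

Real dermoscopy archives cannot ship with the package, so
`synthetic_data` generates ISIC-schema datasets: skin-toned backgrounds
with an illumination gradient, one elliptical lesion whose border is
modulated by random low-order harmonics (amplitude ∝ per-class
*irregularity*) and whose color is a per-class RGB mean plus per-pixel
Gaussian dispersion, plus optional thin dark hair-like streaks. Defaults:
2000 images, balanced classes, 64×64 px, benign = smooth light-brown with
spread 0.03, malignant = jagged dark with spread 0.09, hair probability
0.3. The class signal therefore lives in border irregularity and color
statistics — the axes clinicians actually use — and its strength is a
knob: with widely separated class means a trivial mean-color threshold
reaches ≥95 % accuracy, which guarantees the downstream classifier tests
are well-posed.

What the generator does *not* emulate: dermoscopic texture (pigment
networks, dots, globules), specular highlights, rulers/markers, varying
illumination color, inter-image resolution differences. Passing tests
therefore show that the pipeline and the learning machinery work end to
end on images with this covariate structure — not that the classifier
reaches any particular accuracy on clinical data.

Train/test splitting is stratified by target: the global train size is
round(0.7·n), apportioned across classes by largest fractional remainder
(this reproduces exact 70/30 arithmetic at both archive scale, 2000 →
1400/600, and toy scale, 10 → 7/3, which per-class rounding cannot do).
A seeded 30 % of each class's train records is then marked unlabeled.

## Desk-scale study conditions

The reference training conditions (SGDM 0.01/0.5, batch 64, init 0.02,
latent 100) are the package defaults. The test suite exercises training at
sizes a single CPU handles in minutes, as the package's own desk-scale
protocol:

* **Classification recovery**: 400 synthetic images (280 train / 120
  test, 30 % unlabeled), batch 16, 3 epochs. The discriminator-classifier
  reaches ≥90 % test accuracy — the scaled-down stand-in for full-data
  results.
* **Score equilibrium**: 64 identical constant images (a distribution the
  generator can represent exactly), batch 16, 10 epochs, learning rate
  0.01 with momentum 0 and the saturating generator loss. Because the data
  distribution is a single point, any deviation is detectable and the
  discriminator would dominate under aggressive settings; with momentum
  disabled the two-player dynamics oscillate tightly around the 0.5
  equilibrium, and the mean discriminator score over the final fifth of
  iterations settles in (0.3, 0.7). This run demonstrates the equilibrium
  signature, not production training settings.

## Known limitations

* Pure-numpy training is single-process and CPU-bound (~1.5 s per
  batch-16 iteration at 64×64); the package targets method correctness and
  desk-scale experiments, not large-scale training.
* The saturating generator loss stalls once the discriminator saturates
  (its gradient vanishes); the non-saturating option exists for that
  regime, and neither guarantees convergence on disjoint-support tasks.
* Checkpoints store weights and normalization statistics, not optimizer
  velocity; resuming mid-run restarts momentum.
* ROC/AUC uses the trapezoidal sweep with ties counted ½ (equivalent to
  the pairwise ranking probability); confusion-derived metrics report 0
  with a degeneracy flag when a denominator is empty.
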