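# Methods

This note records the scientific and numerical choices behind octinpaint:
what is modeled, which parameters matter, what the synthetic benchmark does
and does not emulate, and where the design was genuinely open.

## Problem setting

AS-OCT B-scans of the cornea show a bright, curved, multilayer arc over a
dark background, degraded by multiplicative speckle. A saturation artifact
is a vertical stripe of (near-)saturated pixels crossing the cornea where
the beam met the surface perpendicularly. Repair is formulated as masked
inpainting: given the artifact image *s* and a binary mask *m* (1 = region
to repair), produce an image that equals *s* outside the mask and plausible
corneal tissue inside it.

## Dual-generator adversarial model

Two U-Net generators translate between the artifact and clean domains, two
PatchGAN discriminators judge realism patch-wise, and a cycle term ties the
two directions together. Even though the synthetic task provides aligned
pairs (s, w), the dual/cycle structure is retained: the adversarial and
cycle terms regularize textures (notably speckle statistics) that purely
supervised pixel losses flatten.

**Generator.** Encoder: one plain 4×4 stride-2 convolution, then
ReLU–Conv–LayerNorm blocks, then a ReLU–Conv bottleneck; decoder:
ReLU–ConvTranspose–BatchNorm–Dropout blocks (dropout 0.5 in *all* decoder
blocks) and a final ReLU–ConvTranspose–Tanh; skip connections concatenate
mirrored encoder features. Every sampling step halves/doubles the spatial
size, so a 2^d-sided input bottoms out at 1×1 with depth d; for the nominal
256×256 input the depth is 8, and for smaller power-of-two test images the
depth auto-reduces (documented "small-image mode"). The LayerNorm
normalizes each sample over all of (C, H, W) with a per-channel affine.
Channel widths double from `base_channels` and are capped (`channel_cap`);
the nominal widths are 64…512. The generators receive only the image — the
mask enters solely through compositing and region-restricted metrics.

**Compositing.** The artifact-removal generator's raw output is spliced
into its input through the mask, in [0, 1] storage space, using a selective
`where` so the unmasked pixels are *bit-identical* to the input, not merely
close after arithmetic. The composite is applied wherever G_A is invoked,
including inside the cycle. G_B's output is used raw.

**Discriminator.** Five 4×4 convolutions, strides (2, 2, 2, 1, 1), padding
1, LeakyReLU slope 0.2, BatchNorm on the middle three, final sigmoid. The
stride schedule is the unique standard five-layer 4×4 arrangement whose
receptive field is 70×70; the package checks that number two independent
ways (the jump/size recursion, and backpropagating a single patch score to
measure the input support — run with frozen batch statistics, since batch
normalization in training mode couples all spatial positions through the
batch mean and would delocalize the footprint).

**Weight initialization** is zero-mean Gaussian, σ = 0.02, seeded; identical
(spec, seed) construction is bit-reproducible.

## Losses

All terms are mean-reduced (pixels, frequency bins, patch scores, batch) so
the weights stay comparable across image sizes. Defaults
λ = (50, 1, 100, 1, 1) for (SSIM, frequency, L1, adversarial,
reconstruction).

* **SSIM loss** `(1 − SSIM)` in both directions. SSIM uses the
  conventional 11×11 Gaussian window (σ = 1.5), valid-mode convolution, and
  stabilizers C1 = (0.01 L)², C2 = (0.03 L)² with L the declared dynamic
  range (1 in storage space). A `window="global"` mode computes the single
  whole-image statistic instead — used for tiny inputs and narrow crops.
  The implementation is a pure autodiff composition and agrees with
  scikit-image's `structural_similarity` (gaussian_weights, no sample
  covariance) to machine precision; mean-of-ones is computed by true
  division so `ssim(x, x) == 1.0` exactly.
* **Frequency loss**: mean complex modulus of the difference of
  unnormalized 2-D DFTs, both directions. The gradient uses the analytic
  adjoint of the DFT (`H·W · real(ifft2(D/|D|))`). The |·| at a zero bin is
  given subgradient 0.
* **Pixel L1** and **cycle-reconstruction L1**: plain means of absolute
  differences, both directions, in storage space.
* **Adversarial**: the log-likelihood value
  E[log D_A(w)] + E[log(1 − D_A(G_A(s)))] + E[log D_B(s)] +
  E[log(1 − D_B(G_B(w)))] is ascended by the discriminators and *reported*
  as the adversarial term; the generators descend the standard
  non-saturating surrogate −E[log D(fake)]. Scores are clamped to
  [10⁻⁶, 1 − 10⁻⁶] inside logs (clamping passes no gradient outside the
  interval); the reporting function instead rejects scores outside the open
  unit interval, which catches a missing sigmoid.

Complex L1 is read as the modulus of the per-bin complex difference (the
literal norm of a complex number); the alternative real+imaginary reading
differs by at most √2 and is not used.

## Training loop

Per batch: one RMSprop ascent step for both discriminators (fakes
detached), then one RMSprop descent step for both generators against the
just-updated discriminators. RMSprop: α = 0.99, ε = 10⁻⁸; lr 5·10⁻⁴
(generators) / 10⁻⁴ (discriminators); batch 4. No gradient clipping. Terms
with zero weight are skipped entirely, so λ_adv = λ_recon = 0 yields a pure
supervised regression and λ_SSIM = 0 / λ_F = 0 are the ablation variants.

Images are [0, 1] on disk, [−1, 1] inside the networks (Tanh); the affine
conversion is exact. All randomness (weights, dropout, shuffling, phantom
speckle, mask draws) flows from explicit integer seeds through
`numpy.random.Generator`; checkpoints store every parameter, buffer,
optimizer accumulator and RNG state, so a resumed run reproduces the
uninterrupted record stream exactly. Checkpoint and dataset writes are
atomic (temp-then-rename). Divergence (non-finite loss) aborts with the
last finite record attached.

## Synthetic corneal phantom

The clinical source data are private, so the benchmark generates scenes
with known geometry:

* EP is a circular arc (`arc_radius`, apex near the top); beneath it lie
  three constant-intensity bands — epithelium, Bowman's layer, and stroma
  down to the endothelium — whose lower edges define BL and EN. Defaults at
  256×256: radius 320 px, apex row 48, thicknesses (10, 6, 44) px,
  intensities (0.90, 0.55, 0.35), background 0.05; all scale linearly with
  image size via `default_params(size)`.
* Tilt rotates the arc center about the image center (±15° across a
  dataset by default), emulating scans acquired at different inclinations;
  opposite tilts give exactly mirrored geometry, which the tests exploit
  as a flip oracle.
* Speckle is multiplicative, `img·(1 + 0.25·g)` with g ~ N(0, 1), clipped
  to [0, 1] — the standard first-order OCT speckle approximation.
* The artifact is a single vertical stripe of constant fill, default 1.0
  (saturated white, matching the physical appearance of a detector-
  saturating reflection); 0.0 is available for a black-stripe reading.
  Stripe width and center are drawn uniformly per sample; test-set stripes
  are drawn wider than training stripes to probe generalization.
* Boundary labels are 1-pixel curves (one marked pixel per corneal
  column), anterior-to-posterior ordered (EP < BL < EN row indices).

The phantom reproduces the *statistical structure* the method needs —
bright tilted multilayer arc, dark background, multiplicative speckle,
saturated stripe — and nothing else. It does not emulate swept-source
acquisition physics, A-scan geometry, depth-dependent attenuation,
pathology, or instrument-specific noise. Passing tests therefore
demonstrate that the method and metrics behave as designed on images with
this structure, not clinical-grade performance.

Clean images are quantized to 8-bit before corruption, so the paired-sample
identity (artifact = clean outside the mask) survives the PNG round trip
bit-exactly.

## Metrics

* **PSNR** is computed over exactly the masked pixels ("repaired region"),
  10·log10(L²/MSE), capped at 100 dB as the MSE = 0 sentinel.
* **SSIM** is computed over the mask's bounding box (a windowed statistic
  needs 2-D support); stripes narrower than the 11-pixel window use the
  global-window mode. Full-image mode is available for both.
* **Segmentation**: DSC = 2|X∩Y|/(|X|+|Y|), PA, F1 = 2TP/(2TP+FN+FP) and
  Jaccard from exact pixel counts; DSC ≡ F1 and DSC = 2J/(1+J) are enforced
  as identities in tests. Two empty masks score 1 (perfect agreement).
* **Boundary recovery**: a deliberately simple per-column intensity
  threshold (default 0.2) marks the first and last bright pixel as EP and
  EN and fills the band between them. On a saturated stripe this drags the
  recovered region to the image borders, which is precisely the
  segmentation damage the artifact causes; dataset-level evaluation scores
  the recovered region of the repaired image against the same segmenter on
  the clean image. Curve-vs-curve comparison with a configurable dilation
  tolerance (default 0: strict) is also provided. A learned segmenter is
  out of scope; the threshold segmenter is the package's own stand-in and
  is labelled as such.

LPIPS is intentionally excluded (it requires pretrained perceptual-network
weights); the evaluation report schema leaves room for an externally
computed column.

## Problem sizes used in the checks

The test suite and examples run at 64×64 (and 32×32 for plumbing) with
narrow networks (base 4–8 channels, cap 16–64), 36 training pairs and a few
hundred steps — sizes chosen so a complete train–repair–evaluate cycle is a
minutes-scale, single-CPU computation. At these sizes the trained model
raises median masked-region PSNR on held-out phantoms from ≈1 dB (the
saturated stripe scored against the clean image) to ≈18 dB, and
threshold-segmentation DSC from ≈0.73 to ≈0.99. The nominal configuration
(256×256, depth 8, 64-channel base) is the package default for real use.

## Known limitations

* The phantom's layer interiors are piecewise constant apart from speckle;
  real stroma has depth-dependent texture the generator never sees.
* The threshold segmenter assumes a single bright band per column; it is
  not a clinical segmentation method.
* CPU-only NumPy training is practical at benchmark sizes but slow at
  256×256 with nominal widths; the architecture is framework-agnostic, and
  the losses/metrics are independently reusable.
* The adversarial game at tiny batch/model sizes is noisy; the package
  reports medians over seeds for train-time claims.
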