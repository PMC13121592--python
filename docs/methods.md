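# Methods

## The translation model

Virtual staining is posed as unpaired image-to-image translation between a
3-channel multispectral autofluorescence (MAF) domain X — planes ordered
(DAPI, SpGr, SpOr), a convention carried through all I/O — and an RGB H&E
domain Y. Two generators and two PatchGAN discriminators are trained
adversarially with cycle consistency, so no pixel-level registration between
domains is ever required. The core assumption is that the endogenous
fluorophore signal determines stain appearance well enough that a
deterministic mapping exists; the two auxiliary losses encode the prior that
*structure* — above all nuclei — must survive translation even when color is
free to change.

**Generator.** Residual encoder–decoder: 7×7 convolution to `base_width`
(default 64) channels, two stride-2 downsampling convolutions (2×, 4×
width), `n_residual` (default 9) residual blocks at 4× width (two
reflection-padded 3×3 convolutions with instance normalization and an
additive skip), two transposed-convolution upsampling stages, and a 7×7
output convolution with Tanh. Reflection padding on all 7×7/3×3 full-stride
convolutions avoids border artifacts in tiled inference. Inputs must have
spatial sizes divisible by 4 (two stride-2 stages); outputs are
size-preserving with values in (−1, 1).

**Discriminator.** 70×70-receptive-field PatchGAN (stride-2 4×4
convolutions, widths 64→128→256→512, leaky ReLU 0.2, instance norm after all
but the first stage), emitting a raw N×N patch-score map; on 256² inputs,
30×30. The log-form vs least-squares decision is deferred to the loss
module, so scores carry no terminal squashing. Note that instance
normalization couples spatial statistics: strict score locality holds for
the convolutional geometry (verified with `norm=False`), while the
normalized network's scores depend weakly on the whole image. Nothing in the
reference description of this architecture fixes the discriminator's depth or widths; the
70×70 four-stage design is the canonical companion of this generator and is
flagged as an assumption.

## The objective

`L = L_GAN(G_xy, D_y, X, Y) + L_GAN(G_yx, D_x, Y, X) + λ_cyc L_cyc +
λ_feat L_feat + λ_sal L_sal`

* **Adversarial** — the log form `E[log D(y)] + E[log(1 − D(G(x)))]` on
  sigmoid-squashed patch scores (probabilities clamped at ε = 1e-7) is the
  printed objective and the reported value; training defaults to it, with a
  least-squares variant behind `TrainConfig.adversarial="lsgan"` because
  least squares is the de-facto stable choice for this architecture. The
  generator minimizes the non-saturating complement −E[log D(G(x))].
* **Cycle** — mean absolute reconstruction error, both directions summed.
* **Global feature consistency** — per-layer distance between frozen deep
  features of each image and its translation, normalized by C·H·W,
  averaged over the layer set, both directions summed. The printed formula
  is squared L2 while the surrounding description says L1; the formula wins
  (`feature_variant="l2"` default, `"l1"` available). The extractor has
  VGG16 topology truncated at the deepest requested tap
  (relu1_1 … relu5_1); weights are injectable from an `.npz`, with a
  seeded-random He-initialized fallback so nothing is downloaded. Random
  frozen features still define a meaningful, repeatable perceptual metric
  for the consistency term, but absolute values are not comparable with
  ImageNet-pretrained numbers.
* **Saliency consistency** — binary nuclear masks by fixed gray thresholding
  at 170 (0–255), opening then closing with a 3×3 square element (one
  iteration each; borders treated as same-as-edge so a uniform
  suprathreshold image maps to an all-ones mask), L1 between source and
  translated masks, both directions. AF images are bright-salient and use
  the DAPI plane as gray; H&E images are dark-salient and use luminance
  (0.299R + 0.587G + 0.114B) inverted before thresholding. The operator's
  two arguments in the loss are taken to be the domain-X and domain-Y batch
  images themselves. Hard thresholding plus morphology has zero gradient
  almost everywhere, so the *reported* loss is the exact hard-mask value
  while the *training gradient* flows through a smooth surrogate:
  sigmoid((gray − 170)/τ) with τ = 12 gray levels and no morphology. The
  surrogate only steers optimization; every contract and test about the
  saliency loss refers to the exact operator.

λ defaults: λ_cyc = 10 (the established convention for this architecture),
λ_feat = λ_sal = 1 (unit weights for the auxiliary terms; no reference
values exist). All three are config-exposed.

## Training procedure

Adam with betas (0.5, 0.999) — the momentum pair is not part of the
reference recipe; this is the standard stability choice. Initial learning rate 2e-4, batch size 4,
200 epochs with the rate constant for the first 100 and decayed linearly to
zero afterwards; decay is applied per epoch (per-step decay would be an
equally defensible reading; per-epoch is the convention here). 10% of patches are held
out as validation, split at patch granularity with the run seed.
Augmentation is restricted to flips and 90° rotations, matching the blinded
review preprocessing and avoiding interpolation artifacts. Discriminators
update on a 50-image history pool of detached fakes (config-exposed;
0 disables). One run seed determines initialization, splits, batch order,
augmentation, and pooling; short runs reproduce bit-identically. A
non-finite loss raises a divergence error after saving the last-good
checkpoint. Generator updates deposit transient gradients in the
discriminators (the adversarial term backpropagates through them); those
gradients are zeroed without stepping, and a dedicated test asserts
parameter digests are unchanged.

The engine beneath all of this is a small NumPy CNN library (`vstain.nn`):
im2col/GEMM convolutions chunked over output rows to bound the column
buffer (~32 MB), the transposed convolution implemented as the exact
adjoint of the strided convolution, and manual reverse-mode gradients
validated layer-by-layer against central finite differences in float64.

## The tissue phantom

The phantom emulates the *contrast relationships* the translation task
depends on, from one latent layout per patch:

* nuclei: Poisson(`nuclei_rate`) count; ellipses with truncated-normal
  semi-axes (defaults 7 × 5 px, sd 1.2 scaled by `pleomorphism`), centers
  rejection-sampled to one mean radius spacing (overlap allowed after 100
  attempts) to mimic tissue packing;
* stroma: band-limited noise (Gaussian-smoothed white noise, smoothness
  σ = 6 px, amplitude 0.9) normalized to [0, 1];
* MAF render: DAPI = bright nuclei over dim background; SpGr/SpOr follow
  the stromal field with distinct gains and mild nuclear modulation;
* H&E render: Beer–Lambert absorption `I = 10^(−c·M)` with the classic
  Ruifrok-Johnston hematoxylin/eosin OD vectors, hematoxylin concentration on
  nuclei and eosin on stroma — so color deconvolution in the morphometry
  module inverts the forward model *exactly*, and optical-density
  assertions can be made to 1e-6;
* additive Gaussian intensity noise (sd 0.02 of dynamic range) and 8-bit
  quantization on export (3-plane TIFF for MAF, PNG for H&E).

One global seed; per-patch streams derived by counter
(`SeedSequence(seed, spawn_key=(index,))`), so datasets regenerate
byte-identically and paired mode gives exactly co-registered domains.

What the phantom does **not** emulate: real chromatin texture, overlapping
nuclei in 3D, scanner optics, flat-field or filter physics, stain batch
variability, or the nonlinear fluorophore–dye relationship of real tissue.
Passing tests on phantoms therefore certify the *machinery* — losses,
training dynamics, metrics, statistics — not clinical image quality.

## Evaluation stack

**FID/KID.** Images are resized to 299², rescaled to [0, 1], and embedded
by a frozen extractor; the reference protocol uses an Inception-V3 pool3
layer (2048-dim). Extractors are injectable; the default is a seeded-random
convolutional embedder (three strided He-initialized stages, global
mean+std pooling, fixed random projection), so the protocol runs with no
downloads — under any *fixed* extractor, comparisons between model variants
remain meaningful, while absolute magnitudes are extractor-specific and are
not compared against reference table values. FID uses the Gaussian-fit
Fréchet distance with the matrix square root computed by symmetric
eigendecomposition (eigenvalues clipped at 0; 1e-6 diagonal jitter for
near-singular covariances — deterministic and robust at small n). KID is
the unbiased MMD² with kernel (x·y/d + 1)³, subset size min(100, n), 100
seeded subsets. The full evaluation repeats 5 times with distinct seeds
and reports mean ± sd.

**Ablation analogue.** The reference single-channel comparison is
reproduced at desk scale as a property, not a number: per input variant
(each plane replicated to 3 channels, vs the full stack), a per-pixel
affine readout is fit from paired phantoms to H&E and its held-out
predictions are scored by FID. The multispectral variant's median FID over
≥ 5 seeds must not exceed any single-channel variant's. The linear readout
stands in for per-variant adversarial training because it isolates exactly
what the ablation probes — how much stain-predictive information the input
channels carry — at ~1 s per sweep instead of hours.

**Morphometry.** Classical segmentation (stain deconvolution → Otsu within
tissue, with a 0.15 OD hematoxylin floor for degenerate tissue → hole
filling → distance-transform watershed; cells by seeded label expansion of
6 px bounded by the tissue mask). The reference pipeline's segmentation
method is unspecified; here it is pluggable, and the concordance statistics
are the deliverable. Parameters: areas as pixel counts, circularity
4πA/P² with the Crofton perimeter (the plain boundary-step estimator
overestimates digital disks by ~3%, pushing circularity to ~0.93 where the
Crofton value is 1.01), moment-based eccentricity, maximal Feret caliper,
N/C area ratio, and per-stain OD means (nuclear hematoxylin, cytoplasmic
eosin, plus the nuclear-eosin variant since both appear in the reference
parameter lists). Concordance: shared Freedman–Diaconis bins on the pooled
sample; overlap = Σmin/Σmax of bin proportions; Jensen–Shannon divergence
base 2; two-sample KS (scipy's exact/asymptotic switching); Cohen's d with
pooled SD.

**Reader study.** Wilcoxon signed-rank with mid-ranks; zeros discarded
(classic treatment — the Pratt variant would change W in ways the reference
values cannot adjudicate). Exact two-sided p for n ≤ 25 by dynamic-
programming convolution of the signed rank-sum null over doubled ranks —
identical to full 2^n sign enumeration (asserted in tests) but feasible at
n = 25 — otherwise a tie-corrected normal approximation. Concordance
matrices count (pair, reader) observations at each (vHE score, HE score)
cell and report the fraction with vHE ≥ HE. The two-scenario ROC is an
interpretation, documented as such: the composite score (unweighted mean of
the four features; sum and single-feature composites are config options) is
binarized at the scenario threshold (≥ 3 "Good", ≥ 4 "Excellent") and that
indicator classifies modality (vHE positive) with the tie-corrected
Mann-Whitney AUC — which makes AUC = (sensitivity + specificity)/2 at the
single operating point, the relationship the reference AUC/sensitivity/
specificity triplets satisfy almost exactly.

## Problem sizes and numerical choices

Desk-scale study conditions, chosen once: the smoke-training run uses 16
phantom patches per domain at 64×64 for 200 steps with a width-12,
2-residual-block generator, 24/48 discriminator, batch 2, and a single-tap
(relu1_1) random feature extractor; the ablation uses 16 paired phantoms
per seed over 5 seeds; phantom concordance uses 10 patches of 128² per
side (~120 nuclei each); simulated reader tables use 18 pairs × 5 readers,
matching the blinded-study geometry. Tiled inference uses 256-px tiles
with 32-px overlap and separable linear feathering; with a
translation-invariant generator, tiled and untiled outputs agree exactly,
and with instance-norm generators the per-tile statistics differ slightly,
so the guarantee is "no seam discontinuity", not bit-equality. Background
filtering keeps patches whose fraction of pixels deviating more than
τ = 10/255 from the modal gray level is at least f_min = 0.05 (both
config-exposed; the reference filter is named but never defined).

## Known limitations

* Pretrained VGG16/Inception weights are optional inputs, not bundled;
  with the random fallbacks, absolute FID/KID and feature-loss magnitudes
  are extractor-specific.
* The saliency gradient surrogate ignores the morphological cleanup; masks
  dominated by speckle could make the surrogate disagree with the exact
  loss direction.
* The phantom's linear Beer–Lambert world is much easier than real
  histology; training results on it say nothing about clinical fidelity.
* The NumPy engine targets CPU correctness, not throughput: full-scale
  (256², width-64, 200-epoch) training is out of desk-scale reach by
  design.
* Exact Wilcoxon p-values assume exchangeable signs under H0; with heavy
  zero-inflation the classic zero-discard reduces effective n.
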