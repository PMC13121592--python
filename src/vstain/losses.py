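"""The four-term training objective and its component losses.

Total objective: two adversarial terms (one per translation direction), a
bidirectional cycle-consistency L1, a global feature-consistency term computed
on frozen deep features, and a saliency-consistency term comparing binary
masks of nuclear structure between each input and its translation:

    L = L_GAN(G_xy, D_y) + L_GAN(G_yx, D_x)
        + lambda_cyc * L_cyc + lambda_feat * L_feat + lambda_sal * L_sal

Conventions: images are NCHW arrays in model space (-1, 1).  The adversarial
value follows the log form (probabilities after sigmoid squashing of raw patch
scores); a least-squares variant is provided for training stability.  The
feature term defaults to squared L2 normalized by C*H*W per layer (the printed
formula), with an L1 variant.  Saliency masks are extracted by fixed gray
thresholding at 170 (0-255 scale) followed by 3x3 morphological opening then
closing; autofluorescence is bright-salient (DAPI nuclei), H&E is dark-salient
(hematoxylin nuclei, handled by inversion before thresholding).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import nn

_EPS = 1e-7
_SE3 = np.ones((3, 3), dtype=bool)

# ImageNet channel statistics used to normalize extractor inputs
_IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
_IMAGENET_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)

VGG16_TOPOLOGY = (
    # (name, out_channels) per conv; "pool" entries are 2x2 max pools
    ("conv1_1", 64), ("conv1_2", 64), ("pool", None),
    ("conv2_1", 128), ("conv2_2", 128), ("pool", None),
    ("conv3_1", 256), ("conv3_2", 256), ("conv3_3", 256), ("pool", None),
    ("conv4_1", 512), ("conv4_2", 512), ("conv4_3", 512), ("pool", None),
    ("conv5_1", 512),
)
DEFAULT_LAYER_SET = ("relu1_1", "relu2_1", "relu3_1", "relu4_1", "relu5_1")


class ContractError(ValueError):
    pass


class DivergenceError(RuntimeError):
    """A loss component became non-finite during training."""


# ---------------------------------------------------------------------------
# weights / report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LossWeights:
    lambda_cyc: float = 10.0
    lambda_feat: float = 1.0
    lambda_sal: float = 1.0

    def __post_init__(self):
        if min(self.lambda_cyc, self.lambda_feat, self.lambda_sal) < 0:
            raise ContractError("loss weights must be non-negative")


@dataclass
class LossReport:
    l_gan_xy: float
    l_gan_yx: float
    l_cyc: float
    l_feat: float
    l_sal: float
    total: float

    def check(self, weights: LossWeights, tol: float = 1e-6) -> None:
        expected = total_loss(self, weights)
        if abs(expected - self.total) > tol * max(1.0, abs(expected)):
            raise ContractError(
                f"LossReport.total={self.total} inconsistent with "
                f"components (expected {expected})"
            )


def total_loss(components: LossReport, weights: LossWeights) -> float:
    vals = [components.l_gan_xy, components.l_gan_yx, components.l_cyc,
            components.l_feat, components.l_sal]
    if not all(np.isfinite(v) for v in vals):
        raise DivergenceError(f"non-finite loss component: {vals}")
    return (components.l_gan_xy + components.l_gan_yx
            + weights.lambda_cyc * components.l_cyc
            + weights.lambda_feat * components.l_feat
            + weights.lambda_sal * components.l_sal)


# ---------------------------------------------------------------------------
# adversarial
# ---------------------------------------------------------------------------

def sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=np.float64)))


def adversarial_loss(d_real, d_fake) -> float:
    """Log-form adversarial value E[log D(y)] + E[log(1 - D(G(x)))].

    Inputs are patch-score probabilities in (0, 1); values exactly 0 or 1 are
    clamped by epsilon.  The discriminator maximizes this value (0 is a
    perfect discriminator's supremum); the generator plays the complement.
    """
    pr = np.clip(np.asarray(d_real, dtype=np.float64), _EPS, 1 - _EPS)
    pf = np.clip(np.asarray(d_fake, dtype=np.float64), _EPS, 1 - _EPS)
    return float(np.mean(np.log(pr)) + np.mean(np.log1p(-pf)))


def lsgan_discriminator_loss(real_scores, fake_scores) -> float:
    """Least-squares variant on raw scores: (D(y)-1)^2 + D(G(x))^2."""
    return float(np.mean((np.asarray(real_scores) - 1.0) ** 2)
                 + np.mean(np.asarray(fake_scores) ** 2))


def lsgan_generator_loss(fake_scores) -> float:
    return float(np.mean((np.asarray(fake_scores) - 1.0) ** 2))


# ---------------------------------------------------------------------------
# cycle consistency
# ---------------------------------------------------------------------------

def cycle_loss(x, x_cycled, y, y_cycled) -> float:
    """Mean absolute reconstruction error, both directions summed."""
    x, x_cycled = np.asarray(x), np.asarray(x_cycled)
    y, y_cycled = np.asarray(y), np.asarray(y_cycled)
    if x.shape != x_cycled.shape or y.shape != y_cycled.shape:
        raise ContractError("cycle_loss shape mismatch")
    return float(np.mean(np.abs(x_cycled - x)) + np.mean(np.abs(y_cycled - y)))


def l1_grad(a, b):
    """d/da of mean |a - b| (elementwise sign / count)."""
    a = np.asarray(a)
    return np.sign(a - b) / a.size


# ---------------------------------------------------------------------------
# global feature consistency
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureExtractorSpec:
    """Frozen perceptual feature extractor (VGG16 topology).

    weights_source is either "seeded-random" (He-initialized from `seed`, no
    download needed) or a path to an ``.npz`` file holding pretrained conv
    weights named conv1_1_w, conv1_1_b, ...
    """

    layer_set: tuple = DEFAULT_LAYER_SET
    weights_source: str = "seeded-random"
    seed: int = 0

    def __post_init__(self):
        if not self.layer_set:
            raise ContractError("layer_set must be non-empty")
        valid = {f"relu{n[4:]}" for n, c in VGG16_TOPOLOGY if c is not None}
        unknown = set(self.layer_set) - valid
        if unknown:
            raise ContractError(f"unknown layers: {sorted(unknown)}")


class FeatureExtractor:
    """VGG16-topology CNN truncated at the deepest requested tap; frozen."""

    def __init__(self, spec: FeatureExtractorSpec):
        self.spec = spec
        taps = set(spec.layer_set)
        rng = np.random.default_rng(spec.seed)
        weights = None
        if spec.weights_source != "seeded-random":
            weights = np.load(spec.weights_source)
        self.layers = []  # (tap_name_or_None, module)
        in_ch = 3
        deepest = max(
            i for i, (n, c) in enumerate(VGG16_TOPOLOGY)
            if c is not None and f"relu{n[4:]}" in taps
        )
        for name, out_ch in VGG16_TOPOLOGY[:deepest + 1]:
            if out_ch is None:
                self.layers.append((None, nn.MaxPool2d(2)))
                continue
            he_std = float(np.sqrt(2.0 / (in_ch * 9)))
            conv = nn.Conv2d(in_ch, out_ch, 3, padding=1, rng=rng,
                             init_std=he_std)
            if weights is not None:
                conv.weight.data[...] = weights[f"{name}_w"]
                conv.bias.data[...] = weights[f"{name}_b"]
            tap = f"relu{name[4:]}"
            self.layers.append((tap if tap in taps else None, conv))
            in_ch = out_ch

    @staticmethod
    def _normalize(x):
        """Model space (-1,1) -> [0,1] -> ImageNet normalization."""
        x01 = (np.asarray(x, dtype=np.float32) + 1.0) * 0.5
        return (x01 - _IMAGENET_MEAN[:, None, None]) / _IMAGENET_STD[:, None, None]

    def forward_taps(self, x):
        """Returns ({tap: feature}, caches) for backprop to the input."""
        h = self._normalize(x)
        feats, caches = {}, []
        relu = nn.ReLU()
        for tap, mod in self.layers:
            h, c = mod.forward(h)
            if isinstance(mod, nn.Conv2d):
                h, rc = relu.forward(h)
                caches.append((mod, c, rc))
            else:
                caches.append((mod, c, None))
            if tap is not None:
                feats[tap] = h
        return feats, caches

    def backward_taps(self, caches, tap_grads):
        """Chain gradients from tap features back to the model-space input."""
        relu = nn.ReLU()
        taps = {tap: g for tap, g in tap_grads.items()}
        dy = None
        for (tap, mod), (mod2, c, rc) in zip(reversed(self.layers),
                                             reversed(caches)):
            if tap is not None and tap in taps:
                dy = taps[tap] if dy is None else dy + taps[tap]
            if dy is None:
                continue
            if rc is not None:
                dy = relu.backward(rc, dy)
            dy = mod.backward(c, dy)
        # undo normalization chain (the frozen extractor's weights keep the
        # gradients they accumulated; callers never step them)
        return dy * (0.5 / _IMAGENET_STD[:, None, None])

    def layer_dims(self, feats):
        return {k: v.shape[1] * v.shape[2] * v.shape[3] for k, v in feats.items()}


def _feat_term(fa: dict, fb: dict, variant: str) -> float:
    total = 0.0
    for k in fa:
        diff = fa[k] - fb[k]
        chw = diff[0].size
        if variant == "l2":
            per_image = (diff.astype(np.float64) ** 2).sum(axis=(1, 2, 3)) / chw
        else:
            per_image = np.abs(diff.astype(np.float64)).sum(axis=(1, 2, 3)) / chw
        total += per_image.mean()
    return total / len(fa)


def feature_loss(x, x_translated, y, y_translated,
                 extractor: FeatureExtractor, variant: str = "l2") -> float:
    """Per-layer feature distance normalized by C*H*W, averaged over the layer
    set, both translation directions summed.  variant="l2" (squared, default)
    or "l1"."""
    fx, _ = extractor.forward_taps(x)
    fxt, _ = extractor.forward_taps(x_translated)
    fy, _ = extractor.forward_taps(y)
    fyt, _ = extractor.forward_taps(y_translated)
    return float(_feat_term(fx, fxt, variant) + _feat_term(fy, fyt, variant))


def feature_loss_direction_grad(source, translated,
                                extractor: FeatureExtractor,
                                variant: str = "l2"):
    """One direction's value and gradient w.r.t. the translated image."""
    fs, _ = extractor.forward_taps(source)
    ft, caches = extractor.forward_taps(translated)
    value = _feat_term(fs, ft, variant)
    n = translated.shape[0]
    grads = {}
    for k in ft:
        diff = ft[k] - fs[k]
        chw = diff[0].size
        if variant == "l2":
            g = 2.0 * diff / chw
        else:
            g = np.sign(diff) / chw
        grads[k] = (g / (n * len(ft))).astype(np.float32)
    dx = extractor.backward_taps(caches, grads)
    return float(value), dx


# ---------------------------------------------------------------------------
# saliency consistency
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SaliencyOperatorSpec:
    """Fixed-threshold saliency operator T: gray >= threshold (bright polarity)
    or inverted first (dark polarity), then 3x3 opening and closing."""

    threshold: int = 170
    polarity: str = "bright"  # "bright" (AF/DAPI) or "dark" (H&E nuclei)

    def __post_init__(self):
        if not 0 <= self.threshold <= 255:
            raise ContractError("threshold must be in [0, 255]")
        if self.polarity not in ("bright", "dark"):
            raise ContractError("polarity must be 'bright' or 'dark'")

    @classmethod
    def for_af(cls, threshold: int = 170):
        return cls(threshold=threshold, polarity="bright")

    @classmethod
    def for_he(cls, threshold: int = 170):
        return cls(threshold=threshold, polarity="dark")


def to_gray255(image) -> np.ndarray:
    """Map an image to a single gray plane on the 0-255 scale.

    Accepts (H, W); (3, H, W) planes (MAF: the DAPI plane, index 0, is used);
    or (H, W, 3) RGB (luminance 0.299R + 0.587G + 0.114B).  uint8 passes
    through; floats in [0, 1] are scaled by 255; floats with negative values
    are treated as model space (-1, 1).
    """
    img = np.asarray(image)
    if img.ndim == 3:
        if img.shape[0] == 3:  # CHW multispectral -> DAPI plane
            img = img[0]
        elif img.shape[-1] == 3:  # HWC RGB -> luminance
            img = (0.299 * img[..., 0] + 0.587 * img[..., 1]
                   + 0.114 * img[..., 2])
        else:
            raise ContractError(f"cannot interpret image shape {img.shape}")
    elif img.ndim != 2:
        raise ContractError(f"cannot interpret image shape {img.shape}")
    img = img.astype(np.float64)
    if img.min() < 0:  # model space (-1, 1)
        img = (img + 1.0) * 127.5
    elif img.max() <= 1.0:
        img = img * 255.0
    return img


def _open_close(mask: np.ndarray) -> np.ndarray:
    # opening then closing; borders treated as same-as-edge (erosion border
    # value 1, dilation 0) so a uniform suprathreshold image stays all ones
    m = ndimage.binary_erosion(mask, _SE3, border_value=1)
    m = ndimage.binary_dilation(m, _SE3, border_value=0)
    m = ndimage.binary_dilation(m, _SE3, border_value=0)
    m = ndimage.binary_erosion(m, _SE3, border_value=1)
    return m


def saliency_map(image, spec: SaliencyOperatorSpec | None = None) -> np.ndarray:
    """Binary saliency mask: closing(opening(threshold(gray)))."""
    spec = spec or SaliencyOperatorSpec()
    gray = to_gray255(image)
    if spec.polarity == "dark":
        gray = 255.0 - gray
    return _open_close(gray >= spec.threshold).astype(np.uint8)


def _batch_masks(batch, spec):
    batch = np.asarray(batch)
    if batch.ndim == 4:
        return np.stack([saliency_map(img, spec) for img in batch])
    return saliency_map(batch, spec)[None]


def saliency_loss(x, x_translated, y, y_translated,
                  spec_alpha: SaliencyOperatorSpec | None = None,
                  spec_beta: SaliencyOperatorSpec | None = None) -> float:
    """Mean absolute difference between source and translated saliency masks,
    both directions summed.  T_alpha acts on domain-X (AF) images, T_beta on
    domain-Y (H&E) images."""
    spec_alpha = spec_alpha or SaliencyOperatorSpec.for_af()
    spec_beta = spec_beta or SaliencyOperatorSpec.for_he()
    ta_x = _batch_masks(x, spec_alpha).astype(np.float64)
    tb_xt = _batch_masks(x_translated, spec_beta).astype(np.float64)
    tb_y = _batch_masks(y, spec_beta).astype(np.float64)
    ta_yt = _batch_masks(y_translated, spec_alpha).astype(np.float64)
    return float(np.mean(np.abs(ta_x - tb_xt)) + np.mean(np.abs(tb_y - ta_yt)))


_LUMA = np.array([0.299, 0.587, 0.114])


def soft_saliency(batch, spec: SaliencyOperatorSpec, temperature: float = 12.0):
    """Differentiable threshold surrogate used only for training gradients.

    Input is an NCHW batch in model space (-1, 1).  Gray level is the first
    plane (bright polarity, AF/DAPI) or RGB luminance (dark polarity, H&E),
    mapped to 0-255; the mask is sigmoid((gray - threshold)/temperature), no
    morphology.  Returns (soft_mask (N,H,W), jac (N,C,H,W)) where
    dL/dmodel[n,c] = dL/dsoft[n] * jac[n,c].
    """
    batch = np.asarray(batch)
    if spec.polarity == "bright":
        gray = (batch[:, 0] + 1.0) * 127.5
        chain = np.zeros_like(batch)
        chain[:, 0] = 127.5
    else:
        gray = 255.0 - np.tensordot(
            (batch + 1.0) * 127.5, _LUMA, axes=([1], [0])
        )
        chain = -127.5 * _LUMA[None, :, None, None] * np.ones_like(batch)
    z = (gray - spec.threshold) / temperature
    s = sigmoid(z)
    jac = (s * (1.0 - s) / temperature)[:, None] * chain
    return s, jac
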