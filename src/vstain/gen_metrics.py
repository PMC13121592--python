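"""Distribution-level image quality metrics: FID and KID, plus the
channel-ablation harness.

Protocol: images are resized to 299 x 299, rescaled to [0, 1], and embedded
by a frozen feature extractor; FID is the Frechet distance between Gaussian
fits of the two embedding clouds, KID the unbiased polynomial-kernel MMD^2
averaged over seeded random subsets, and the whole evaluation is repeated
(5 by default) with distinct seeds to report mean +/- sd.

The reference extractor is an Inception-V3 pool3 layer (2048-dim); because
pretrained weights are an injectable asset, a seeded-random convolutional
embedder is provided as the default so the full protocol runs self-contained.
Absolute FID/KID magnitudes are then extractor-specific; comparisons between
model variants under one extractor remain meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.transform import resize

from . import nn, staining_io


class ContractError(ValueError):
    pass


@dataclass
class EmbeddingSet:
    features: np.ndarray  # (n, d), float64
    extractor_id: str
    preprocessing: dict = field(default_factory=dict)

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.ndim != 2:
            raise ContractError("features must be 2-D (n, d)")
        if not np.isfinite(self.features).all():
            raise ContractError("non-finite embedding values")

    def __len__(self):
        return self.features.shape[0]


@dataclass
class MetricReport:
    fid_mean: float
    fid_sd: float
    kid_mean: float
    kid_sd: float
    n_repeats: int
    n_real: int
    n_generated: int

    def as_dict(self):
        return {
            "fid_mean": self.fid_mean, "fid_sd": self.fid_sd,
            "kid_mean": self.kid_mean, "kid_sd": self.kid_sd,
            "n_repeats": self.n_repeats,
            "n_real": self.n_real, "n_generated": self.n_generated,
        }


# ---------------------------------------------------------------------------
# embedding
# ---------------------------------------------------------------------------

class RandomConvEmbedder:
    """Seeded-random convolutional embedder (frozen, forward only).

    Three strided He-initialized conv stages with ReLU, global average
    pooling, and a fixed random projection to ``dim`` features.  Serves as the
    injectable stand-in for a pretrained pooling-layer extractor.
    """

    def __init__(self, dim: int = 192, seed: int = 0, input_size: int = 299):
        rng = np.random.default_rng(seed)
        self.input_size = input_size
        self.dim = dim
        self.id = f"random-conv-d{dim}-s{seed}"
        chans = [(3, 24, 7, 4), (24, 48, 5, 4), (48, 96, 3, 2)]
        self.layers = []
        for cin, cout, k, s in chans:
            std = float(np.sqrt(2.0 / (cin * k * k)))
            self.layers.append(nn.Conv2d(cin, cout, k, stride=s,
                                         padding=k // 2, rng=rng,
                                         init_std=std))
        self.proj = rng.normal(0, 1 / np.sqrt(2 * 96), size=(2 * 96, dim))

    def __call__(self, batch01: np.ndarray) -> np.ndarray:
        """(N, 3, H, W) in [0, 1] -> (N, dim)."""
        h = (batch01.astype(np.float32) - 0.5) * 2.0
        relu = nn.ReLU()
        for conv in self.layers:
            h, _ = conv.forward(h)
            h, _ = relu.forward(h)
        mean = h.mean(axis=(2, 3))
        sd = h.std(axis=(2, 3))
        return np.concatenate([mean, sd], axis=1) @ self.proj


def _as_batch(images, size: int) -> np.ndarray:
    """Arbitrary (H,W,3)/(3,H,W)/uint8/float images -> (N,3,size,size) [0,1]."""
    out = np.empty((len(images), 3, size, size), dtype=np.float32)
    for i, img in enumerate(images):
        arr = np.asarray(img)
        if arr.dtype == np.uint8:
            arr = arr.astype(np.float32) / 255.0
        if arr.ndim == 2:
            arr = np.stack([arr] * 3, axis=-1)
        if arr.shape[0] == 3 and arr.ndim == 3:
            arr = arr.transpose(1, 2, 0)
        if arr.shape[:2] != (size, size):
            arr = resize(arr, (size, size), order=1, mode="reflect",
                         anti_aliasing=True)
        out[i] = arr.transpose(2, 0, 1)
    return np.clip(out, 0.0, 1.0)


def embed(images, extractor=None) -> EmbeddingSet:
    """Resize -> rescale [0,1] -> frozen extractor -> one feature row/image."""
    if len(images) == 0:
        raise ContractError("empty image set")
    extractor = extractor or RandomConvEmbedder()
    size = getattr(extractor, "input_size", 299)
    batch = _as_batch(images, size)
    feats = []
    for i in range(0, len(batch), 32):
        feats.append(np.asarray(extractor(batch[i:i + 32]), dtype=np.float64))
    return EmbeddingSet(
        np.vstack(feats),
        extractor_id=getattr(extractor, "id", type(extractor).__name__),
        preprocessing={"resize": size, "rescale": "[0,1]"},
    )


# ---------------------------------------------------------------------------
# FID
# ---------------------------------------------------------------------------

def _sqrtm_psd(mat: np.ndarray) -> np.ndarray:
    """Symmetric PSD square root by eigendecomposition, eigenvalues clipped
    at zero."""
    vals, vecs = np.linalg.eigh((mat + mat.T) / 2.0)
    vals = np.clip(vals, 0.0, None)
    return (vecs * np.sqrt(vals)) @ vecs.T


def fid(a: EmbeddingSet, b: EmbeddingSet, jitter: float = 1e-6) -> float:
    """Frechet distance between Gaussian fits:
    ||mu_a - mu_b||^2 + tr(S_a + S_b - 2 (S_a S_b)^{1/2})."""
    if len(a) < 2 or len(b) < 2:
        raise ContractError("need >= 2 embeddings per side")
    fa, fb = a.features, b.features
    mu_a, mu_b = fa.mean(0), fb.mean(0)
    sa = np.cov(fa, rowvar=False)
    sb = np.cov(fb, rowvar=False)
    sa = np.atleast_2d(sa) + jitter * np.eye(fa.shape[1])
    sb = np.atleast_2d(sb) + jitter * np.eye(fb.shape[1])
    # tr sqrt(Sa Sb) via the symmetric similar matrix A Sb A, A = sqrt(Sa)
    root_a = _sqrtm_psd(sa)
    cross = _sqrtm_psd(root_a @ sb @ root_a)
    d2 = float(np.sum((mu_a - mu_b) ** 2)
               + np.trace(sa) + np.trace(sb) - 2.0 * np.trace(cross))
    return max(d2, 0.0)


# ---------------------------------------------------------------------------
# KID
# ---------------------------------------------------------------------------

def _poly_kernel(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    d = x.shape[1]
    return (x @ y.T / d + 1.0) ** 3


def _mmd2_unbiased(x: np.ndarray, y: np.ndarray) -> float:
    m, n = len(x), len(y)
    kxx = _poly_kernel(x, x)
    kyy = _poly_kernel(y, y)
    kxy = _poly_kernel(x, y)
    sum_xx = (kxx.sum() - np.trace(kxx)) / (m * (m - 1))
    sum_yy = (kyy.sum() - np.trace(kyy)) / (n * (n - 1))
    return float(sum_xx + sum_yy - 2.0 * kxy.mean())


def kid(a: EmbeddingSet, b: EmbeddingSet, n_subsets: int = 100,
        subset_size: int | None = None, seed: int = 0) -> tuple:
    """Unbiased polynomial-kernel MMD^2 ((x.y/d + 1)^3) averaged over seeded
    random subsets; returns (mean, sd)."""
    subset_size = subset_size or min(100, len(a), len(b))
    if subset_size < 2:
        raise ContractError("subset_size must be >= 2")
    if subset_size > min(len(a), len(b)):
        raise ContractError("subset_size exceeds a set size")
    rng = np.random.default_rng(seed)
    vals = np.empty(n_subsets)
    for i in range(n_subsets):
        ia = rng.choice(len(a), subset_size, replace=False)
        ib = rng.choice(len(b), subset_size, replace=False)
        vals[i] = _mmd2_unbiased(a.features[ia], b.features[ib])
    return float(vals.mean()), float(vals.std())


# ---------------------------------------------------------------------------
# evaluation protocol
# ---------------------------------------------------------------------------

def _load_dir(path) -> list:
    path = Path(path)
    images = []
    for p in sorted(path.iterdir()):
        if p.suffix.lower() in (".png", ".jpg", ".jpeg"):
            images.append(staining_io.read_rgb(p))
        elif p.suffix.lower() in (".tif", ".tiff"):
            images.append(staining_io.read_maf(p).transpose(1, 2, 0))
    return images


def evaluate_pair(real, generated, extractor=None, n_repeats: int = 5,
                  seed: int = 0, kid_subsets: int = 100,
                  kid_subset_size: int | None = None) -> MetricReport:
    """Full FID/KID protocol between two image sets (or directories).

    Embeddings are computed once (deterministic); the evaluation is repeated
    ``n_repeats`` times with distinct KID subset seeds and the report carries
    mean +/- sd of both metrics.
    """
    if isinstance(real, (str, Path)):
        real = _load_dir(real)
    if isinstance(generated, (str, Path)):
        generated = _load_dir(generated)
    ea = embed(real, extractor)
    eb = embed(generated, extractor)
    fids, kids = [], []
    base = np.random.default_rng(seed).integers(2 ** 31, size=n_repeats)
    for rep_seed in base:
        fids.append(fid(ea, eb))
        km, _ = kid(ea, eb, n_subsets=kid_subsets,
                    subset_size=kid_subset_size, seed=int(rep_seed))
        kids.append(km)
    return MetricReport(
        fid_mean=float(np.mean(fids)), fid_sd=float(np.std(fids)),
        kid_mean=float(np.mean(kids)), kid_sd=float(np.std(kids)),
        n_repeats=n_repeats, n_real=len(ea), n_generated=len(eb),
    )


def relative_improvement(baseline: float, improved: float) -> float:
    """Percentage decrease (baseline - improved) / baseline * 100."""
    return (baseline - improved) / baseline * 100.0


# ---------------------------------------------------------------------------
# channel ablation
# ---------------------------------------------------------------------------

ABLATION_CHANNELS = ("DAPI", "SpGr", "SpOr", "all")


def select_channels(maf: np.ndarray, channel: str) -> np.ndarray:
    """Build a model input from a (3, H, W) MAF patch: the full multispectral
    stack, or a chosen single plane replicated to 3 channels."""
    if channel == "all":
        return maf
    try:
        idx = ("DAPI", "SpGr", "SpOr").index(channel)
    except ValueError:
        raise ContractError(f"unknown channel {channel!r}") from None
    return np.repeat(maf[idx:idx + 1], 3, axis=0)


def linear_readout_fid(channel: str, spec, n_pairs: int = 16,
                       embed_dim: int = 48, embed_seed: int = 0) -> float:
    """Desk-scale ablation closure: FID of a per-pixel affine readout.

    Fits a linear map from the (optionally single-channel-restricted) MAF
    planes to H&E RGB on half of a paired phantom set and scores the FID of
    its predictions on the held-out half.  A fast, deterministic surrogate
    for per-variant adversarial training: a variant whose input channels
    carry less of the latent tissue information cannot reconstruct the
    stain image, and its FID rises accordingly.
    """
    from . import phantom  # deferred: phantom also imports nothing from here

    size = spec.image_size
    mafs, hes = [], []
    for i in range(n_pairs):
        layout = phantom.sample_layout(spec, index=i)
        maf = phantom.render_maf(layout, spec, index=i).planes
        mafs.append(select_channels(maf, channel))
        hes.append(phantom.render_he(layout, spec, index=i).rgb)
    half = n_pairs // 2
    x_train = np.concatenate([m.reshape(3, -1).T for m in mafs[:half]])
    y_train = np.concatenate([h.reshape(-1, 3) for h in hes[:half]])
    design = np.column_stack([x_train, np.ones(len(x_train))])
    coef, *_ = np.linalg.lstsq(design, y_train, rcond=None)
    preds = []
    for m in mafs[half:]:
        d = np.column_stack([m.reshape(3, -1).T, np.ones(size * size)])
        preds.append(np.clip(d @ coef, 0, 1).reshape(size, size, 3))
    extractor = RandomConvEmbedder(dim=embed_dim, seed=embed_seed,
                                   input_size=size)
    return fid(embed(hes[half:], extractor), embed(preds, extractor))


def ablation_harness(run, channels=ABLATION_CHANNELS) -> dict:
    """Run a train+evaluate closure per input-channel variant.

    ``run(channel)`` returns a MetricReport (or any mapping with fid/kid
    fields); the harness returns {channel: report} in Table-style layout.
    """
    results = {}
    for channel in channels:
        if channel not in ABLATION_CHANNELS:
            raise ContractError(f"unknown channel {channel!r}")
        results[channel] = run(channel)
    return results
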