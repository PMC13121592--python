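"""Seeded adversarial training loop for the bidirectional staining model.

Optimization follows the standard unpaired-translation recipe: Adam
(betas 0.5/0.999), initial learning rate 2e-4 held constant for the first 100
epochs then decayed linearly to zero at epoch 200, batch size 4, random
flip/90-degree-rotation augmentation, a 10% held-out validation split, and a
history pool of previously generated images for discriminator updates.

Each step performs one joint generator update (both directions share one
optimizer) followed by one update of each discriminator on detached fakes.
The saliency term's reported value is the exact hard-mask loss; its gradient
flows through a smooth threshold surrogate (see losses.soft_saliency).
"""

from __future__ import annotations

import csv
import hashlib
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from . import losses, networks, nn


class DataError(ValueError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    lr_init: float = 2e-4
    batch_size: int = 4
    epochs_total: int = 200
    epochs_constant: int = 100
    betas: tuple = (0.5, 0.999)
    seed: int = 0
    augment: bool = True
    pool_size: int = 50
    val_fraction: float = 0.10
    weights: losses.LossWeights = field(default_factory=losses.LossWeights)
    adversarial: str = "log"  # "log" (printed form) or "lsgan"
    feature_variant: str = "l2"
    sal_temperature: float = 12.0
    gen_spec: networks.GeneratorSpec = field(
        default_factory=networks.GeneratorSpec)
    disc_spec: networks.DiscriminatorSpec = field(
        default_factory=networks.DiscriminatorSpec)
    extractor_spec: losses.FeatureExtractorSpec | None = field(
        default_factory=losses.FeatureExtractorSpec)
    checkpoint_every: int = 0  # epochs; 0 = final only

    def __post_init__(self):
        if not self.lr_init > 0:
            raise ValueError("lr_init must be > 0")
        if not 0 <= self.val_fraction < 1:
            raise ValueError("val_fraction must be in [0, 1)")
        if self.epochs_constant > self.epochs_total:
            raise ValueError("epochs_constant must be <= epochs_total")
        if self.adversarial not in ("log", "lsgan"):
            raise ValueError("adversarial must be 'log' or 'lsgan'")


@dataclass
class TrainState:
    epoch: int = 0
    step: int = 0
    current_lr: float = 0.0
    history: list = field(default_factory=list)  # LossReport per step
    checkpoint_paths: list = field(default_factory=list)


def lr_schedule(epoch: int, cfg: TrainConfig) -> float:
    """lr_init through epochs_constant, then linear decay to 0 at epochs_total."""
    if not 0 <= epoch <= cfg.epochs_total:
        raise ValueError(f"epoch {epoch} outside [0, {cfg.epochs_total}]")
    if epoch < cfg.epochs_constant:
        return cfg.lr_init
    span = cfg.epochs_total - cfg.epochs_constant
    if span == 0:
        return 0.0
    return cfg.lr_init * (cfg.epochs_total - epoch) / span


def split_validation(n: int, val_fraction: float, rng) -> tuple:
    """Seeded patch-level split; returns (train_idx, val_idx)."""
    idx = rng.permutation(n)
    n_val = int(n * val_fraction)
    return idx[n_val:], idx[:n_val]


class ImagePool:
    """History buffer of generated images; returns the current fake or, with
    probability 1/2 once full, a stored one (swapping it out)."""

    def __init__(self, size: int, rng):
        self.size = size
        self.rng = rng
        self.images: list = []

    def query(self, batch: np.ndarray) -> np.ndarray:
        if self.size == 0:
            return batch
        out = []
        for img in batch:
            if len(self.images) < self.size:
                self.images.append(img.copy())
                out.append(img)
            elif self.rng.random() < 0.5:
                j = self.rng.integers(len(self.images))
                out.append(self.images[j].copy())
                self.images[j] = img.copy()
            else:
                out.append(img)
        return np.stack(out)


# ---------------------------------------------------------------------------
# data loading
# ---------------------------------------------------------------------------

def _to_model_space(arr: np.ndarray) -> np.ndarray:
    return (arr.astype(np.float32) / 127.5) - 1.0


def load_domain(manifest: str | Path, domain: str) -> np.ndarray:
    """Load one domain's patches from a phantom/dataset manifest CSV into an
    (N, 3, H, W) model-space array."""
    manifest = Path(manifest)
    table = pd.read_csv(manifest)
    rows = table[table["domain"] == domain]
    if rows.empty:
        raise DataError(f"no {domain} entries in {manifest}")
    images = []
    for rel in rows["path"]:
        path = manifest.parent / rel
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = np.asarray(Image.open(path))
        if arr.ndim == 3 and arr.shape[-1] == 3 and arr.shape[0] != 3:
            arr = arr.transpose(2, 0, 1)  # HWC -> CHW
        images.append(_to_model_space(arr))
    return np.stack(images)


def _augment_batch(batch: np.ndarray, rng) -> np.ndarray:
    out = np.empty_like(batch)
    for i, img in enumerate(batch):
        k = int(rng.integers(4))
        img = np.rot90(img, k, axes=(1, 2))
        if rng.random() < 0.5:
            img = img[:, :, ::-1]
        if rng.random() < 0.5:
            img = img[:, ::-1, :]
        out[i] = img
    return out


def parameter_digest(model: nn.Module) -> str:
    h = hashlib.sha256()
    for p in model.parameters():
        h.update(np.ascontiguousarray(p.data).tobytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# loss gradients on raw patch scores
# ---------------------------------------------------------------------------

def _gen_adv(scores, variant):
    """Generator-side adversarial loss and d/dscores (non-saturating log
    form, or least squares)."""
    n = scores.size
    if variant == "lsgan":
        return (float(np.mean((scores - 1.0) ** 2)),
                (2.0 * (scores - 1.0) / n).astype(np.float32))
    p = losses.sigmoid(scores)
    p = np.clip(p, losses._EPS, 1 - losses._EPS)
    return (float(-np.mean(np.log(p))),
            (-(1.0 - p) / n).astype(np.float32))


def _disc_adv(real_scores, fake_scores, variant):
    """Discriminator loss (minimized) and gradients w.r.t. both score maps."""
    nr, nf = real_scores.size, fake_scores.size
    if variant == "lsgan":
        loss = losses.lsgan_discriminator_loss(real_scores, fake_scores)
        return (float(loss),
                (2.0 * (real_scores - 1.0) / nr).astype(np.float32),
                (2.0 * fake_scores / nf).astype(np.float32))
    pr = np.clip(losses.sigmoid(real_scores), losses._EPS, 1 - losses._EPS)
    pf = np.clip(losses.sigmoid(fake_scores), losses._EPS, 1 - losses._EPS)
    loss = -(np.mean(np.log(pr)) + np.mean(np.log1p(-pf)))
    return (float(loss),
            (-(1.0 - pr) / nr).astype(np.float32),
            (pf / nf).astype(np.float32))


def _soft_sal_grad(source, translated, spec_src, spec_tr, temperature):
    """Gradient of the smooth saliency surrogate w.r.t. the translation."""
    s_src, _ = losses.soft_saliency(source, spec_src, temperature)
    s_tr, jac = losses.soft_saliency(translated, spec_tr, temperature)
    dsoft = -np.sign(s_src - s_tr) / s_tr.size
    return (dsoft[:, None] * jac).astype(np.float32)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def train(cfg: TrainConfig, af_manifest, he_manifest, out_dir=None,
          max_steps: int | None = None) -> TrainState:
    """Train G_xy (AF->HE), G_yx (HE->AF), D_x, D_y from unpaired manifests.

    Returns the TrainState; writes a per-step CSV loss log and generator
    checkpoints under out_dir when given.  Fully determined by cfg.seed.
    """
    x_all = load_domain(af_manifest, "AF")
    y_all = load_domain(he_manifest, "HE")

    rng = np.random.default_rng(cfg.seed)
    init_rng = np.random.default_rng(rng.integers(2 ** 31))
    g_xy = networks.build_generator(cfg.gen_spec, rng=init_rng)
    g_yx = networks.build_generator(cfg.gen_spec, rng=init_rng)
    d_x = networks.build_discriminator(cfg.disc_spec, rng=init_rng)
    d_y = networks.build_discriminator(cfg.disc_spec, rng=init_rng)
    extractor = (losses.FeatureExtractor(cfg.extractor_spec)
                 if cfg.extractor_spec is not None
                 and cfg.weights.lambda_feat > 0 else None)

    tr_x, _val_x = split_validation(len(x_all), cfg.val_fraction, rng)
    tr_y, _val_y = split_validation(len(y_all), cfg.val_fraction, rng)
    if len(tr_x) == 0 or len(tr_y) == 0:
        raise DataError("empty training split in one domain")
    x_train, y_train = x_all[tr_x], y_all[tr_y]

    opt_g = nn.Adam(g_xy.parameters() + g_yx.parameters(),
                    lr=cfg.lr_init, betas=cfg.betas)
    opt_dx = nn.Adam(d_x.parameters(), lr=cfg.lr_init, betas=cfg.betas)
    opt_dy = nn.Adam(d_y.parameters(), lr=cfg.lr_init, betas=cfg.betas)
    pool_x = ImagePool(cfg.pool_size, np.random.default_rng(rng.integers(2 ** 31)))
    pool_y = ImagePool(cfg.pool_size, np.random.default_rng(rng.integers(2 ** 31)))

    sal_a = losses.SaliencyOperatorSpec.for_af()
    sal_b = losses.SaliencyOperatorSpec.for_he()
    w = cfg.weights

    out_dir = Path(out_dir) if out_dir is not None else None
    log_rows = []
    state = TrainState()
    steps_per_epoch = max(1, math.ceil(min(len(x_train), len(y_train))
                                       / cfg.batch_size))

    def _save(tag):
        if out_dir is None:
            return
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, model in (("g_xy", g_xy), ("g_yx", g_yx)):
            path = out_dir / f"{name}_{tag}.npz"
            networks.save_checkpoint(path, model, cfg.gen_spec)
            state.checkpoint_paths.append(str(path))

    done = False
    for epoch in range(cfg.epochs_total):
        lr = lr_schedule(epoch, cfg)
        opt_g.lr = opt_dx.lr = opt_dy.lr = lr
        state.epoch, state.current_lr = epoch, lr
        for _ in range(steps_per_epoch):
            bx = x_train[rng.integers(len(x_train), size=cfg.batch_size)]
            by = y_train[rng.integers(len(y_train), size=cfg.batch_size)]
            if cfg.augment:
                bx = _augment_batch(bx, rng)
                by = _augment_batch(by, rng)
            report = _train_step(
                bx, by, g_xy, g_yx, d_x, d_y, extractor, pool_x, pool_y,
                opt_g, opt_dx, opt_dy, w, cfg, sal_a, sal_b)
            try:
                report.check(w)
            except losses.DivergenceError:
                _save("diverged_last_good")
                raise
            state.history.append(report)
            log_rows.append(report)
            state.step += 1
            if max_steps is not None and state.step >= max_steps:
                done = True
                break
        if cfg.checkpoint_every and (epoch + 1) % cfg.checkpoint_every == 0:
            _save(f"epoch{epoch + 1:04d}")
        if done:
            break

    _save("final")
    if out_dir is not None:
        with open(out_dir / "loss_log.csv", "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["step", "l_gan_xy", "l_gan_yx", "l_cyc",
                         "l_feat", "l_sal", "total"])
            for i, r in enumerate(log_rows):
                wr.writerow([i, r.l_gan_xy, r.l_gan_yx, r.l_cyc,
                             r.l_feat, r.l_sal, r.total])
    state.models = {"g_xy": g_xy, "g_yx": g_yx, "d_x": d_x, "d_y": d_y}
    return state


def _train_step(bx, by, g_xy, g_yx, d_x, d_y, extractor, pool_x, pool_y,
                opt_g, opt_dx, opt_dy, w, cfg, sal_a, sal_b):
    fake_x, fake_y, s_fx, s_fy, l_cyc, l_feat, l_sal = _generator_update(
        bx, by, g_xy, g_yx, d_x, d_y, extractor, opt_g, w, cfg, sal_a, sal_b)
    l_gan_xy, l_gan_yx = _discriminator_update(
        bx, by, fake_x, fake_y, s_fx, s_fy, d_x, d_y, pool_x, pool_y,
        opt_dx, opt_dy, cfg)
    report = losses.LossReport(
        l_gan_xy=l_gan_xy, l_gan_yx=l_gan_yx, l_cyc=l_cyc,
        l_feat=l_feat, l_sal=l_sal, total=0.0)
    report.total = losses.total_loss(report, w)
    return report


def _generator_update(bx, by, g_xy, g_yx, d_x, d_y, extractor, opt_g, w, cfg,
                      sal_a=None, sal_b=None):
    """One joint update of both generators; discriminator parameters receive
    transient gradients but are restored to zero and never stepped."""
    sal_a = sal_a or losses.SaliencyOperatorSpec.for_af()
    sal_b = sal_b or losses.SaliencyOperatorSpec.for_he()
    fake_y, c_xy = g_xy.forward(bx)
    rec_x, c_yx2 = g_yx.forward(fake_y)
    fake_x, c_yx = g_yx.forward(by)
    rec_y, c_xy2 = g_xy.forward(fake_x)

    s_fy, cd_y = d_y.forward(fake_y)
    s_fx, cd_x = d_x.forward(fake_x)
    _gadv_y, ds_fy = _gen_adv(s_fy, cfg.adversarial)
    _gadv_x, ds_fx = _gen_adv(s_fx, cfg.adversarial)
    d_fake_y = d_y.backward(cd_y, ds_fy)
    d_fake_x = d_x.backward(cd_x, ds_fx)

    l_cyc = losses.cycle_loss(bx, rec_x, by, rec_y)
    g_rec_x = (w.lambda_cyc * losses.l1_grad(rec_x, bx)).astype(np.float32)
    g_rec_y = (w.lambda_cyc * losses.l1_grad(rec_y, by)).astype(np.float32)

    l_feat = 0.0
    if extractor is not None:
        v1, gf_y = losses.feature_loss_direction_grad(
            bx, fake_y, extractor, cfg.feature_variant)
        v2, gf_x = losses.feature_loss_direction_grad(
            by, fake_x, extractor, cfg.feature_variant)
        l_feat = v1 + v2
        d_fake_y = d_fake_y + w.lambda_feat * gf_y
        d_fake_x = d_fake_x + w.lambda_feat * gf_x

    l_sal = losses.saliency_loss(
        (bx + 1) / 2, (fake_y + 1) / 2, (by + 1) / 2, (fake_x + 1) / 2,
        sal_a, sal_b)
    if w.lambda_sal > 0:
        d_fake_y = d_fake_y + w.lambda_sal * _soft_sal_grad(
            bx, fake_y, sal_a, sal_b, cfg.sal_temperature)
        d_fake_x = d_fake_x + w.lambda_sal * _soft_sal_grad(
            by, fake_x, sal_b, sal_a, cfg.sal_temperature)

    # cycle gradients flow through the second generator back to the first
    d_fake_y = d_fake_y + g_yx.backward(c_yx2, g_rec_x)
    d_fake_x = d_fake_x + g_xy.backward(c_xy2, g_rec_y)
    g_xy.backward(c_xy, d_fake_y.astype(np.float32))
    g_yx.backward(c_yx, d_fake_x.astype(np.float32))
    opt_g.step()
    # generator backprop also deposited gradients in the discriminators
    for m in (g_xy, g_yx, d_x, d_y):
        m.zero_grad()
    return fake_x, fake_y, s_fx, s_fy, l_cyc, l_feat, l_sal


def _discriminator_update(bx, by, fake_x, fake_y, s_fx, s_fy, d_x, d_y,
                          pool_x, pool_y, opt_dx, opt_dy, cfg):
    """Update each discriminator on real batches vs detached pooled fakes;
    returns the Eq-form adversarial values on the current batch."""
    s_ry, c_ry = d_y.forward(by)
    s_fy2, c_fy2 = d_y.forward(pool_y.query(fake_y))
    _dl_y, g_ry, g_fy = _disc_adv(s_ry, s_fy2, cfg.adversarial)
    d_y.backward(c_ry, g_ry)
    d_y.backward(c_fy2, g_fy)
    opt_dy.step()
    d_y.zero_grad()

    s_rx, c_rx = d_x.forward(bx)
    s_fx2, c_fx2 = d_x.forward(pool_x.query(fake_x))
    _dl_x, g_rx, g_fx = _disc_adv(s_rx, s_fx2, cfg.adversarial)
    d_x.backward(c_rx, g_rx)
    d_x.backward(c_fx2, g_fx)
    opt_dx.step()
    d_x.zero_grad()

    # Eq-form adversarial values on the current batch, for the report
    l_gan_xy = losses.adversarial_loss(losses.sigmoid(s_ry),
                                       losses.sigmoid(s_fy))
    l_gan_yx = losses.adversarial_loss(losses.sigmoid(s_rx),
                                       losses.sigmoid(s_fx))
    return l_gan_xy, l_gan_yx
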