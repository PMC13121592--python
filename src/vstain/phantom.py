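"""Synthetic tissue phantoms: co-registered MAF and H&E-style patches.

A shared latent layout (random nuclear ellipses over a band-limited stromal
field) is rendered twice — once as a three-channel autofluorescence patch
(DAPI: bright nuclei; SpGr/SpOr: diffuse cytoplasmic/stromal signal with
distinct gains) and once as an H&E patch via Beer-Lambert composition of a
hematoxylin-like absorber on nuclei and an eosin-like absorber on stroma.
Because both renders derive from one layout, paired phantoms provide exact
ground truth (identity registration, known nucleus masks, invertible optical
densities) for every downstream evaluation statistic.

The generator is deliberately schematic: it emulates contrast relationships
between the domains, not scanner optics or real histology texture.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image
from scipy import ndimage

from . import stains

CHANNEL_NAMES = ("DAPI", "SpGr", "SpOr")


class PhantomError(ValueError):
    """Invalid phantom specification or layout/spec mismatch."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic tissue generator.

    nucleus_axes is (mean_major, mean_minor, sd) in pixels for the ellipse
    semi-axes; pleomorphism scales the axis/orientation variability;
    stroma_texture is (smoothness_sigma_px, amplitude in [0, 1]).
    """

    image_size: int = 128
    nuclei_rate: float = 18.0
    nucleus_axes: tuple[float, float, float] = (7.0, 5.0, 1.2)
    pleomorphism: float = 1.0
    stroma_texture: tuple[float, float] = (6.0, 0.9)
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 64:
            raise PhantomError("image_size must be >= 64")
        if not self.nuclei_rate > 0:
            raise PhantomError("nuclei_rate must be > 0")
        if self.noise_sd < 0:
            raise PhantomError("noise_sd must be >= 0")


@dataclass
class TissueLayout:
    """Latent geometry shared by the MAF and H&E renders of one patch."""

    image_size: int
    nuclei: list  # (center_rc, semi_axes, orientation_rad)
    stroma_field: np.ndarray  # (H, W) in [0, 1]
    nucleus_mask: np.ndarray  # (H, W) bool


@dataclass
class MultispectralPatch:
    """3-plane MAF patch, planes ordered (DAPI, SpGr, SpOr), values in [0,1]."""

    planes: np.ndarray
    channel_names: tuple = CHANNEL_NAMES

    def to_uint8(self) -> np.ndarray:
        return np.clip(np.rint(self.planes * 255), 0, 255).astype(np.uint8)


@dataclass
class StainPatch:
    """RGB H&E-style patch, values in [0, 1], shape (H, W, 3)."""

    rgb: np.ndarray

    def to_uint8(self) -> np.ndarray:
        return np.clip(np.rint(self.rgb * 255), 0, 255).astype(np.uint8)


def _patch_rng(spec: PhantomSpec, index: int) -> np.random.Generator:
    # one global seed; per-patch streams derived by counter
    return np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(index,)))


def sample_layout(spec: PhantomSpec, index: int = 0) -> TissueLayout:
    """Draw a tissue layout: Poisson nucleus count, packed random ellipses,
    band-limited stromal field.  Deterministic for (spec, index)."""
    rng = _patch_rng(spec, index)
    size = spec.image_size
    n = int(rng.poisson(spec.nuclei_rate))
    mean_major, mean_minor, sd = spec.nucleus_axes
    sd = sd * spec.pleomorphism
    min_dist = mean_major  # reject centers within ~1 nuclear radius

    nuclei = []
    centers = np.empty((0, 2))
    for _ in range(n):
        for _attempt in range(100):
            c = rng.uniform(0, size, size=2)
            if centers.size == 0 or np.min(
                np.hypot(*(centers - c).T)
            ) >= min_dist:
                break
        a = max(2.0, rng.normal(mean_major, sd))
        b = max(1.5, min(a, rng.normal(mean_minor, sd)))
        theta = rng.uniform(0, np.pi) * min(1.0, spec.pleomorphism + 0.5)
        nuclei.append((tuple(c), (a, b), theta))
        centers = np.vstack([centers, c])

    sigma, amplitude = spec.stroma_texture
    noise = rng.normal(size=(size, size))
    smooth = ndimage.gaussian_filter(noise, sigma)
    rngv = smooth.max() - smooth.min()
    stroma = (smooth - smooth.min()) / rngv if rngv > 0 else np.zeros_like(smooth)
    stroma = np.clip(stroma * amplitude, 0.0, 1.0)

    mask = _rasterize(nuclei, size)
    return TissueLayout(size, nuclei, stroma, mask)


def _rasterize(nuclei, size: int) -> np.ndarray:
    mask = np.zeros((size, size), dtype=bool)
    for (cr, cc), (a, b), theta in nuclei:
        r0 = max(0, int(cr - a - 1))
        r1 = min(size, int(cr + a + 2))
        c0 = max(0, int(cc - a - 1))
        c1 = min(size, int(cc + a + 2))
        if r0 >= r1 or c0 >= c1:
            continue
        rr, cc_ = np.mgrid[r0:r1, c0:c1]
        dr, dc = rr - cr, cc_ - cc
        ct, st = np.cos(theta), np.sin(theta)
        u = dr * ct + dc * st
        v = -dr * st + dc * ct
        mask[r0:r1, c0:c1] |= (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return mask


def _check_sizes(layout: TissueLayout, spec: PhantomSpec) -> None:
    if layout.image_size != spec.image_size:
        raise PhantomError(
            f"layout size {layout.image_size} != spec size {spec.image_size}"
        )


def _soft_mask(mask: np.ndarray) -> np.ndarray:
    return ndimage.gaussian_filter(mask.astype(float), 0.7)


def render_maf(layout: TissueLayout, spec: PhantomSpec,
               index: int = 0) -> MultispectralPatch:
    """Render the autofluorescence domain: DAPI tracks the nucleus mask,
    SpGr/SpOr track the stromal field with distinct gains."""
    _check_sizes(layout, spec)
    soft = _soft_mask(layout.nucleus_mask)
    stroma = layout.stroma_field
    dapi = 0.08 + 0.85 * soft
    spgr = 0.12 + 0.62 * stroma * (1.0 - 0.55 * soft)
    spor = 0.10 + 0.50 * stroma * (1.0 - 0.35 * soft) + 0.06 * soft
    planes = np.stack([dapi, spgr, spor])
    if spec.noise_sd > 0:
        rng = _patch_rng(spec, index + 1_000_003)
        planes = planes + rng.normal(0, spec.noise_sd, planes.shape)
    return MultispectralPatch(np.clip(planes, 0.0, 1.0))


def render_he(layout: TissueLayout, spec: PhantomSpec,
              index: int = 0) -> StainPatch:
    """Render the H&E domain by Beer-Lambert absorption: hematoxylin on
    nuclei (dark blue-violet), eosin on stroma (pink), white background."""
    _check_sizes(layout, spec)
    soft = _soft_mask(layout.nucleus_mask)
    stroma = layout.stroma_field
    conc_h = 0.95 * soft + 0.04 * stroma
    conc_e = 0.55 * stroma * (1.0 - 0.55 * soft) + 0.10 * soft
    conc = np.stack([conc_h, conc_e, np.zeros_like(conc_h)], axis=-1)
    rgb = stains.rgb_from_concentrations(conc)
    if spec.noise_sd > 0:
        rng = _patch_rng(spec, index + 2_000_003)
        rgb = rgb + rng.normal(0, spec.noise_sd, rgb.shape)
    return StainPatch(np.clip(rgb, 0.0, 1.0))


def make_dataset(spec: PhantomSpec, out_dir, n_x: int, n_y: int,
                 paired: bool = False) -> pd.DataFrame:
    """Write n_x MAF patches (3-plane TIFF) and n_y H&E patches (PNG) plus a
    CSV manifest (columns: path, domain, layout_id).

    Unpaired mode draws the two domains from disjoint layouts; paired mode
    reuses layout i for AF_i and HE_i (evaluation oracles only).
    """
    if n_x < 1 or n_y < 1:
        raise PhantomError("n_x and n_y must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(n_x):
        layout = sample_layout(spec, index=i)
        patch = render_maf(layout, spec, index=i)
        path = out_dir / f"af_{i:04d}.tiff"
        tifffile.imwrite(path, patch.to_uint8(), photometric="minisblack")
        rows.append({"path": path.name, "domain": "AF", "layout_id": i})
    for j in range(n_y):
        layout_id = j if paired else n_x + j
        layout = sample_layout(spec, index=layout_id)
        patch = render_he(layout, spec, index=layout_id)
        path = out_dir / f"he_{j:04d}.png"
        Image.fromarray(patch.to_uint8()).save(path)
        rows.append({"path": path.name, "domain": "HE", "layout_id": layout_id})
    manifest = pd.DataFrame(rows, columns=["path", "domain", "layout_id"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
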