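"""Generators and discriminators of the bidirectional translation system.

The generator is the residual encoder-decoder used throughout unpaired
image-to-image translation: a 7x7 stem to ``base_width`` channels, two
stride-2 downsampling stages (2x, 4x width), ``n_residual`` residual blocks at
4x width, two transposed-convolution upsampling stages, and a 7x7 head with
Tanh.  Instance normalization and reflection padding throughout.

The discriminator is a PatchGAN: a stack of stride-2 4x4 convolutions whose
raw N x N output scores local windows (70 x 70 receptive field for the
default 64-128-256-512 spec).  No terminal squashing — the loss module decides
between the log form and least squares.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn


class SpecError(ValueError):
    pass


@dataclass(frozen=True)
class GeneratorSpec:
    in_channels: int = 3
    out_channels: int = 3
    base_width: int = 64
    n_residual: int = 9
    norm: str = "instance"

    def __post_init__(self):
        if self.base_width <= 0:
            raise SpecError("base_width must be > 0")
        if self.n_residual < 0:
            raise SpecError("n_residual must be >= 0")
        if self.norm != "instance":
            raise SpecError("only instance normalization is supported")


@dataclass(frozen=True)
class DiscriminatorSpec:
    in_channels: int = 3
    widths: tuple = (64, 128, 256, 512)
    norm: bool = True  # instance norm after all but the first stage; note
    # that its global spatial statistics make patch scores weakly depend on
    # the whole image — strict receptive-field locality holds with norm=False

    def __post_init__(self):
        if len(self.widths) < 2 or any(
            b <= a for a, b in zip(self.widths, self.widths[1:])
        ):
            raise SpecError("widths must be strictly increasing")

    @property
    def receptive_field(self) -> int:
        """Receptive field of one patch score (k=4 stack, stride 2 except the
        last learned stage and the 1-channel head)."""
        rf, jump = 1, 1
        for stride in self._strides():
            rf += 3 * jump
            jump *= stride
        return rf

    def _strides(self):
        n = len(self.widths)
        return [2] * (n - 1) + [1, 1]  # widths stages + final 1-ch head


class _ResidualBlock(nn.Module):
    """Two reflection-padded 3x3 convs with instance norm; additive skip."""

    def __init__(self, width, rng, dtype=np.float32):
        self.body = nn.Sequential(
            nn.ReflectionPad2d(1),
            nn.Conv2d(width, width, 3, rng=rng, dtype=dtype),
            nn.InstanceNorm2d(width),
            nn.ReLU(),
            nn.ReflectionPad2d(1),
            nn.Conv2d(width, width, 3, rng=rng, dtype=dtype),
            nn.InstanceNorm2d(width),
        )

    def forward(self, x):
        y, cache = self.body.forward(x)
        return x + y, cache

    def backward(self, cache, dy):
        return dy + self.body.backward(cache, dy)


class Generator(nn.Module):
    def __init__(self, spec: GeneratorSpec, rng=None, dtype=np.float32):
        self.spec = spec
        rng = rng or np.random.default_rng(0)
        w = spec.base_width
        layers = [
            nn.ReflectionPad2d(3),
            nn.Conv2d(spec.in_channels, w, 7, rng=rng, dtype=dtype),
            nn.InstanceNorm2d(w),
            nn.ReLU(),
            nn.Conv2d(w, 2 * w, 3, stride=2, padding=1, rng=rng, dtype=dtype),
            nn.InstanceNorm2d(2 * w),
            nn.ReLU(),
            nn.Conv2d(2 * w, 4 * w, 3, stride=2, padding=1, rng=rng, dtype=dtype),
            nn.InstanceNorm2d(4 * w),
            nn.ReLU(),
        ]
        self.residual_blocks = [
            _ResidualBlock(4 * w, rng, dtype) for _ in range(spec.n_residual)
        ]
        layers += self.residual_blocks
        layers += [
            nn.ConvTranspose2d(4 * w, 2 * w, 3, stride=2, padding=1,
                               output_padding=1, rng=rng, dtype=dtype),
            nn.InstanceNorm2d(2 * w),
            nn.ReLU(),
            nn.ConvTranspose2d(2 * w, w, 3, stride=2, padding=1,
                               output_padding=1, rng=rng, dtype=dtype),
            nn.InstanceNorm2d(w),
            nn.ReLU(),
            nn.ReflectionPad2d(3),
            nn.Conv2d(w, spec.out_channels, 7, rng=rng, dtype=dtype),
            nn.Tanh(),
        ]
        self.net = nn.Sequential(*layers)

    def forward(self, x):
        if x.ndim != 4 or x.shape[1] != self.spec.in_channels:
            raise SpecError(
                f"expected (N,{self.spec.in_channels},H,W), got {x.shape}"
            )
        if x.shape[2] % 4 or x.shape[3] % 4:
            raise SpecError("input H and W must be divisible by 4")
        return self.net.forward(x)

    def backward(self, cache, dy):
        return self.net.backward(cache, dy)

    def translate(self, x):
        """Inference-only forward; drops the cache."""
        return self.forward(x)[0]


class Discriminator(nn.Module):
    def __init__(self, spec: DiscriminatorSpec, rng=None, dtype=np.float32):
        self.spec = spec
        rng = rng or np.random.default_rng(0)
        widths = spec.widths
        layers = [
            nn.Conv2d(spec.in_channels, widths[0], 4, stride=2, padding=1,
                      rng=rng, dtype=dtype),
            nn.LeakyReLU(0.2),
        ]
        for w_in, w_out in zip(widths[:-1], widths[1:-1]):
            layers.append(nn.Conv2d(w_in, w_out, 4, stride=2, padding=1,
                                    rng=rng, dtype=dtype))
            if spec.norm:
                layers.append(nn.InstanceNorm2d(w_out))
            layers.append(nn.LeakyReLU(0.2))
        layers.append(nn.Conv2d(widths[-2], widths[-1], 4, stride=1,
                                padding=1, rng=rng, dtype=dtype))
        if spec.norm:
            layers.append(nn.InstanceNorm2d(widths[-1]))
        layers += [
            nn.LeakyReLU(0.2),
            nn.Conv2d(widths[-1], 1, 4, stride=1, padding=1, rng=rng,
                      dtype=dtype),
        ]
        self.net = nn.Sequential(*layers)

    def forward(self, x):
        if min(x.shape[2], x.shape[3]) < self.spec.receptive_field:
            raise SpecError(
                f"input smaller than receptive field "
                f"{self.spec.receptive_field}"
            )
        return self.net.forward(x)

    def backward(self, cache, dy):
        return self.net.backward(cache, dy)

    def score_map(self, x):
        """Raw N x N patch realism scores (PatchScoreMap)."""
        return self.forward(x)[0][:, 0]


def build_generator(spec: GeneratorSpec, rng=None) -> Generator:
    return Generator(spec, rng=rng)


def build_discriminator(spec: DiscriminatorSpec, rng=None) -> Discriminator:
    return Discriminator(spec, rng=rng)


# -- checkpointing ---------------------------------------------------------

def save_checkpoint(path, model: nn.Module, spec) -> None:
    arrays = {f"p{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, _spec=json.dumps(asdict(spec)), **arrays)


def load_generator(path) -> Generator:
    with np.load(Path(path), allow_pickle=False) as data:
        raw = json.loads(str(data["_spec"]))
        raw["widths"] = raw.get("widths")
        spec = GeneratorSpec(**{k: (tuple(v) if isinstance(v, list) else v)
                                for k, v in raw.items() if v is not None})
        gen = Generator(spec)
        gen.load_state_arrays([data[f"p{i}"]
                               for i in range(len(gen.parameters()))])
    return gen
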