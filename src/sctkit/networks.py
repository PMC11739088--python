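"""Generators and discriminators for the unpaired MR<->CT translation GAN.

Two interchangeable generator variants sit behind one contract (1-channel
grid in [-1, 1] in, same-shape 1-channel grid in [-1, 1] out):

* ``resnet_baseline`` — the classic residual encoder-decoder generator of
  unpaired image translation (7x7 stem/head, two stride-2 downsamplings,
  residual blocks, learned upsampling), with instance normalisation.
* ``swin_unetr_2d`` — a U-shaped encoder-decoder whose stages are shifted-
  window multi-head self-attention blocks (layer-normalised), wrapped by an
  extra 7x7 convolution before and after the attention body.  Window
  attention alternates between unshifted and half-window-shifted partitions
  with the standard cyclic-shift attention mask.

The discriminator is a patch discriminator: a small strided conv stack whose
output is a spatial map of real/fake scores with no output nonlinearity
(least-squares adversarial objective).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np

from . import nn
from .nn import Tensor
from .nn.functional import softmax

__all__ = [
    "GeneratorSpec",
    "DiscriminatorSpec",
    "build_generator",
    "build_discriminator",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class GeneratorSpec:
    variant: str = "swin_unetr_2d"
    stem_kernel: int = 7
    head_kernel: int = 7
    embed_dim: int = 24
    depths: Tuple[int, ...] = (2, 2, 2)
    heads: Tuple[int, ...] = (2, 4, 8)
    window_size: int = 4
    patch_size: int = 2
    base_width: int = 16  # resnet variant channel width
    n_res_blocks: int = 4

    def validate(self) -> None:
        if self.variant not in ("swin_unetr_2d", "resnet_baseline"):
            raise ValueError(f"unknown generator variant {self.variant!r}")
        if self.stem_kernel % 2 == 0 or self.head_kernel % 2 == 0:
            raise ValueError("stem/head kernels must be odd")
        if len(self.depths) != len(self.heads):
            raise ValueError("depths and heads must have equal length")
        for i, h in enumerate(self.heads):
            if (self.embed_dim * 2**i) % h:
                raise ValueError("stage dim must be divisible by its head count")


@dataclass(frozen=True)
class DiscriminatorSpec:
    base_width: int = 16
    n_layers: int = 3
    kernel: int = 5

    @property
    def receptive_field(self) -> int:
        # two stride-1 convs on top of n stride-2 convs
        r = 1
        for _ in range(2):
            r = r + (self.kernel - 1)
        for _ in range(self.n_layers):
            r = r * 2 + (self.kernel - 2)
        return r

    def validate(self) -> None:
        if self.n_layers < 1 or self.base_width < 1:
            raise ValueError("invalid discriminator spec")
        if self.kernel % 2 == 0:
            raise ValueError("kernel must be odd")


# --------------------------------------------------------------------------
# shifted-window attention
# --------------------------------------------------------------------------

def _shift_mask(h: int, w: int, ws: int, shift: int) -> np.ndarray:
    """Additive attention mask for cyclic-shifted windows, (n_windows, T, T)."""
    img = np.zeros((h, w))
    cnt = 0
    for hs in (slice(0, -ws), slice(-ws, -shift), slice(-shift, None)):
        for wsl in (slice(0, -ws), slice(-ws, -shift), slice(-shift, None)):
            img[hs, wsl] = cnt
            cnt += 1
    win = img.reshape(h // ws, ws, w // ws, ws).transpose(0, 2, 1, 3).reshape(-1, ws * ws)
    return np.where(win[:, None, :] != win[:, :, None], -100.0, 0.0).astype(np.float32)


class WindowAttention(nn.Module):
    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        self.dim = dim
        self.heads = heads
        self.qkv = nn.Linear(dim, 3 * dim, rng=rng)
        self.proj = nn.Linear(dim, dim, rng=rng)

    def forward(self, xw: Tensor, mask: Optional[np.ndarray]) -> Tensor:
        # xw: (B*nw, T, C)
        bnw, t, c = xw.shape
        hd = c // self.heads
        qkv = self.qkv(xw).reshape((bnw, t, 3, self.heads, hd)).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]  # (bnw, heads, T, hd)
        attn = (q @ k.transpose(0, 1, 3, 2)) * (hd**-0.5)
        if mask is not None:
            nw = mask.shape[0]
            attn = attn.reshape((bnw // nw, nw, self.heads, t, t)) + mask[None, :, None]
            attn = attn.reshape((bnw, self.heads, t, t))
        attn = softmax(attn, axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape((bnw, t, c))
        return self.proj(out)


class SwinBlock(nn.Module):
    """LN -> windowed MHSA (optionally shifted) -> LN -> MLP, with residuals."""

    def __init__(self, dim: int, heads: int, window: int, shifted: bool, rng: np.random.Generator):
        self.window = window
        self.shifted = shifted
        self.norm1 = nn.LayerNorm(dim)
        self.attn = WindowAttention(dim, heads, rng)
        self.norm2 = nn.LayerNorm(dim)
        self.mlp = nn.Sequential(nn.Linear(dim, 4 * dim, rng=rng), nn.GELU(), nn.Linear(4 * dim, dim, rng=rng))
        self._mask_cache: Dict[Tuple[int, int], np.ndarray] = {}

    def _partition(self, x: Tensor) -> Tensor:
        b, h, w, c = x.shape
        ws = self.window
        y = x.reshape((b, h // ws, ws, w // ws, ws, c)).transpose(0, 1, 3, 2, 4, 5)
        return y.reshape((b * (h // ws) * (w // ws), ws * ws, c))

    def _merge(self, xw: Tensor, b: int, h: int, w: int, c: int) -> Tensor:
        ws = self.window
        y = xw.reshape((b, h // ws, w // ws, ws, ws, c)).transpose(0, 1, 3, 2, 4, 5)
        return y.reshape((b, h, w, c))

    def forward(self, x: Tensor) -> Tensor:
        b, h, w, c = x.shape
        ws = self.window
        if h % ws or w % ws:
            raise ValueError(f"feature map {h}x{w} not divisible by window {ws}")
        shift = ws // 2 if self.shifted else 0
        y = self.norm1(x)
        if shift:
            y = y.roll((-shift, -shift), axis=(1, 2))
            key = (h, w)
            if key not in self._mask_cache:
                self._mask_cache[key] = _shift_mask(h, w, ws, shift)
            mask = self._mask_cache[key]
        else:
            mask = None
        y = self.attn(self._partition(y), mask)
        y = self._merge(y, b, h, w, c)
        if shift:
            y = y.roll((shift, shift), axis=(1, 2))
        x = x + y
        return x + self.mlp(self.norm2(x))


class PatchMerging(nn.Module):
    def __init__(self, dim: int, rng: np.random.Generator):
        self.norm = nn.LayerNorm(4 * dim)
        self.reduce = nn.Linear(4 * dim, 2 * dim, bias=False, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        b, h, w, c = x.shape
        y = x.reshape((b, h // 2, 2, w // 2, 2, c)).transpose(0, 1, 3, 2, 4, 5)
        y = y.reshape((b, h // 2, w // 2, 4 * c))
        return self.reduce(self.norm(y))


class SwinUNetGenerator(nn.Module):
    """7x7 conv stem/head around a shifted-window-attention U-net."""

    def __init__(self, spec: GeneratorSpec, rng: np.random.Generator):
        self.spec = spec
        e = spec.embed_dim
        self.stem = nn.Conv2d(1, e, spec.stem_kernel, rng=rng)
        self.embed = nn.Conv2d(e, e, 3, stride=spec.patch_size, rng=rng)
        self.stages = []
        self.merges = []
        n = len(spec.depths)
        for i, depth in enumerate(spec.depths):
            dim = e * 2**i
            blocks = [
                SwinBlock(dim, spec.heads[i], spec.window_size, shifted=(d % 2 == 1), rng=rng)
                for d in range(depth)
            ]
            self.stages.append(blocks)
            if i < n - 1:
                self.merges.append(PatchMerging(dim, rng))
        self.up_proj = []
        self.fuse = []
        self.dec_blocks = []
        for i in range(n - 2, -1, -1):
            dim = e * 2**i
            self.up_proj.append(nn.Linear(2 * dim, dim, rng=rng))
            self.fuse.append(nn.Linear(2 * dim, dim, rng=rng))
            self.dec_blocks.append(SwinBlock(dim, spec.heads[i], spec.window_size, shifted=False, rng=rng))
        self.out_conv = nn.Conv2d(2 * e, e, 3, rng=rng)
        self.head = nn.Conv2d(e, 1, spec.head_kernel, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        spec = self.spec
        h, w = x.shape[-2:]
        side = min(h, w) // spec.patch_size // 2 ** (len(spec.depths) - 1)
        if side < spec.window_size or side % spec.window_size:
            raise ValueError(
                f"input {h}x{w} incompatible with patch {spec.patch_size}, "
                f"{len(spec.depths)} stages and window {spec.window_size}"
            )
        s = self.stem(x).relu()
        t = self.embed(s).transpose(0, 2, 3, 1)  # tokens (B, H', W', C)
        skips = []
        for i, blocks in enumerate(self.stages):
            for blk in blocks:
                t = blk(t)
            if i < len(self.stages) - 1:
                skips.append(t)
                t = self.merges[i](t)
        for j, i in enumerate(range(len(self.stages) - 2, -1, -1)):
            t = nn.upsample2x_tokens(t)
            t = self.up_proj[j](t)
            t = self.fuse[j](nn.concat([t, skips[i]], axis=-1))
            t = self.dec_blocks[j](t)
        f = t.transpose(0, 3, 1, 2)
        for _ in range(int(np.log2(spec.patch_size))):
            f = nn.upsample2x_nchw(f)
        f = nn.concat([f, s], axis=1)
        f = self.out_conv(f).relu()
        return self.head(f).tanh()


class ResidualBlock(nn.Module):
    def __init__(self, dim: int, rng: np.random.Generator):
        self.conv1 = nn.Conv2d(dim, dim, 3, rng=rng)
        self.norm1 = nn.InstanceNorm2d(dim)
        self.conv2 = nn.Conv2d(dim, dim, 3, rng=rng)
        self.norm2 = nn.InstanceNorm2d(dim)

    def forward(self, x: Tensor) -> Tensor:
        y = self.norm1(self.conv1(x)).relu()
        return x + self.norm2(self.conv2(y))


class ResnetGenerator(nn.Module):
    """Original unpaired-translation generator: 7x7 stem, two stride-2
    downsamplings, residual blocks, nearest-upsample decoding, 7x7 head."""

    def __init__(self, spec: GeneratorSpec, rng: np.random.Generator):
        self.spec = spec
        wdt = spec.base_width
        self.stem = nn.Conv2d(1, wdt, spec.stem_kernel, rng=rng)
        self.stem_norm = nn.InstanceNorm2d(wdt)
        self.down = [
            nn.Conv2d(wdt, 2 * wdt, 3, stride=2, rng=rng), nn.InstanceNorm2d(2 * wdt),
            nn.Conv2d(2 * wdt, 4 * wdt, 3, stride=2, rng=rng), nn.InstanceNorm2d(4 * wdt),
        ]
        self.blocks = [ResidualBlock(4 * wdt, rng) for _ in range(spec.n_res_blocks)]
        self.up = [
            nn.Conv2d(4 * wdt, 2 * wdt, 3, rng=rng), nn.InstanceNorm2d(2 * wdt),
            nn.Conv2d(2 * wdt, wdt, 3, rng=rng), nn.InstanceNorm2d(wdt),
        ]
        self.head = nn.Conv2d(wdt, 1, spec.head_kernel, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        y = self.stem_norm(self.stem(x)).relu()
        for conv, norm in zip(self.down[0::2], self.down[1::2]):
            y = norm(conv(y)).relu()
        for blk in self.blocks:
            y = blk(y)
        for conv, norm in zip(self.up[0::2], self.up[1::2]):
            y = norm(conv(nn.upsample2x_nchw(y))).relu()
        return self.head(y).tanh()


class PatchDiscriminator(nn.Module):
    def __init__(self, spec: DiscriminatorSpec, rng: np.random.Generator):
        self.spec = spec
        k, wdt = spec.kernel, spec.base_width
        layers = [nn.Conv2d(1, wdt, k, stride=2, rng=rng), nn.LeakyReLU(0.2)]
        ch = wdt
        for _ in range(spec.n_layers - 1):
            layers += [nn.Conv2d(ch, 2 * ch, k, stride=2, rng=rng), nn.InstanceNorm2d(2 * ch), nn.LeakyReLU(0.2)]
            ch *= 2
        layers += [nn.Conv2d(ch, 2 * ch, k, rng=rng), nn.InstanceNorm2d(2 * ch), nn.LeakyReLU(0.2)]
        self.body = nn.Sequential(*layers)
        self.score = nn.Conv2d(2 * ch, 1, k, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        if min(x.shape[-2:]) < 2 ** self.spec.n_layers * 2:
            raise ValueError(
                f"input {x.shape[-2:]} smaller than the discriminator's receptive footprint"
            )
        return self.score(self.body(x))


def build_generator(spec: GeneratorSpec, seed: int = 0) -> nn.Module:
    """Instantiate a generator with reproducible N(0, 0.02) initialisation."""
    spec.validate()
    rng = np.random.default_rng(seed)
    if spec.variant == "resnet_baseline":
        return ResnetGenerator(spec, rng)
    return SwinUNetGenerator(spec, rng)


def build_discriminator(spec: DiscriminatorSpec, seed: int = 0) -> nn.Module:
    spec.validate()
    return PatchDiscriminator(spec, np.random.default_rng(seed))


# --------------------------------------------------------------------------
# checkpoints: weights and spec serialized together
# --------------------------------------------------------------------------

def save_checkpoint(path: str | Path, models: Dict[str, nn.Module],
                    specs: Dict[str, object], meta: Optional[dict] = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for mname, model in models.items():
        for pname, arr in model.state_dict().items():
            arrays[f"{mname}::{pname}"] = arr
    header = {
        "specs": {k: {"class": type(v).__name__, "fields": asdict(v)} for k, v in specs.items()},
        "meta": meta or {},
    }
    np.savez(path, __header__=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8), **arrays)
    return path


def load_checkpoint(path: str | Path):
    """Rebuild models from a checkpoint; returns (models, specs, meta)."""
    with np.load(path if str(path).endswith(".npz") else str(path)) as z:
        header = json.loads(bytes(z["__header__"]).decode())
        arrays = {k: z[k] for k in z.files if k != "__header__"}
    spec_classes = {"GeneratorSpec": GeneratorSpec, "DiscriminatorSpec": DiscriminatorSpec}
    specs = {}
    for k, sv in header["specs"].items():
        fields = {
            key: tuple(v) if isinstance(v, list) else v for key, v in sv["fields"].items()
        }
        specs[k] = spec_classes[sv["class"]](**fields)
    models: Dict[str, nn.Module] = {}
    for k, spec in specs.items():
        if isinstance(spec, GeneratorSpec):
            models[k] = build_generator(spec)
        else:
            models[k] = build_discriminator(spec)
        state = {
            pname.split("::", 1)[1]: arr
            for pname, arr in arrays.items()
            if pname.startswith(k + "::")
        }
        models[k].load_state_dict(state)
    return models, specs, header["meta"]
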