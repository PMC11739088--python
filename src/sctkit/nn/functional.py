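"""Differentiable counterparts of toolkit operations used inside training.

The differentiable MIND here mirrors :mod:`sctkit.mind` step for step
(replicate-padded translation, all-ones box kernel on the squared difference,
relative variance floor), so the trained structural loss and the evaluated
descriptor are the same quantity; a test pins the two implementations
together.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np

from ..mind import MINDConfig
from .tensor import Tensor, concat

__all__ = ["softmax", "translate", "mind_descriptor_t", "mind_loss_t"]


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - x.data.max(axis=axis, keepdims=True)  # constant shift, no grad needed
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def translate(x: Tensor, dy: int, dx: int) -> Tensor:
    """Replicate-padded translation of the last two axes: out(x) = in(x + a)."""
    if dy == 0 and dx == 0:
        return x
    h, w = x.shape[-2:]
    py, px = abs(dy), abs(dx)
    padded = x.pad_edge2d(py, px)
    return padded[..., py + dy : py + dy + h, px + dx : px + dx + w]


def mind_descriptor_t(x: Tensor, cfg: MINDConfig = MINDConfig()) -> Tensor:
    """MIND map of a (B, 1, H, W) tensor; output (B, 8, H, W)."""
    r = cfg.patch_size // 2
    patch_offsets = [(i, j) for i in range(-r, r + 1) for j in range(-r, r + 1)]
    dps = []
    for off in cfg.offsets:
        d2 = (x - translate(x, *off)) ** 2
        acc = None
        for p in patch_offsets:
            term = translate(d2, *p)
            acc = term if acc is None else acc + term
        dps.append(acc)
    dp = concat(dps, axis=1)
    v = dp.mean(axis=1, keepdims=True)
    floor = max(cfg.variance_floor * float(v.data.mean()), 1e-12)
    v = v.clamp_min(floor)
    desc = (-(dp / v)).exp()
    if cfg.normalization == "max_one":
        desc = desc / desc.max(axis=1, keepdims=True)
    else:
        desc = desc * (1.0 / len(cfg.offsets))
    return desc


def mind_loss_t(a: Tensor, b: Tensor, cfg: MINDConfig = MINDConfig()) -> Tensor:
    """Differentiable structure-conserving loss between two (B,1,H,W) images."""
    return (mind_descriptor_t(a, cfg) - mind_descriptor_t(b, cfg)).abs().mean()
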