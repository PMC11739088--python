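"""Modality-independent neighborhood descriptor (MIND) and structural loss.

MIND encodes, at every pixel, how similar the patch around the pixel is to
the patches around its 8 neighbours:

    MIND(I, x, r) = (1/n) exp(-Dp(I, x, x+r) / V(I, x))
    Dp(I, x, x+r) = sum_{p in P} (I(x+p) - I(x+r+p))^2
    V(I, x)       = (1/N) sum_{r in N8} Dp(I, x, x+r)

Because Dp and V both scale with the square of any positive affine intensity
change, the ratio — and therefore the descriptor — is invariant to such
restyling.  That is what lets an MR slice and a CT slice of the same anatomy
be compared structurally even though their intensities are unrelated.

Dp is computed for all pixels at once as a box filter over the squared
difference between the image and its translated copy, which is exactly the
double sum above (the all-ones kernel acts on the *squared* difference).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np
from scipy import ndimage

from .grid import ImageGrid

__all__ = ["N8_OFFSETS", "MINDConfig", "patch_distance", "mind_descriptor", "mind_loss"]

N8_OFFSETS: Tuple[Tuple[int, int], ...] = (
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1),           (0, 1),
    (1, -1), (1, 0), (1, 1),
)


@dataclass(frozen=True)
class MINDConfig:
    """Descriptor parameters: the 8-neighbourhood offsets, an odd square
    patch (all-ones kernel), a relative variance floor, and the channel
    normalization (``max_one``: per-pixel maximum channel set to 1, as in the
    original descriptor; ``sum_inv_n``: plain 1/8 prefactor)."""

    offsets: Tuple[Tuple[int, int], ...] = N8_OFFSETS
    patch_size: int = 3
    variance_floor: float = 1e-3
    normalization: str = "max_one"

    def __post_init__(self) -> None:
        if len(self.offsets) != 8:
            raise ValueError("MIND uses the 8-neighbourhood: exactly 8 offsets")
        if self.patch_size < 1 or self.patch_size % 2 == 0:
            raise ValueError("patch_size must be odd and >= 1")
        if self.variance_floor <= 0:
            raise ValueError("variance_floor must be positive")
        if self.normalization not in ("max_one", "sum_inv_n"):
            raise ValueError("normalization must be 'max_one' or 'sum_inv_n'")


def _as_array(img) -> np.ndarray:
    return img.values if isinstance(img, ImageGrid) else np.asarray(img, dtype=np.float64)


def _translate(arr: np.ndarray, offset: Tuple[int, int]) -> np.ndarray:
    """Translated copy I'(a) with replicate (edge) padding: output at x is
    I(x + a)."""
    dy, dx = offset
    py = abs(dy)
    px = abs(dx)
    padded = np.pad(arr, ((py, py), (px, px)), mode="edge")
    return padded[py + dy : py + dy + arr.shape[0], px + dx : px + dx + arr.shape[1]]


def patch_distance(img, offset: Tuple[int, int], cfg: MINDConfig = MINDConfig()) -> np.ndarray:
    """Per-pixel sum of squared patch differences between x and x+offset.

    Box-filter form of the direct double loop: the all-ones kernel is applied
    to the squared difference image, with replicate boundary handling.
    """
    arr = _as_array(img)
    if min(arr.shape) < cfg.patch_size:
        raise ValueError("patch larger than image")
    diff2 = (arr - _translate(arr, offset)) ** 2
    # uniform_filter averages; rescale to the plain all-ones sum
    return ndimage.uniform_filter(diff2, size=cfg.patch_size, mode="nearest") * cfg.patch_size**2


def mind_descriptor(img, cfg: MINDConfig = MINDConfig()) -> np.ndarray:
    """8-channel MIND map, shape (8, H, W), channel order = ``cfg.offsets``.

    V is clamped below at ``variance_floor`` times its spatial mean so that
    flat regions (V -> 0) stay well defined; all channels lie in (0, 1].
    """
    arr = _as_array(img)
    extent = cfg.patch_size // 2 + max(max(abs(dy), abs(dx)) for dy, dx in cfg.offsets)
    if min(arr.shape) < 2 * extent + 1:
        raise ValueError("image too small for the patch/offset extent")
    dp = np.stack([patch_distance(arr, off, cfg) for off in cfg.offsets])
    v = dp.mean(axis=0)
    floor = max(cfg.variance_floor * float(v.mean()), 1e-12)
    v = np.maximum(v, floor)
    desc = np.exp(-dp / v)
    if cfg.normalization == "max_one":
        desc /= desc.max(axis=0, keepdims=True)
    else:
        desc /= len(cfg.offsets)
    return desc


def mind_loss(a, b, cfg: MINDConfig = MINDConfig()) -> float:
    """Structure-conserving loss: mean absolute difference of the two MIND
    maps over all pixels and channels.  Zero iff the descriptors coincide;
    invariant to positive affine restyling of either image."""
    arr_a, arr_b = _as_array(a), _as_array(b)
    if arr_a.shape != arr_b.shape:
        raise ValueError("mind_loss requires images on the same grid")
    return float(np.mean(np.abs(mind_descriptor(arr_a, cfg) - mind_descriptor(arr_b, cfg))))
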