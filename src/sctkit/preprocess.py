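"""Normalization chain applied before training and evaluation.

CT: clip to [-1024, 3071] HU, extract a body mask (largest connected
above-air component, holes filled), blank everything outside it.
MR: histogram-match to a reference, then robust-rescale into the network
range [-1, 1].  CT uses a *fixed* affine [-1024, 3071] -> [-1, 1], so HU are
recovered exactly from network outputs by the inverse map.

Coordinate convention throughout: 0-based indices, pixel-center sampling;
resampling keeps the physical field-of-view centre fixed.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

from .grid import ImageGrid, Modality

__all__ = [
    "HU_MIN",
    "HU_MAX",
    "clip_hu",
    "body_mask",
    "remove_external",
    "histogram_match",
    "resample_to_grid",
    "ct_to_net",
    "net_to_ct",
    "mr_to_net",
]

HU_MIN, HU_MAX = -1024.0, 3071.0


def clip_hu(ct: ImageGrid) -> ImageGrid:
    """Clip CT values into the scanner HU range [-1024, 3071]."""
    if ct.modality not in (Modality.CT, Modality.SCT):
        raise ValueError(f"clip_hu expects CT-like modality, got {ct.modality}")
    return ct.with_values(np.clip(ct.values, HU_MIN, HU_MAX))


def body_mask(ct: ImageGrid, air_threshold_hu: float = -300.0) -> np.ndarray:
    """Body mask: largest connected component above the air threshold, with
    interior holes filled (so bowel gas stays inside the body).

    A mid fat/air threshold (-300 HU) separates patient from couch air.
    """
    fg = ct.values > air_threshold_hu
    if not fg.any():
        raise ValueError("no voxels above the air threshold; cannot build a body mask")
    lab, n = ndimage.label(fg)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        fg = lab == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(fg)


def remove_external(ct: ImageGrid, mask: np.ndarray, fill_value: float = HU_MIN) -> ImageGrid:
    """Set everything outside the body mask to ``fill_value``."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != ct.shape:
        raise ValueError("mask shape does not match image shape")
    out = ct.values.copy()
    out[~mask] = fill_value
    return ct.with_values(out)


def histogram_match(mr: ImageGrid, reference: ImageGrid) -> ImageGrid:
    """Map MR intensities so their empirical distribution matches the
    reference's (classic quantile mapping; monotone, hence rank-preserving)."""
    ref = reference.values.ravel()
    if np.ptp(ref) == 0:
        raise ValueError("histogram matching against a constant reference is undefined")
    src = mr.values.ravel()
    src_sorted = np.sort(src)
    ref_sorted = np.sort(ref)
    # empirical CDF positions of the source, mapped through the reference quantile function
    src_cdf = (np.searchsorted(src_sorted, src, side="right") - 0.5) / src.size
    q = np.linspace(0.5 / ref.size, 1.0 - 0.5 / ref.size, ref.size)
    matched = np.interp(src_cdf, q, ref_sorted)
    return mr.with_values(matched.reshape(mr.shape))


def resample_to_grid(
    img: ImageGrid,
    size: int | Tuple[int, ...],
    spacing_mm: float | Tuple[float, ...],
    order: Optional[int] = None,
) -> ImageGrid:
    """Resample onto a new grid of the given size and spacing.

    Linear interpolation for intensities, nearest-neighbour when the image
    carries mask-like (binary) content or ``order=0`` is forced.  The physical
    centre of the field of view is preserved: output pixel ``i`` sits at
    physical ``(i - (n_out-1)/2) * sp_out`` relative to the common centre.
    """
    nd = img.values.ndim
    size = (size,) * nd if np.isscalar(size) else tuple(size)
    spacing = (spacing_mm,) * nd if np.isscalar(spacing_mm) else tuple(spacing_mm)
    if any(s < 2 for s in size):
        raise ValueError("target size must be >= 2 along every axis")
    if any(s <= 0 for s in spacing):
        raise ValueError("target spacing must be positive")
    if order is None:
        order = 1

    coords = []
    for ax in range(nd):
        n_in, n_out = img.shape[ax], size[ax]
        phys = (np.arange(n_out) - (n_out - 1) / 2.0) * spacing[ax]
        coords.append(phys / img.spacing_mm[ax] + (n_in - 1) / 2.0)
    mesh = np.meshgrid(*coords, indexing="ij")
    out = ndimage.map_coordinates(img.values, np.stack(mesh), order=order, mode="nearest")

    new_mask = None
    if img.mask is not None:
        new_mask = (
            ndimage.map_coordinates(img.mask.astype(np.float64), np.stack(mesh), order=0, mode="nearest") > 0.5
        )
    return ImageGrid(out, spacing, img.modality, mask=new_mask)


# --- network-range scaling ------------------------------------------------

def ct_to_net(ct: ImageGrid) -> np.ndarray:
    """Fixed affine HU -> [-1, 1]; invertible exactly by :func:`net_to_ct`."""
    return (np.clip(ct.values, HU_MIN, HU_MAX) - HU_MIN) / (HU_MAX - HU_MIN) * 2.0 - 1.0


def net_to_ct(x: np.ndarray) -> np.ndarray:
    """Inverse of :func:`ct_to_net`: [-1, 1] -> HU in [-1024, 3071]."""
    return np.clip((np.asarray(x) + 1.0) / 2.0 * (HU_MAX - HU_MIN) + HU_MIN, HU_MIN, HU_MAX)


def mr_to_net(mr: ImageGrid, lo_pct: float = 0.5, hi_pct: float = 99.5) -> np.ndarray:
    """Per-image robust rescale of MR intensities into [-1, 1]."""
    lo, hi = np.percentile(mr.values, [lo_pct, hi_pct])
    if hi <= lo:
        raise ValueError("degenerate MR intensity range")
    return np.clip((mr.values - lo) / (hi - lo), 0.0, 1.0) * 2.0 - 1.0
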