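"""Image-quality evaluation of synthetic CT against planning CT.

All metrics are computed *within the body mask only* (values outside it
never influence a result): MAE in HU, PSNR in dB over a fixed HU data range,
SSIM with mask-restricted window centres, and the KL divergence between
masked intensity histograms.  Method comparison across cases uses the
two-sided Wilcoxon rank-sum test.

Conventions the evaluation protocol leaves open are fixed here and flagged
in report headers: KL(planning-CT || sCT) with 100 bins over [-1024, 3071],
natural log and 1e-10 additive smoothing; PSNR over the fixed clip width
4095 HU (not per-image max) so values are comparable across cases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage, stats

from .grid import ImageGrid

__all__ = ["MetricsReport", "mae", "psnr", "ssim", "histogram_kl",
           "compare_methods", "evaluate_case"]

HU_RANGE = (-1024.0, 3071.0)
PSNR_CAP_DB = 100.0


@dataclass
class MetricsReport:
    mae: float
    psnr: float
    ssim: float
    kl_divergence: float
    n_masked_pixels: int

    def as_dict(self) -> dict:
        return {
            "mae": self.mae, "psnr": self.psnr, "ssim": self.ssim,
            "kl_divergence": self.kl_divergence, "n_masked_pixels": self.n_masked_pixels,
        }


def _values(img) -> np.ndarray:
    return img.values if isinstance(img, ImageGrid) else np.asarray(img, dtype=np.float64)


def _masked(ref, test, mask) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    r, t = _values(ref), _values(test)
    if r.shape != t.shape:
        raise ValueError("images must share a grid")
    m = np.asarray(mask, dtype=bool)
    if m.shape != r.shape:
        raise ValueError("mask must share the image grid")
    if not m.any():
        raise ValueError("empty mask")
    return r, t, m


def mae(ref, test, mask) -> float:
    """Mean absolute error (HU) over the masked support."""
    r, t, m = _masked(ref, test, mask)
    return float(np.mean(np.abs(r[m] - t[m])))


def psnr(ref, test, mask, data_range: float = HU_RANGE[1] - HU_RANGE[0]) -> float:
    """Peak signal-to-noise ratio in dB over the masked support; identical
    images report the 100 dB cap."""
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    r, t, m = _masked(ref, test, mask)
    mse = float(np.mean((r[m] - t[m]) ** 2))
    if mse == 0.0:
        return PSNR_CAP_DB
    return min(10.0 * np.log10(data_range**2 / mse), PSNR_CAP_DB)


def _gaussian_kernel(size: int, sigma: float) -> np.ndarray:
    ax = np.arange(size) - (size - 1) / 2.0
    k = np.exp(-0.5 * (ax / sigma) ** 2)
    k2 = np.outer(k, k)
    return k2 / k2.sum()


def ssim(ref, test, mask=None, data_range: float = HU_RANGE[1] - HU_RANGE[0],
         win_size: int = 11, sigma: float = 1.5, k1: float = 0.01, k2: float = 0.03) -> float:
    """Structural similarity with an 11x11 Gaussian window (sigma 1.5).

    Windows use the full (unmasked) arrays for context; the mean is taken
    over window centres inside the mask, restricted to centres whose window
    fits entirely within the image.
    """
    r, t = _values(ref), _values(test)
    if r.shape != t.shape:
        raise ValueError("images must share a grid")
    if min(r.shape) < win_size:
        raise ValueError("image smaller than the SSIM window")
    kern = _gaussian_kernel(win_size, sigma)
    filt = lambda a: ndimage.correlate(a, kern, mode="constant")
    ux, uy = filt(r), filt(t)
    uxx, uyy, uxy = filt(r * r), filt(t * t), filt(r * t)
    vx = uxx - ux * ux
    vy = uyy - uy * uy
    cxy = uxy - ux * uy
    c1, c2 = (k1 * data_range) ** 2, (k2 * data_range) ** 2
    s = ((2 * ux * uy + c1) * (2 * cxy + c2)) / ((ux**2 + uy**2 + c1) * (vx + vy + c2))
    pad = win_size // 2
    interior = np.zeros(r.shape, dtype=bool)
    interior[pad:-pad, pad:-pad] = True
    sel = interior if mask is None else interior & np.asarray(mask, dtype=bool)
    if not sel.any():
        raise ValueError("no valid window centres inside the mask")
    return float(s[sel].mean())


def histogram_kl(ref, test, mask, bins: int = 100,
                 value_range: Tuple[float, float] = HU_RANGE, eps: float = 1e-10) -> float:
    """KL(P_ref || P_test) in nats between masked intensity histograms,
    with additive-epsilon smoothing and renormalisation."""
    if bins < 2:
        raise ValueError("need at least 2 bins")
    r, t, m = _masked(ref, test, mask)
    p, _ = np.histogram(np.clip(r[m], *value_range), bins=bins, range=value_range)
    q, _ = np.histogram(np.clip(t[m], *value_range), bins=bins, range=value_range)
    p = p.astype(np.float64) + eps
    q = q.astype(np.float64) + eps
    p /= p.sum()
    q /= q.sum()
    return float(np.sum(p * np.log(p / q)))


def compare_methods(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value between per-case metric lists.

    Exact small-sample distribution when both samples are small and tie-free;
    midrank normal approximation otherwise.  Degenerate all-equal input
    gives p = 1.
    """
    a = np.asarray(list(a), dtype=np.float64)
    b = np.asarray(list(b), dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (max(a.size, b.size) <= 10 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def evaluate_case(ref_ct: ImageGrid, sct: ImageGrid, mask: np.ndarray) -> MetricsReport:
    """All four image metrics for one case over one shared masked support."""
    return MetricsReport(
        mae=mae(ref_ct, sct, mask),
        psnr=psnr(ref_ct, sct, mask),
        ssim=ssim(ref_ct, sct, mask),
        kl_divergence=histogram_kl(ref_ct, sct, mask),
        n_masked_pixels=int(np.asarray(mask, dtype=bool).sum()),
    )
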