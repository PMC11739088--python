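"""Exhaustive brute-force gamma oracle, independent of the implementation.

Searches every candidate shift on the same subsampled lattice the
implementation declares, with its own bilinear interpolation, voxel by
voxel.  Used by the unit and acceptance suites to pin the vectorised
implementation's pass rates exactly.
"""

import numpy as np

from sctkit.dosimetry import GammaCriteria


def _bilinear(arr: np.ndarray, ys: np.ndarray, xs: np.ndarray) -> np.ndarray:
    h, w = arr.shape
    y0 = np.clip(np.floor(ys).astype(int), 0, h - 1)
    x0 = np.clip(np.floor(xs).astype(int), 0, w - 1)
    y1 = np.clip(y0 + 1, 0, h - 1)
    x1 = np.clip(x0 + 1, 0, w - 1)
    fy = ys - y0
    fx = xs - x0
    return (
        arr[y0, x0] * (1 - fy) * (1 - fx)
        + arr[y1, x0] * fy * (1 - fx)
        + arr[y0, x1] * (1 - fy) * fx
        + arr[y1, x1] * fy * fx
    )


def brute_force_pass_rate(ref: np.ndarray, evl: np.ndarray, spacing,
                          criteria: GammaCriteria) -> float:
    norm = criteria.global_norm if criteria.global_norm is not None else float(ref.max())
    threshold = criteria.threshold_percent / 100.0 * norm
    pts = np.argwhere(ref >= threshold)
    dd = criteria.dose_diff_percent / 100.0
    dta = criteria.dta_mm
    radius = criteria.search_radius_factor * dta

    axes = []
    for ax in range(ref.ndim):
        step = spacing[ax] / criteria.subsample_factor
        kmax = int(np.floor(radius / step))
        axes.append(np.arange(-kmax, kmax + 1) * step)
    offs = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, ref.ndim)
    d2 = (offs**2).sum(axis=1)
    inside_r = d2 <= radius**2 + 1e-12
    offs, d2 = offs[inside_r], d2[inside_r]

    n_pass = 0
    for y, x in pts:
        dref = ref[y, x]
        delta = dd * dref if criteria.mode == "local" else dd * norm
        py = y + offs[:, 0] / spacing[0]
        px = x + offs[:, 1] / spacing[1]
        valid = (py >= 0) & (py <= ref.shape[0] - 1) & (px >= 0) & (px <= ref.shape[1] - 1)
        de = _bilinear(evl, py[valid], px[valid])
        g2 = (de - dref) ** 2 / delta**2 + d2[valid] / dta**2
        if g2.min() <= 1.0:
            n_pass += 1
    return n_pass / len(pts)


def smooth_dose_pair(rng: np.random.Generator, n: int = 16, max_gy: float = 10.0):
    """A smooth reference dose and a mildly perturbed evaluated dose."""
    from scipy import ndimage

    ref = ndimage.gaussian_filter(rng.uniform(size=(n, n)), sigma=3.0)
    ref = ref / ref.max() * max_gy
    pert = 1.0 + 0.03 * ndimage.gaussian_filter(rng.normal(size=(n, n)), sigma=2.0)
    shift = 0.02 * max_gy * ndimage.gaussian_filter(rng.normal(size=(n, n)), sigma=2.0)
    evl = np.clip(ref * pert + shift, 0.0, None)
    return ref, evl
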