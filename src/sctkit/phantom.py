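"""Synthetic abdominal MR/CT phantom slices, dose fields and structure masks.

The generator emulates the data regime of an unpaired abdominal MR-to-CT
translation study: pixel-aligned MR-like and CT-like slices whose anatomy
agrees everywhere *except* for a controllable fraction of bowel-gas pockets
present in only one modality (the dominant source of genuine MR/CT anatomical
disagreement in the abdomen), plus smooth dose distributions and structure
masks so that dosimetric evaluation can run with no clinical data.

Anatomy is deliberately stylised (ellipse organs), because downstream code
only needs class-wise intensity statistics, a single body component, bone,
and gas — not realistic organ shapes.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import ImageGrid, Modality, save_nifti

__all__ = [
    "LABEL_NAMES",
    "PhantomSpec",
    "TissueLabelMap",
    "generate_pair",
    "generate_dose",
    "generate_structures",
    "generate_cohort",
]

# integer tissue classes
BACKGROUND, FAT, SOFT, LIVER, KIDNEY, BONE, STOMACH, GAS = range(8)
LABEL_NAMES = {
    BACKGROUND: "background",
    FAT: "fat",
    SOFT: "soft_tissue",
    LIVER: "liver",
    KIDNEY: "kidney",
    BONE: "spine",
    STOMACH: "stomach",
    GAS: "gas",
}

# class-wise mean intensities; CT in HU, MR in arbitrary units (bone dark,
# fat bright — the opposite ordering from CT, so no affine map links them)
CT_MEANS = {
    BACKGROUND: -1024.0,
    FAT: -100.0,
    SOFT: 40.0,
    LIVER: 60.0,
    KIDNEY: 30.0,
    BONE: 700.0,
    STOMACH: 20.0,
    GAS: -800.0,
}
MR_MEANS = {
    BACKGROUND: 0.0,
    FAT: 900.0,
    SOFT: 400.0,
    LIVER: 320.0,
    KIDNEY: 470.0,
    BONE: 90.0,
    STOMACH: 250.0,
    GAS: 20.0,
}

HU_MIN, HU_MAX = -1024.0, 3071.0


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic cohort.

    ``discrepancy_level`` is the fraction of gas pockets present in only one
    of the two modalities; 0 means perfectly aligned anatomy.
    """

    grid_size: int = 256
    spacing_mm: float = 0.83
    n_slices: int = 1
    discrepancy_level: float = 0.0
    n_gas_pockets: int = 8
    noise_sd_ct: float = 20.0
    noise_sd_mr: float = 15.0
    bias_field_amplitude: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.grid_size < 32:
            raise ValueError("grid_size must be >= 32")
        if self.spacing_mm <= 0:
            raise ValueError("spacing_mm must be positive")
        if not 0.0 <= self.discrepancy_level <= 1.0:
            raise ValueError("discrepancy_level must lie in [0, 1]")
        if self.n_gas_pockets < 0:
            raise ValueError("n_gas_pockets must be >= 0")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")


@dataclass
class TissueLabelMap:
    """Per-pixel tissue classes for one slice, in both modality views.

    ``labels`` holds the shared anatomy with the CT-visible gas set;
    ``mr_labels`` differs only in which gas pockets are painted.
    ``gas_pockets`` records every pocket with its modality visibility, so the
    number of modality-unique pockets is inspectable.
    """

    labels: np.ndarray
    mr_labels: np.ndarray
    spacing_mm: float
    gas_pockets: List[Dict] = field(default_factory=list)

    @property
    def ct_labels(self) -> np.ndarray:
        return self.labels

    def view(self, source: str) -> np.ndarray:
        if source == "ct":
            return self.labels
        if source == "mr":
            return self.mr_labels
        raise ValueError("source must be 'ct' or 'mr'")

    @property
    def n_unique_gas(self) -> int:
        return sum(1 for p in self.gas_pockets if p["unique"])


def _rng_for(spec: PhantomSpec, *streams: int) -> np.random.Generator:
    # independent, reproducible stream per (seed, purpose, slice)
    return np.random.default_rng([spec.seed & 0x7FFFFFFF, *streams])


def _ellipse(yy, xx, cy, cx, ry, rx, angle=0.0):
    ca, sa = np.cos(angle), np.sin(angle)
    y, x = yy - cy, xx - cx
    u = ca * y + sa * x
    v = -sa * y + ca * x
    return (u / ry) ** 2 + (v / rx) ** 2 <= 1.0


def _base_anatomy(spec: PhantomSpec, slice_index: int) -> Tuple[np.ndarray, np.random.Generator]:
    """Shared (gas-free) anatomy for one slice. y runs top->bottom; posterior
    (spine) sits at large y."""
    rng = _rng_for(spec, 1, slice_index)
    n = spec.grid_size
    coords = (np.arange(n) + 0.5) / n * 2.0 - 1.0
    yy, xx = np.meshgrid(coords, coords, indexing="ij")

    j = lambda s: rng.normal(0.0, s)  # per-slice anatomical jitter
    labels = np.full((n, n), BACKGROUND, dtype=np.int16)

    body_ry, body_rx = 0.72 + j(0.02), 0.90 + j(0.02)
    body = _ellipse(yy, xx, 0.0, 0.0, body_ry, body_rx)
    inner = _ellipse(yy, xx, 0.0, 0.0, body_ry - 0.10, body_rx - 0.10)
    labels[body] = FAT
    labels[inner] = SOFT

    liver = _ellipse(yy, xx, -0.18 + j(0.02), -0.38 + j(0.02), 0.30, 0.34, angle=0.3 + j(0.05))
    labels[liver & inner] = LIVER
    stomach = _ellipse(yy, xx, -0.16 + j(0.02), 0.28 + j(0.02), 0.17, 0.21, angle=-0.4 + j(0.05))
    labels[stomach & inner] = STOMACH
    for side in (-1.0, 1.0):
        kidney = _ellipse(yy, xx, 0.28 + j(0.02), side * (0.45 + j(0.02)), 0.14, 0.09, angle=side * 0.2)
        labels[kidney & inner] = KIDNEY
    spine = _ellipse(yy, xx, 0.48 + j(0.01), 0.0 + j(0.01), 0.13, 0.11)
    labels[spine & body] = BONE
    return labels, rng


def _gas_pockets(spec: PhantomSpec, slice_index: int, labels: np.ndarray) -> List[Dict]:
    """Sample gas pockets and flag a deterministic fraction as modality-unique."""
    rng = _rng_for(spec, 2, slice_index)
    n = spec.grid_size
    pockets: List[Dict] = []
    allowed = np.isin(labels, (SOFT, STOMACH))
    ys, xs = np.nonzero(allowed)
    if len(ys) == 0 or spec.n_gas_pockets == 0:
        return pockets
    for _ in range(spec.n_gas_pockets):
        k = rng.integers(0, len(ys))
        pockets.append(
            {
                "center": (int(ys[k]), int(xs[k])),
                "radius_px": float(rng.uniform(0.02, 0.05) * n),
                "unique": False,
                "modality": "both",
            }
        )
    n_unique = int(round(spec.discrepancy_level * len(pockets)))
    unique_idx = rng.choice(len(pockets), size=n_unique, replace=False)
    for i in unique_idx:
        pockets[int(i)]["unique"] = True
        pockets[int(i)]["modality"] = "ct" if rng.random() < 0.5 else "mr"
    return pockets


def _paint_gas(labels: np.ndarray, pockets: List[Dict], modality: str) -> np.ndarray:
    out = labels.copy()
    n = labels.shape[0]
    coords = np.arange(n)
    yy, xx = np.meshgrid(coords, coords, indexing="ij")
    for p in pockets:
        if p["modality"] not in ("both", modality):
            continue
        cy, cx = p["center"]
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= p["radius_px"] ** 2
        out[disk & (out != BACKGROUND) & (out != BONE)] = GAS
    return out


def _bias_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field exp(A * low-order polynomial), emulating
    B0 inhomogeneity in MR acquisition."""
    n = spec.grid_size
    c = (np.arange(n) + 0.5) / n * 2.0 - 1.0
    yy, xx = np.meshgrid(c, c, indexing="ij")
    coef = rng.normal(0.0, 1.0, size=6)
    poly = (
        coef[0] * yy + coef[1] * xx + coef[2] * yy * xx
        + coef[3] * (yy**2 - 0.5) + coef[4] * (xx**2 - 0.5) + coef[5] * yy * xx**2
    )
    poly = poly / max(np.abs(poly).max(), 1e-12)
    return np.exp(spec.bias_field_amplitude * poly)


def generate_pair(spec: PhantomSpec, slice_index: int = 0) -> Tuple[ImageGrid, ImageGrid, TissueLabelMap]:
    """Generate one pixel-aligned MR/CT slice pair plus its label map.

    The two images share geometry exactly, except that gas pockets flagged
    modality-unique appear in only one of them.  Identical ``spec`` and
    ``slice_index`` give bit-identical output.
    """
    spec.validate()
    base, _ = _base_anatomy(spec, slice_index)
    pockets = _gas_pockets(spec, slice_index, base)
    ct_labels = _paint_gas(base, pockets, "ct")
    mr_labels = _paint_gas(base, pockets, "mr")
    lmap = TissueLabelMap(
        labels=ct_labels, mr_labels=mr_labels, spacing_mm=spec.spacing_mm, gas_pockets=pockets
    )

    rng = _rng_for(spec, 3, slice_index)
    ct = np.empty(ct_labels.shape)
    for lab, mean in CT_MEANS.items():
        ct[ct_labels == lab] = mean
    ct += rng.normal(0.0, spec.noise_sd_ct, size=ct.shape)
    ct[ct_labels == BACKGROUND] = HU_MIN  # air outside the body is exact
    ct = np.clip(ct, HU_MIN, HU_MAX)

    mr = np.empty(mr_labels.shape)
    for lab, mean in MR_MEANS.items():
        mr[mr_labels == lab] = mean
    mr *= _bias_field(spec, rng)
    mr += rng.normal(0.0, spec.noise_sd_mr, size=mr.shape)
    mr[mr_labels == BACKGROUND] = 0.0
    mr = np.clip(mr, 0.0, None)

    sp = (spec.spacing_mm, spec.spacing_mm)
    return (
        ImageGrid(mr, sp, Modality.MR),
        ImageGrid(ct, sp, Modality.CT),
        lmap,
    )


def generate_dose(
    spec: PhantomSpec,
    labels: TissueLabelMap | np.ndarray,
    target_label: int = LIVER,
    source: str = "ct",
    prescribed_max_gy: float = 25.0,
    n_blobs: int = 3,
    gas_attenuation: float = 0.25,
) -> ImageGrid:
    """Smooth synthetic dose: anisotropic Gaussian blobs centred in the
    target structure, scaled so the maximum equals ``prescribed_max_gy``.

    ``gas_attenuation`` > 0 scales dose down around gas (a crude density
    effect), so label maps whose gas differs yield different dose fields —
    the mechanism that separates aligned from misaligned cases downstream.
    Set it to 0 for a pure sum of Gaussians.
    """
    spec.validate()
    lab = labels.view(source) if isinstance(labels, TissueLabelMap) else np.asarray(labels)
    target = lab == target_label
    if not target.any():
        raise ValueError(f"target label {target_label} absent from label map")

    rng = _rng_for(spec, 4)
    ys, xs = np.nonzero(target)
    n = lab.shape[0]
    yy, xx = np.meshgrid(np.arange(n, dtype=float), np.arange(n, dtype=float), indexing="ij")
    dose = np.zeros(lab.shape)
    mm = spec.spacing_mm
    for _ in range(n_blobs):
        k = rng.integers(0, len(ys))
        cy, cx = float(ys[k]), float(xs[k])
        sy = rng.uniform(8.0, 15.0) / mm  # sigma in pixels from mm
        sx = rng.uniform(8.0, 15.0) / mm
        amp = rng.uniform(0.5, 1.0)
        dose += amp * np.exp(-0.5 * (((yy - cy) / sy) ** 2 + ((xx - cx) / sx) ** 2))

    if gas_attenuation > 0.0:
        gas = (lab == GAS).astype(float)
        gas_s = ndimage.gaussian_filter(gas, sigma=3.0 / mm)
        dose *= 1.0 - gas_attenuation * gas_s

    dose *= prescribed_max_gy / dose.max()
    return ImageGrid(dose, (mm, mm), Modality.DOSE)


def generate_structures(labels: TissueLabelMap, source: str = "ct") -> Dict[str, np.ndarray]:
    """Structure masks for DVH evaluation: GTV = target organ (liver), PTV =
    GTV dilated by ~5 mm, OARs = kidneys and spine."""
    lab = labels.view(source)
    gtv = lab == LIVER
    dil = max(1, int(round(5.0 / labels.spacing_mm)))
    ptv = ndimage.binary_dilation(gtv, iterations=dil)
    return {
        "GTV": gtv,
        "PTV": ptv,
        "kidney": lab == KIDNEY,
        "spine": lab == BONE,
    }


def generate_cohort(
    spec: PhantomSpec,
    n_train: int,
    n_val: int,
    n_test: int,
    out_dir: str | Path,
    write_dose: bool = True,
) -> pd.DataFrame:
    """Write a train/val/test phantom cohort of NIfTI slice pairs plus a
    manifest CSV.

    Test cases are split half/half into Group 1 (discrepancy 0: good MR/CT
    anatomical alignment) and Group 2 (the configured discrepancy level:
    poor alignment); train/val use the configured level throughout.  Per
    test case two
    dose grids are written — one computed from the CT-view anatomy and one
    from the MR-view anatomy — standing in for plan doses recalculated on
    planning CT and on synthetic CT.
    """
    spec.validate()
    if min(n_train, n_val, n_test) < 1:
        raise ValueError("all split counts must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    idx = 0
    for split, count in (("train", n_train), ("val", n_val), ("test", n_test)):
        for k in range(count):
            if split == "test":
                group = 1 if k < count - count // 2 else 2
                level = 0.0 if group == 1 else max(spec.discrepancy_level, 1e-12)
                case_spec = PhantomSpec(**{**spec.__dict__, "discrepancy_level": level if group == 2 else 0.0})
            else:
                group = 0
                case_spec = spec
            mr, ct, lmap = generate_pair(case_spec, slice_index=idx)
            cid = f"case_{idx:03d}"
            mr_path = save_nifti(mr, out_dir / f"{cid}_mr.nii.gz")
            ct_path = save_nifti(ct, out_dir / f"{cid}_ct.nii.gz")
            dose_path = dose_mr_path = ""
            if write_dose and split == "test":
                dose_ct = generate_dose(case_spec, lmap, source="ct")
                dose_mr = generate_dose(case_spec, lmap, source="mr")
                dose_path = str(save_nifti(dose_ct, out_dir / f"{cid}_dose_ct.nii.gz"))
                dose_mr_path = str(save_nifti(dose_mr, out_dir / f"{cid}_dose_mr.nii.gz"))
            rows.append(
                {
                    "id": cid,
                    "mr_path": str(mr_path),
                    "ct_path": str(ct_path),
                    "dose_path": dose_path,
                    "dose_mr_path": dose_mr_path,
                    "split": split,
                    "group": group,
                }
            )
            idx += 1

    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]
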