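"""Image and dose containers with physical spacing, plus NIfTI round-tripping.

Everything in the toolkit moves through :class:`ImageGrid`: a scalar field
(HU for CT, arbitrary units for MR, Gy for dose) on a regular grid with a
per-axis physical spacing in millimetres, a modality tag and an optional
validity mask.  2D slices are the common case; dose grids may be 3D.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Optional, Tuple

import nibabel as nib
import numpy as np

__all__ = ["Modality", "ImageGrid", "load_nifti", "save_nifti"]


class Modality(str, Enum):
    MR = "MR"
    CT = "CT"
    SCT = "SCT"
    DOSE = "DOSE"


@dataclass
class ImageGrid:
    """A scalar field with physical spacing.

    Parameters
    ----------
    values : ndarray
        2D (or 3D for dose) array of finite scalars.
    spacing_mm : tuple of float
        Physical pixel/voxel size per axis, in mm; all entries positive.
    modality : Modality
        What the values mean (MR units, HU, Gy).
    mask : ndarray of bool, optional
        Validity mask on the same grid.
    """

    values: np.ndarray
    spacing_mm: Tuple[float, ...]
    modality: Modality = Modality.CT
    mask: Optional[np.ndarray] = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if isinstance(self.spacing_mm, (int, float)):
            self.spacing_mm = (float(self.spacing_mm),) * self.values.ndim
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.modality = Modality(self.modality)
        if len(self.spacing_mm) != self.values.ndim:
            raise ValueError(
                f"spacing_mm has {len(self.spacing_mm)} entries for a "
                f"{self.values.ndim}D array"
            )
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm entries must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image values must be finite")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape must match values shape")

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.values.shape

    def with_values(self, values: np.ndarray, modality: Optional[Modality] = None) -> "ImageGrid":
        """Copy of this grid carrying new values (same geometry)."""
        return replace(
            self,
            values=np.asarray(values, dtype=np.float64),
            modality=self.modality if modality is None else Modality(modality),
        )

    def same_grid(self, other: "ImageGrid") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing_mm, other.spacing_mm)


def _affine_from_spacing(spacing_mm: Tuple[float, ...], ndim: int) -> np.ndarray:
    aff = np.eye(4)
    for i in range(min(ndim, 3)):
        aff[i, i] = spacing_mm[i]
    return aff


def save_nifti(img: ImageGrid, path: str | Path) -> Path:
    """Write an :class:`ImageGrid` as NIfTI; spacing goes into the affine."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = img.values.astype(np.float32)
    nii = nib.Nifti1Image(arr, _affine_from_spacing(img.spacing_mm, arr.ndim))
    zooms = img.spacing_mm + (1.0,) * (arr.ndim - len(img.spacing_mm))
    nii.header.set_zooms(zooms[: arr.ndim])
    nii.header["descrip"] = img.modality.value.encode()
    nib.save(nii, str(path))
    return path


def load_nifti(path: str | Path, modality: Modality | str | None = None) -> ImageGrid:
    """Read a NIfTI file into an :class:`ImageGrid`.

    The modality is taken from the header description when not given
    explicitly; unknown descriptions default to CT.
    """
    nii = nib.load(str(path))
    values = np.asarray(nii.dataobj, dtype=np.float64)
    zooms = nii.header.get_zooms()[: values.ndim]
    if modality is None:
        descrip = bytes(nii.header["descrip"]).split(b"\x00")[0].decode(errors="ignore")
        try:
            modality = Modality(descrip)
        except ValueError:
            modality = Modality.CT
    return ImageGrid(values=values, spacing_mm=tuple(zooms), modality=Modality(modality))
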