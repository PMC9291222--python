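"""Imaging data model, NIfTI I/O and the pre-processing operators the pipeline needs.

The in-memory containers are deliberately thin: a 3-D scalar lattice with
physical geometry (``ImageVolume``) and a boolean region on the same lattice
(``Mask``).  All world coordinates are millimetres, RAS-oriented; voxel
indices are 0-based.  Volumes carry an intensity-unit tag so that CBF maps
(ml/100 g/min) are never silently mixed with arbitrary-unit MR signal.

Registration and spatial normalisation are out of scope: every volume of a
subject is assumed to live on one shared lattice (the synthetic cohort is
generated that way), and :func:`require_aligned` asserts that contract.  A
pre-computed transform can be applied externally before entering the
pipeline.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "ImageVolume",
    "Mask",
    "LabelMap",
    "FormatError",
    "GeometryError",
    "read_nifti",
    "write_nifti",
    "read_mask",
    "write_mask",
    "resample_isotropic",
    "gaussian_smooth",
    "correct_bias_field",
    "require_aligned",
]

#: Conversion between a Gaussian FWHM and its standard deviation.
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

UNITS_ARBITRARY = "arbitrary"
UNITS_CBF = "ml_per_100g_per_min"
_VALID_UNITS = (UNITS_ARBITRARY, UNITS_CBF)


class FormatError(ValueError):
    """Raised when a file on disk cannot be decoded as NIfTI."""


class GeometryError(ValueError):
    """Raised when two lattices that must coincide do not."""


@dataclass
class ImageVolume:
    """A 3-D scalar image on a regular lattice with physical geometry.

    Parameters
    ----------
    data:
        3-D float array, index order (x, y, z) in RAS convention.
    spacing:
        Voxel edge lengths in mm, one per axis; all strictly positive.
    origin:
        World-space (mm) position of voxel (0, 0, 0).
    axis_codes:
        Anatomical orientation labels, default RAS.
    intensity_units:
        ``"arbitrary"`` for MR signal, ``"ml_per_100g_per_min"`` for CBF.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_codes: tuple[str, str, str] = ("R", "A", "S")
    intensity_units: str = UNITS_ARBITRARY

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D lattice, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        self.axis_codes = tuple(self.axis_codes)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if np.isinf(self.data).any():
            raise ValueError("volume contains infinities")
        if self.intensity_units not in _VALID_UNITS:
            raise ValueError(f"unknown intensity_units {self.intensity_units!r}")

    # -- geometry helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def geometry(self) -> tuple:
        return (self.shape, self.spacing, self.origin, self.axis_codes)

    def same_lattice(self, other: "ImageVolume | Mask") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
            and self.axis_codes == other.axis_codes
        )

    def with_data(self, data: np.ndarray, units: str | None = None) -> "ImageVolume":
        return replace(
            self,
            data=data,
            intensity_units=self.intensity_units if units is None else units,
        )

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff


@dataclass
class Mask:
    """A boolean region on the same lattice as its parent volume."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_codes: tuple[str, str, str] = ("R", "A", "S")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D lattice, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        self.axis_codes = tuple(self.axis_codes)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @classmethod
    def like(cls, vol: ImageVolume, data: np.ndarray) -> "Mask":
        return cls(data=data, spacing=vol.spacing, origin=vol.origin, axis_codes=vol.axis_codes)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def volume_cm3(self) -> float:
        return self.n_voxels * self.voxel_volume_mm3 / 1000.0

    def same_lattice(self, other: "ImageVolume | Mask") -> bool:
        return ImageVolume.same_lattice(self, other)  # type: ignore[arg-type]

    def with_data(self, data: np.ndarray) -> "Mask":
        return replace(self, data=data)

    def __and__(self, other: "Mask") -> "Mask":
        return self.with_data(self.data & other.data)

    def __or__(self, other: "Mask") -> "Mask":
        return self.with_data(self.data | other.data)

    def __sub__(self, other: "Mask") -> "Mask":
        return self.with_data(self.data & ~other.data)

    def is_empty(self) -> bool:
        return not self.data.any()


@dataclass
class LabelMap:
    """An integer tissue-class partition on a lattice (every voxel one class)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_codes: tuple[str, str, str] = ("R", "A", "S")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label map data must be integer-typed")
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D lattice, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        self.axis_codes = tuple(self.axis_codes)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_lattice(self, other) -> bool:
        return ImageVolume.same_lattice(self, other)  # type: ignore[arg-type]

    def mask(self, *labels: int) -> Mask:
        """Binary mask of the union of the given class labels."""
        sel = np.isin(self.data, labels)
        return Mask(sel, spacing=self.spacing, origin=self.origin, axis_codes=self.axis_codes)

    def labels_present(self) -> list[int]:
        return sorted(int(v) for v in np.unique(self.data))


def require_aligned(*items: ImageVolume | Mask, context: str = "") -> None:
    """Assert the pre-aligned contract: all lattices identical.

    Raises :class:`GeometryError` naming the first mismatch.
    """
    if len(items) < 2:
        return
    ref = items[0]
    for i, item in enumerate(items[1:], start=1):
        if not ref.same_lattice(item):  # type: ignore[union-attr]
            raise GeometryError(
                f"lattice mismatch{' in ' + context if context else ''}: "
                f"item 0 has {ref.geometry() if isinstance(ref, ImageVolume) else (ref.shape, ref.spacing)}, "
                f"item {i} has shape {item.shape}, spacing {item.spacing}"
            )


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def read_nifti(path: str | Path) -> ImageVolume:
    """Read a NIfTI-1/2 file into an :class:`ImageVolume`.

    Spacing is taken from the header zooms, the origin from the affine
    translation.  The intensity-unit tag is recovered from the header
    ``descrip`` field when present (written by :func:`write_nifti`).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
        zooms = img.header.get_zooms()[:3]
        affine = img.affine
    except FileNotFoundError:
        raise
    except Exception as exc:  # nibabel raises a zoo of header errors
        raise FormatError(f"cannot decode {path} as NIfTI: {exc}") from exc
    if data.ndim != 3:
        raise FormatError(f"{path}: expected 3-D data, header reports ndim={data.ndim}")
    if any(z <= 0 for z in zooms):
        raise FormatError(f"{path}: non-positive pixdim {zooms}")
    descrip = img.header["descrip"].tobytes().rstrip(b"\x00").decode("ascii", "ignore")
    units = UNITS_CBF if UNITS_CBF in descrip else UNITS_ARBITRARY
    codes = nib.orientations.aff2axcodes(affine)
    return ImageVolume(
        data=data,
        spacing=tuple(float(z) for z in zooms),
        origin=tuple(float(v) for v in affine[:3, 3]),
        axis_codes=codes,
        intensity_units=units,
    )


def write_nifti(vol: ImageVolume, path: str | Path, sidecar: bool = True) -> Path:
    """Write an :class:`ImageVolume` to NIfTI-1, with a JSON geometry sidecar.

    The intensity-unit tag is stored in the header ``descrip`` field so a
    round trip preserves it.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float64), vol.affine())
    img.header.set_zooms(vol.spacing)
    img.header["descrip"] = vol.intensity_units.encode("ascii")[:79]
    nib.save(img, str(path))
    if sidecar:
        meta = {
            "shape": list(vol.shape),
            "spacing_mm": list(vol.spacing),
            "origin_mm": list(vol.origin),
            "axis_codes": list(vol.axis_codes),
            "intensity_units": vol.intensity_units,
        }
        path.with_suffix("").with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return path


def write_mask(mask: Mask, path: str | Path) -> Path:
    """Write a mask as an unsigned 8-bit NIfTI volume (values 0/1)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    vol = ImageVolume(
        data=mask.data.astype(np.uint8),
        spacing=mask.spacing,
        origin=mask.origin,
        axis_codes=mask.axis_codes,
    )
    img = nib.Nifti1Image(mask.data.astype(np.uint8), vol.affine())
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))
    return path


def read_mask(path: str | Path) -> Mask:
    vol = read_nifti(path)
    return Mask.like(vol, vol.data > 0.5)


# ---------------------------------------------------------------------------
# Pre-processing operators
# ---------------------------------------------------------------------------

def resample_isotropic(
    vol: ImageVolume | Mask,
    target_mm: float = 1.0,
    mode: str = "linear",
) -> ImageVolume | Mask:
    """Resample onto an isotropic lattice of ``target_mm`` voxels.

    Physical extent is preserved (cell-centred resampling, so the output
    grid covers the same physical box within one voxel).  ``mode="nearest"``
    must be used for masks and label maps; it introduces no new values.
    """
    if target_mm <= 0:
        raise ValueError(f"target_mm must be positive, got {target_mm}")
    if mode not in ("linear", "nearest"):
        raise ValueError(f"mode must be 'linear' or 'nearest', got {mode!r}")
    is_mask = isinstance(vol, Mask)
    if is_mask and mode != "nearest":
        raise ValueError("masks must be resampled with mode='nearest'")
    data = vol.data.astype(np.float64) if not is_mask else vol.data.astype(np.uint8)
    factors = tuple(s / target_mm for s in vol.spacing)
    order = 1 if mode == "linear" else 0
    out = ndimage.zoom(data, zoom=factors, order=order, mode="nearest", grid_mode=True)
    spacing = (target_mm,) * 3
    if is_mask:
        return Mask(out > 0.5, spacing=spacing, origin=vol.origin, axis_codes=vol.axis_codes)
    return ImageVolume(
        out,
        spacing=spacing,
        origin=vol.origin,
        axis_codes=vol.axis_codes,
        intensity_units=vol.intensity_units,
    )


def gaussian_smooth(vol: ImageVolume, fwhm_mm: float = 6.0) -> ImageVolume:
    """Separable Gaussian smoothing with an isotropic physical FWHM.

    The per-axis standard deviation in voxel units is
    ``fwhm_mm * FWHM_TO_SIGMA / spacing``, so anisotropic lattices are
    handled correctly.  Boundary handling is nearest-edge replication,
    which preserves the mean of interior-supported signals.
    """
    if fwhm_mm <= 0:
        raise ValueError(f"fwhm_mm must be positive, got {fwhm_mm}")
    sigma_vox = tuple(fwhm_mm * FWHM_TO_SIGMA / s for s in vol.spacing)
    out = ndimage.gaussian_filter(vol.data.astype(np.float64), sigma=sigma_vox, mode="nearest")
    return vol.with_data(out)


def correct_bias_field(
    vol: ImageVolume,
    brain_mask: Mask,
    degree: int = 2,
) -> ImageVolume:
    """Flatten a smooth multiplicative intensity bias field.

    Fits a low-order 3-D polynomial to log-intensities inside the brain
    mask (ordinary least squares on coordinates normalised to [-1, 1]),
    exponentiates it into a multiplicative field normalised to unit mean
    inside the mask, and divides it out everywhere.  The within-mask mean
    intensity of the output equals that of the input (gain renormalised).

    Non-positive intensities inside the mask trigger a shifted-log
    fallback with a warning.
    """
    if brain_mask.is_empty():
        raise ValueError("brain mask is empty")
    require_aligned(vol, brain_mask, context="correct_bias_field")
    if degree < 1:
        raise ValueError("polynomial degree must be >= 1")
    data = vol.data.astype(np.float64)
    inside = brain_mask.data
    shift = 0.0
    min_in = data[inside].min()
    if min_in <= 0:
        shift = -min_in + 1e-3 * (float(np.ptp(data[inside])) or 1.0)
        warnings.warn(
            "non-positive intensities inside mask; using shifted-log bias fit",
            RuntimeWarning,
            stacklevel=2,
        )
    logd = np.log(data + shift, out=np.full_like(data, np.nan), where=(data + shift) > 0)

    coords = [np.linspace(-1.0, 1.0, n) for n in vol.shape]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    terms = []
    for i in range(degree + 1):
        for j in range(degree + 1 - i):
            for k in range(degree + 1 - i - j):
                terms.append(xx**i * yy**j * zz**k)
    design = np.stack([t[inside] for t in terms], axis=1)
    target = logd[inside]
    ok = np.isfinite(target)
    coef, *_ = np.linalg.lstsq(design[ok], target[ok], rcond=None)
    log_field = sum(c * t for c, t in zip(coef, terms))
    log_field -= log_field[inside].mean()  # unit geometric mean in mask
    fieldv = np.exp(log_field)
    out = (data + shift) / fieldv - shift
    # renormalise gain so the within-mask arithmetic mean is unchanged
    gain = data[inside].mean() / out[inside].mean()
    return vol.with_data(out * gain)
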