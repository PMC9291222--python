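"""GTV delineation, perfusion-threshold sub-volume splitting, ROI placement and CBF statistics.

The gross tumor volume (GTV) is the Flair-hyperintense abnormality; the
high-perfusion sub-volume (GTV-ASL) is carved out of it by a CBF threshold
rule and the remainder is the low-perfusion GTV-SUB.  The manual contouring
of the clinical workflow is replaced by reproducible threshold + morphology
rules validated against phantom ground truth.

Region statistics follow the measurement protocol: absolute CBF max/min/mean
over a region, and relative values normalised by the mean CBF of a normal
gray-matter reference region (contralateral mirror for unilateral lesions,
a fixed standard gray-matter site otherwise).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .asl_quant import CBFMap
from .core_io import ImageVolume, Mask, require_aligned

__all__ = [
    "ThresholdRule",
    "TargetSet",
    "PerfusionStats",
    "ROISet",
    "EmptyGTVError",
    "delineate_gtv",
    "segment_gtv_asl",
    "place_rois",
    "perfusion_stats",
]

_STRUCT_26 = ndimage.generate_binary_structure(3, 3)
_STRUCT_6 = ndimage.generate_binary_structure(3, 1)


class EmptyGTVError(ValueError):
    """No Flair-hyperintense lesion found."""


@dataclass(frozen=True)
class ThresholdRule:
    """CBF threshold rule splitting the GTV.

    ``absolute``   — CBF >= value (ml/100 g/min); default value is the
                     ROC-derived cut-off 44.16.
    ``relative``   — CBF >= value * gm_reference (value is an rCBF cut-off,
                     e.g. 1.49).
    ``percentile`` — CBF >= the value-th percentile of CBF within the GTV.
    ``otsu``       — subject-adaptive: the Otsu threshold of the within-GTV
                     CBF histogram.  This emulates the visual contouring
                     construct ("the locally high-perfusion part of the
                     lesion") independently of the patient's global
                     perfusion level; ``value`` is ignored.
    """

    kind: str = "absolute"
    value: float = 44.16
    gm_reference: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("absolute", "relative", "percentile", "otsu"):
            raise ValueError(f"unknown rule kind {self.kind!r}")
        if self.value <= 0:
            raise ValueError("rule threshold must be positive")
        if self.kind == "relative" and (self.gm_reference is None or self.gm_reference <= 0):
            raise ValueError("relative rule needs a positive gm_reference")
        if self.kind == "percentile" and not (0 < self.value < 100):
            raise ValueError("percentile must lie in (0, 100)")

    @classmethod
    def parse(cls, text: str, gm_reference: float | None = None) -> "ThresholdRule":
        """Parse ``"absolute:44.16"`` / ``"relative:1.49"`` / ``"percentile:70"`` / ``"otsu"``."""
        kind, _, value = text.partition(":")
        kind = kind.strip()
        if kind == "otsu":
            return cls(kind="otsu")
        if not value:
            raise ValueError(f"cannot parse threshold rule {text!r}")
        return cls(kind=kind, value=float(value), gm_reference=gm_reference)

    def threshold(self, cbf_in_gtv: np.ndarray) -> float:
        if self.kind == "absolute":
            return self.value
        if self.kind == "relative":
            return self.value * float(self.gm_reference)  # type: ignore[arg-type]
        if self.kind == "otsu":
            from skimage.filters import threshold_otsu

            return float(threshold_otsu(cbf_in_gtv))
        return float(np.percentile(cbf_in_gtv, self.value))


@dataclass
class TargetSet:
    """GTV and its perfusion partition; the mask algebra is enforced on build."""

    gtv: Mask
    gtv_asl: Mask
    gtv_sub: Mask
    exclusion: Mask

    def __post_init__(self) -> None:
        require_aligned(self.gtv, self.gtv_asl, self.gtv_sub, self.exclusion, context="TargetSet")
        if (self.gtv_asl.data & ~self.gtv.data).any():
            raise ValueError("GTV-ASL must be a subset of the GTV")
        if (self.gtv_asl.data & self.gtv_sub.data).any():
            raise ValueError("GTV-ASL and GTV-SUB must be disjoint")
        if not np.array_equal(self.gtv_sub.data, self.gtv.data & ~self.gtv_asl.data):
            raise ValueError("GTV-SUB must equal GTV minus GTV-ASL")
        if (self.gtv_asl.data & self.exclusion.data).any():
            raise ValueError("GTV-ASL must avoid exclusion regions")


@dataclass
class PerfusionStats:
    """Absolute and relative CBF statistics of one region."""

    cbf_max: float
    cbf_min: float
    cbf_mean: float
    reference_gm_mean: float
    n_voxels: int

    @property
    def r_cbf_max(self) -> float:
        return self.cbf_max / self.reference_gm_mean

    @property
    def r_cbf_min(self) -> float:
        return self.cbf_min / self.reference_gm_mean

    @property
    def r_cbf_mean(self) -> float:
        return self.cbf_mean / self.reference_gm_mean

    def as_dict(self) -> dict:
        return {
            "cbf_max": self.cbf_max,
            "cbf_min": self.cbf_min,
            "cbf_mean": self.cbf_mean,
            "r_cbf_max": self.r_cbf_max,
            "r_cbf_min": self.r_cbf_min,
            "r_cbf_mean": self.r_cbf_mean,
            "reference_gm_mean": self.reference_gm_mean,
            "n_voxels": self.n_voxels,
        }


@dataclass
class ROISet:
    """Measurement ROIs: tumor sample, up to four edema samples, GM reference."""

    roi_t: Mask
    roi_e: list[Mask]
    roi_n: Mask
    areas_mm2: dict[str, float] = field(default_factory=dict)


def _cbf_arrays(cbf: CBFMap | ImageVolume) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(cbf, CBFMap):
        return cbf.data, cbf.invalid.data
    return cbf.data, np.zeros(cbf.data.shape, dtype=bool)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def delineate_gtv(flair: ImageVolume, brain_mask: Mask, k_sigma: float = 2.0) -> Mask:
    """Contour the Flair-hyperintense abnormality as the GTV.

    Two-pass intensity thresholding: normal-brain mean and SD are first
    estimated over the whole brain, then re-estimated excluding the
    candidate hyperintensity, and voxels above ``mu + k_sigma * sd`` form
    the lesion.  The largest 26-connected component, hole-filled, is
    returned.  Raises :class:`EmptyGTVError` when nothing exceeds the
    threshold.
    """
    if brain_mask.is_empty():
        raise ValueError("brain mask is empty")
    require_aligned(flair, brain_mask, context="delineate_gtv")
    data = flair.data
    inside = brain_mask.data

    normal = inside
    for _ in range(2):
        mu = data[normal].mean()
        sd = data[normal].std(ddof=1)
        candidate = inside & (data > mu + k_sigma * sd)
        remaining = inside & ~candidate
        if not remaining.any():
            break
        normal = remaining

    if not candidate.any():
        raise EmptyGTVError("no Flair-hyperintense voxels above the threshold")
    comp, n_comp = ndimage.label(candidate, structure=_STRUCT_26)
    sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=np.arange(1, n_comp + 1))
    largest = int(np.argmax(sizes)) + 1
    gtv = ndimage.binary_fill_holes(comp == largest)
    return Mask.like(flair, gtv)


def segment_gtv_asl(
    cbf: CBFMap | ImageVolume,
    gtv: Mask,
    exclusion: Mask | None = None,
    rule: ThresholdRule | str = ThresholdRule(),
    min_component_cm3: float = 0.1,
) -> TargetSet:
    """Split the GTV into GTV-ASL (high perfusion) and GTV-SUB by a CBF rule.

    The thresholded set inside ``gtv`` minus ``exclusion`` is cleaned with a
    morphological closing (radius one voxel) and components smaller than
    ``min_component_cm3`` are dropped.  GTV-SUB is the set difference; an
    empty GTV-ASL is legal and warned about.  Raising the threshold can
    never grow the GTV-ASL (both cleanup steps are increasing operators).
    """
    if gtv.is_empty():
        raise ValueError("GTV is empty")
    if isinstance(rule, str):
        rule = ThresholdRule.parse(rule)
    data, invalid = _cbf_arrays(cbf)
    if exclusion is None:
        exclusion = gtv.with_data(np.zeros(gtv.shape, dtype=bool))
    require_aligned(gtv, exclusion, context="segment_gtv_asl")

    eligible = gtv.data & ~exclusion.data & ~invalid
    thr = rule.threshold(data[gtv.data & ~invalid])
    raw = eligible & (data >= thr)

    cleaned = ndimage.binary_closing(raw, structure=_STRUCT_6) | raw
    cleaned &= eligible  # closing must not leak outside the eligible set
    min_vox = int(np.ceil(min_component_cm3 * 1000.0 / gtv.voxel_volume_mm3))
    if min_vox > 1 and cleaned.any():
        comp, n_comp = ndimage.label(cleaned, structure=_STRUCT_26)
        sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=np.arange(1, n_comp + 1))
        keep = np.flatnonzero(sizes >= min_vox) + 1
        cleaned = np.isin(comp, keep)

    if not cleaned.any():
        warnings.warn("GTV-ASL is empty under this rule", RuntimeWarning, stacklevel=2)
    gtv_asl = gtv.with_data(cleaned)
    gtv_sub = gtv.with_data(gtv.data & ~cleaned)
    return TargetSet(gtv=gtv, gtv_asl=gtv_asl, gtv_sub=gtv_sub, exclusion=exclusion)


def _disc(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    centre_xy: tuple[float, float],
    z: int,
    area_mm2: float,
) -> np.ndarray:
    """Rasterise a single-slice disc of the requested in-plane area."""
    radius = np.sqrt(area_mm2 / np.pi)
    xs = (np.arange(shape[0]) - centre_xy[0]) * spacing[0]
    ys = (np.arange(shape[1]) - centre_xy[1]) * spacing[1]
    in_disc = (xs[:, None] ** 2 + ys[None, :] ** 2) <= radius**2
    out = np.zeros(shape, dtype=bool)
    out[:, :, z] = in_disc
    return out


def place_rois(
    cbf: CBFMap | ImageVolume,
    targets: TargetSet,
    gm_mask: Mask,
    laterality: str = "unilateral",
    area_mm2: float = 120.0,
) -> ROISet:
    """Place the measurement ROIs on the peak-perfusion slice.

    ROI-T is a disc centred on the CBF maximum of the axial slice whose
    in-slice mean GTV-ASL perfusion is highest, clipped to GTV-ASL.
    Four ROI-E discs sample the edema (GTV-SUB) around the GTV-ASL
    centroid at 90-degree spacing; each is kept only if at least
    100 mm2 of it fits in GTV-SUB (fewer ROIs with a warning otherwise).
    ROI-N samples normal gray matter: the mirror of the lesion centroid
    across the lattice mid-sagittal plane for unilateral lesions, else a
    fixed standard gray-matter site.  All ROIs avoid exclusion regions.
    """
    data, invalid = _cbf_arrays(cbf)
    if targets.gtv_asl.is_empty():
        raise ValueError("cannot place ROIs: GTV-ASL is empty")
    if gm_mask.is_empty():
        raise ValueError("gray-matter mask is empty")
    spacing = targets.gtv.spacing
    shape = targets.gtv.shape
    pixel_mm2 = spacing[0] * spacing[1]
    asl = targets.gtv_asl.data & ~targets.exclusion.data & ~invalid
    sub = targets.gtv_sub.data & ~targets.exclusion.data & ~invalid
    areas: dict[str, float] = {}

    # --- ROI-T on the hottest slice ---
    slice_counts = asl.sum(axis=(0, 1))
    with np.errstate(invalid="ignore"):
        slice_means = np.where(
            slice_counts > 0, np.sum(data * asl, axis=(0, 1)) / np.maximum(slice_counts, 1), -np.inf
        )
    z_star = int(np.argmax(slice_means))
    plane = np.where(asl[:, :, z_star], data[:, :, z_star], -np.inf)
    cx, cy = np.unravel_index(int(np.argmax(plane)), plane.shape)
    roi_t = _disc(shape, spacing, (cx, cy), z_star, area_mm2) & asl
    if roi_t.sum() * pixel_mm2 < area_mm2 * 0.5:
        warnings.warn("ROI-T clipped well below the requested area", RuntimeWarning, stacklevel=2)
    areas["roi_t"] = float(roi_t.sum() * pixel_mm2)

    # --- four ROI-E discs around the GTV-ASL centroid, one per quadrant ---
    centroid = np.array(ndimage.center_of_mass(asl))
    sub_slice = sub[:, :, z_star]
    # distance (in pixels) to the edge of GTV-SUB within the slice
    dt = ndimage.distance_transform_edt(sub_slice, sampling=spacing[:2])
    gx, gy = np.indices(sub_slice.shape)
    angles = np.degrees(np.arctan2(gy - centroid[1], gx - centroid[0])) % 360.0
    rois_e: list[np.ndarray] = []
    for start in (315.0, 45.0, 135.0, 225.0):  # quadrants centred on 0/90/180/270
        in_quadrant = ((angles - start) % 360.0) < 90.0
        cand_dt = np.where(in_quadrant & sub_slice, dt, 0.0)
        placed = None
        # try the deepest few centres in this quadrant, shrinking to 100 mm2
        for _ in range(4):
            if cand_dt.max() <= 0:
                break
            cx_e, cy_e = np.unravel_index(int(np.argmax(cand_dt)), cand_dt.shape)
            for area in (area_mm2, 100.0):
                cand = _disc(shape, spacing, (cx_e, cy_e), z_star, area) & sub
                for prev in rois_e:
                    cand &= ~prev
                if cand.sum() * pixel_mm2 >= 100.0:
                    placed = cand
                    break
            if placed is not None:
                break
            cand_dt[max(0, cx_e - 2): cx_e + 3, max(0, cy_e - 2): cy_e + 3] = 0.0
        if placed is not None:
            rois_e.append(placed)
    if len(rois_e) < 4:
        warnings.warn(
            f"only {len(rois_e)} edema ROIs of >=100 mm2 fit in GTV-SUB", RuntimeWarning, stacklevel=2
        )
    for i, roi in enumerate(rois_e, start=1):
        areas[f"roi_e{i}"] = float(roi.sum() * pixel_mm2)

    # --- ROI-N in normal gray matter ---
    gm_ok = gm_mask.data & ~targets.gtv.data & ~targets.exclusion.data & ~invalid
    if not gm_ok.any():
        raise ValueError("no gray matter available outside the GTV for ROI-N")
    lesion_centroid = np.array(ndimage.center_of_mass(targets.gtv.data))
    if laterality == "unilateral":
        target_pt = lesion_centroid.copy()
        target_pt[0] = (shape[0] - 1) - target_pt[0]  # mirror across mid-sagittal plane
    else:
        # standard gray-matter site (insular stand-in): left hemisphere, mid-depth
        target_pt = np.array([0.25 * shape[0], 0.5 * shape[1], 0.5 * shape[2]])
    gm_idx = np.argwhere(gm_ok)
    dists = np.linalg.norm((gm_idx - target_pt) * np.array(spacing), axis=1)
    nx, ny, nz = gm_idx[int(np.argmin(dists))]
    roi_n = _disc(shape, spacing, (nx, ny), int(nz), area_mm2) & gm_ok
    grow = 1.0
    while roi_n.sum() * pixel_mm2 < 100.0 and grow < 2.0:
        grow += 0.25
        roi_n = _disc(shape, spacing, (nx, ny), int(nz), area_mm2 * grow) & gm_ok
    if roi_n.sum() * pixel_mm2 < 100.0:
        warnings.warn("ROI-N below 100 mm2 after clipping to gray matter", RuntimeWarning, stacklevel=2)
    areas["roi_n"] = float(roi_n.sum() * pixel_mm2)

    like = targets.gtv
    return ROISet(
        roi_t=like.with_data(roi_t),
        roi_e=[like.with_data(r) for r in rois_e],
        roi_n=like.with_data(roi_n),
        areas_mm2=areas,
    )


def perfusion_stats(
    cbf: CBFMap | ImageVolume,
    region: Mask,
    reference: Mask,
) -> PerfusionStats:
    """Absolute and GM-normalised CBF statistics over a region.

    Invalid (uncalibratable) voxels are excluded from both the region and
    the reference; both must remain non-empty.
    """
    data, invalid = _cbf_arrays(cbf)
    require_aligned(region, reference, context="perfusion_stats")
    reg = region.data & ~invalid
    ref = reference.data & ~invalid
    if not reg.any():
        raise ValueError("region is empty (or fully invalid)")
    if not ref.any():
        raise ValueError("reference region is empty (or fully invalid)")
    values = data[reg]
    ref_mean = float(data[ref].mean())
    return PerfusionStats(
        cbf_max=float(values.max()),
        cbf_min=float(values.min()),
        cbf_mean=float(values.mean()),
        reference_gm_mean=ref_mean,
        n_voxels=int(reg.sum()),
    )
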