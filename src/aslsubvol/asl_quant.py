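"""CBF quantification from ASL control/label/M0 triplets.

Single-compartment pCASL model.  With time-averaged control and label
signal intensities ``SI_control``/``SI_label`` and a proton-density
calibration image ``SI_PD``::

    CBF = 6000 * lambda * (SI_control - SI_label) * exp(PLD / T1b)
          -----------------------------------------------------------
          2 * alpha * T1b * SI_PD * (1 - exp(-tau / T1b))

in ml/100 g/min, with all times in seconds.  The factor 6000 converts
ml/g/s to ml/100 g/min.  ``lambda`` is the brain/blood partition
coefficient (ml/g), ``alpha`` the labeling efficiency, ``tau`` the label
duration and ``PLD`` the post-labeling delay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import UNITS_CBF, ImageVolume, Mask, require_aligned

__all__ = [
    "AcquisitionParams",
    "ASLTriplet",
    "CBFMap",
    "compute_cbf",
    "cbf_scale_factor",
    "average_stack",
    "qc_summary",
]


@dataclass(frozen=True)
class AcquisitionParams:
    """pCASL acquisition constants of the quantification model.

    Defaults are the clinical 3-T protocol values: lambda = 0.9 ml/g,
    alpha = 0.85, tau = 1.5 s, PLD = 2.025 s, T1_blood = 1.65 s.
    Millisecond values may be supplied through :meth:`from_config`, which
    converts any field named ``*_ms`` to seconds.
    """

    lambda_partition: float = 0.9   # ml/g
    alpha_efficiency: float = 0.85  # dimensionless
    tau_label_s: float = 1.5        # s
    pld_s: float = 2.025            # s
    t1_blood_s: float = 1.65        # s

    def __post_init__(self) -> None:
        for name in ("lambda_partition", "alpha_efficiency", "tau_label_s", "pld_s", "t1_blood_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (0 < self.alpha_efficiency <= 1):
            raise ValueError("alpha_efficiency must be in (0, 1]")
        if not (0 < self.lambda_partition < 2):
            raise ValueError("lambda_partition must be in (0, 2)")

    @classmethod
    def from_config(cls, cfg: dict) -> "AcquisitionParams":
        """Build from a config mapping, accepting ``_ms`` time fields."""
        kwargs: dict[str, float] = {}
        for key, value in cfg.items():
            if key.endswith("_ms"):
                kwargs[key[:-3] + "_s"] = float(value) / 1000.0
            else:
                kwargs[key] = float(value)
        return cls(**kwargs)


def cbf_scale_factor(params: AcquisitionParams) -> float:
    """CBF per unit (ΔS / SI_PD): the closed-form model constant.

    ``CBF = scale * (SI_control - SI_label) / SI_PD``, so the same factor
    serves quantification and, inverted, the phantom's forward simulator.
    """
    t1b = params.t1_blood_s
    num = 6000.0 * params.lambda_partition * np.exp(params.pld_s / t1b)
    den = 2.0 * params.alpha_efficiency * t1b * (1.0 - np.exp(-params.tau_label_s / t1b))
    return float(num / den)


@dataclass
class ASLTriplet:
    """Control / label / M0 calibration volumes on one lattice.

    ``control`` and ``label`` are the time-averaged (NEX-averaged) ASL
    signal volumes; ``m0`` is the proton-density calibration image SI_PD.
    Pre-average repetition stacks with :func:`average_stack`.
    """

    control: ImageVolume
    label: ImageVolume
    m0: ImageVolume

    def __post_init__(self) -> None:
        require_aligned(self.control, self.label, self.m0, context="ASLTriplet")


@dataclass
class CBFMap:
    """A quantified CBF volume plus the mask of invalid (uncalibratable) voxels."""

    volume: ImageVolume
    invalid: Mask

    def __post_init__(self) -> None:
        require_aligned(self.volume, self.invalid, context="CBFMap")
        if self.volume.intensity_units != UNITS_CBF:
            raise ValueError("CBFMap volume must carry ml_per_100g_per_min units")

    @property
    def data(self) -> np.ndarray:
        return self.volume.data


def compute_cbf(
    triplet: ASLTriplet,
    params: AcquisitionParams | None = None,
    m0_floor: float | None = None,
    clip_negative: bool = False,
) -> CBFMap:
    """Quantify CBF voxel-wise from a control/label/M0 triplet.

    Voxels whose M0 falls below ``m0_floor`` are flagged invalid (CBF set
    to 0 there); the default floor is 5% of the median positive M0 value.
    Negative CBF values from noise are retained unless ``clip_negative`` —
    clipping would bias QC statistics.
    """
    params = params or AcquisitionParams()
    ctrl, labl, m0 = triplet.control, triplet.label, triplet.m0

    m0_data = m0.data.astype(np.float64)
    if m0_floor is None:
        positive = m0_data[m0_data > 0]
        m0_floor = 0.05 * float(np.median(positive)) if positive.size else 0.0
    invalid = m0_data < m0_floor

    delta = ctrl.data.astype(np.float64) - labl.data.astype(np.float64)
    scale = cbf_scale_factor(params)
    with np.errstate(divide="ignore", invalid="ignore"):
        cbf = scale * delta / m0_data
    cbf[invalid] = 0.0
    cbf[~np.isfinite(cbf)] = 0.0
    if clip_negative:
        np.clip(cbf, 0.0, None, out=cbf)
    vol = ImageVolume(
        cbf,
        spacing=m0.spacing,
        origin=m0.origin,
        axis_codes=m0.axis_codes,
        intensity_units=UNITS_CBF,
    )
    return CBFMap(volume=vol, invalid=Mask.like(vol, invalid))


def average_stack(volumes: list[ImageVolume]) -> ImageVolume:
    """Average pre-registered repetitions (NEX) of the same acquisition."""
    if not volumes:
        raise ValueError("empty repetition stack")
    require_aligned(*volumes, context="average_stack")
    data = np.mean([v.data for v in volumes], axis=0)
    return volumes[0].with_data(data)


def qc_summary(cbf: CBFMap, brain_mask: Mask) -> dict:
    """Deterministic quality-control record for a quantified map.

    Reports the within-brain fraction of invalid and of negative voxels and
    the mean/SD of valid in-brain CBF.
    """
    if brain_mask.is_empty():
        raise ValueError("brain mask is empty")
    require_aligned(cbf.volume, brain_mask, context="qc_summary")
    inside = brain_mask.data
    n = int(inside.sum())
    invalid = cbf.invalid.data & inside
    valid = inside & ~cbf.invalid.data
    values = cbf.data[valid]
    return {
        "n_voxels": n,
        "fraction_invalid": float(invalid.sum()) / n,
        "fraction_negative": float((values < 0).sum()) / n,
        "mean_cbf": float(values.mean()) if values.size else float("nan"),
        "sd_cbf": float(values.std(ddof=1)) if values.size > 1 else float("nan"),
    }
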