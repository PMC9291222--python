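"""Synthetic cohort generator for the non-enhancing low-grade glioma study design.

Each synthetic subject is a digital head phantom on one shared lattice:

* a brain ellipsoid with a gray-matter shell around a white-matter core;
* a gross tumor volume (GTV) of prescribed physical volume, placed per
  laterality (unilateral / midline / bilateral), consisting of a
  high-perfusion tumor core nested inside peritumoral edema — the core
  occupies a prescribed fraction of the GTV;
* a ground-truth CBF volume, constant per tissue class up to a smooth
  correlated within-class texture;
* forward-simulated ASL control/label/M0 volumes (the exact inverse of
  the quantification model, plus additive Gaussian noise);
* four structural sequences (T1WI, T2 Propeller, T2 Flair, CE-T1WI).
  The GTV is hyperintense on T2 Flair; on CE-T1WI the tumor takes its
  plain-T1 intensity (non-enhancing lesion).

Geometry is parametric, not anatomical: every downstream quantity in the
pipeline is region-statistical, so class topology (core inside edema
inside brain) is what matters.  Region volumes are controlled by selecting
the required number of voxels in order of (optionally perturbed) distance
from the lesion centre, so prescribed volumes and fractions are honoured
to within a voxel.

Cohort-level parameters default to the study population being emulated:
per-subject true CBF of the high-perfusion core ~ N(66.98, 18.03),
edema ~ N(35.19, 7.75) and normal gray matter ~ N(33.92, 8.48) ml/100 g/min
(all truncated positive), GTV volume ~ N(167.46, 209.64) cm3 and
high-perfusion volume fraction ~ N(0.3708, 0.1788), truncated to feasible
ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .asl_quant import AcquisitionParams, ASLTriplet, cbf_scale_factor
from .core_io import UNITS_CBF, ImageVolume, LabelMap, Mask

__all__ = [
    "TissueClass",
    "TruncatedNormal",
    "SubjectSpec",
    "CohortSpec",
    "SubjectBundle",
    "SEQUENCES",
    "generate_subject",
    "simulate_asl",
    "generate_cohort",
]


class TissueClass(IntEnum):
    BACKGROUND = 0
    WHITE_MATTER = 1
    GRAY_MATTER = 2
    EDEMA = 3
    TUMOR_HIGH_PERFUSION = 4
    CYST_NECROSIS = 5
    VESSEL = 6


#: The five MR sequences extracted per subject, in canonical order.
SEQUENCES = ("T1WI", "T2_Propeller", "T2_Flair", "CE_T1WI", "ASL")

#: Structural sequences actually synthesised (ASL enters as the CBF map).
STRUCTURAL_SEQUENCES = ("T1WI", "T2_Propeller", "T2_Flair", "CE_T1WI")

_TC = TissueClass

# Class-mean signal intensities (a.u.) of the structural sequences.  Chosen
# for the qualitative contrasts of the disease: tumor+edema hyperintense on
# T2/Flair (well above the ~2-sigma normal-brain threshold used for GTV
# delineation), mildly hypointense on T1, and CE-T1WI identical to T1WI in
# the lesion (no enhancement).
DEFAULT_STRUCTURAL_MEANS: dict[str, dict[TissueClass, float]] = {
    "T1WI": {
        _TC.BACKGROUND: 0.0, _TC.WHITE_MATTER: 500.0, _TC.GRAY_MATTER: 400.0,
        _TC.EDEMA: 340.0, _TC.TUMOR_HIGH_PERFUSION: 330.0,
        _TC.CYST_NECROSIS: 200.0, _TC.VESSEL: 420.0,
    },
    "T2_Propeller": {
        _TC.BACKGROUND: 0.0, _TC.WHITE_MATTER: 300.0, _TC.GRAY_MATTER: 350.0,
        _TC.EDEMA: 520.0, _TC.TUMOR_HIGH_PERFUSION: 495.0,
        _TC.CYST_NECROSIS: 620.0, _TC.VESSEL: 150.0,
    },
    "T2_Flair": {
        _TC.BACKGROUND: 0.0, _TC.WHITE_MATTER: 310.0, _TC.GRAY_MATTER: 360.0,
        _TC.EDEMA: 560.0, _TC.TUMOR_HIGH_PERFUSION: 575.0,
        _TC.CYST_NECROSIS: 150.0, _TC.VESSEL: 200.0,
    },
}
# non-enhancing: lesion classes keep their plain-T1 intensity
DEFAULT_STRUCTURAL_MEANS["CE_T1WI"] = dict(DEFAULT_STRUCTURAL_MEANS["T1WI"])

DEFAULT_NOISE_SD = {seq: 8.0 for seq in STRUCTURAL_SEQUENCES}

DEFAULT_CBF_TRUE = {
    _TC.BACKGROUND: 0.0,
    _TC.WHITE_MATTER: 22.0,
    _TC.GRAY_MATTER: 33.92,
    _TC.EDEMA: 35.19,
    _TC.TUMOR_HIGH_PERFUSION: 66.98,
    _TC.CYST_NECROSIS: 5.0,
    _TC.VESSEL: 120.0,
}

LATERALITIES = ("unilateral", "midline", "bilateral")


class GeometryInfeasibleError(ValueError):
    """The requested lesion cannot be placed inside the phantom brain."""


@dataclass(frozen=True)
class TruncatedNormal:
    """A truncated normal population distribution N(mean, sd) on [low, high]."""

    mean: float
    sd: float
    low: float = -np.inf
    high: float = np.inf

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if not self.low < self.high:
            raise ValueError(f"empty truncation interval [{self.low}, {self.high}]")

    def sample(self, rng: np.random.Generator, size=None):
        a = (self.low - self.mean) / self.sd
        b = (self.high - self.mean) / self.sd
        return stats.truncnorm.rvs(a, b, loc=self.mean, scale=self.sd, size=size, random_state=rng)


@dataclass
class SubjectSpec:
    """Ground-truth description of one synthetic subject."""

    gtv_volume_cm3: float = 167.46
    high_perfusion_fraction: float = 0.3708
    grid_shape: tuple[int, int, int] = (64, 64, 48)
    spacing_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    cbf_true: dict[TissueClass, float] = field(default_factory=lambda: dict(DEFAULT_CBF_TRUE))
    structural_means: dict[str, dict[TissueClass, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_STRUCTURAL_MEANS.items()}
    )
    noise_sd: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    asl_noise_sd: float = 0.2          # a.u. on control and label independently
    m0_value: float = 1000.0           # SI_PD (a.u.)
    bias_amplitude: float = 0.0        # multiplicative bias field amplitude
    texture_rel_sd: float = 0.10       # within-class relative CBF/signal texture
    texture_corr_vox: float = 2.0      # correlation length of the texture field
    boundary_perturbation: float = 0.15  # lesion boundary waviness (0 = sphere)
    laterality: str = "unilateral"
    include_cyst: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.high_perfusion_fraction < 1.0):
            raise ValueError("high_perfusion_fraction must lie in (0, 1)")
        if self.gtv_volume_cm3 <= 0:
            raise ValueError("gtv_volume_cm3 must be positive")
        if self.laterality not in LATERALITIES:
            raise ValueError(f"laterality must be one of {LATERALITIES}")
        if self.cbf_true[_TC.TUMOR_HIGH_PERFUSION] <= self.cbf_true[_TC.EDEMA]:
            raise ValueError(
                "high-perfusion core CBF must exceed edema CBF "
                f"({self.cbf_true[_TC.TUMOR_HIGH_PERFUSION]} <= {self.cbf_true[_TC.EDEMA]})"
            )
        if any(v < 0 for v in self.cbf_true.values()):
            raise ValueError("true CBF values must be non-negative")


@dataclass
class CohortSpec:
    """Population distributions from which per-subject ground truth is drawn."""

    n_subjects: int = 15
    gtv_volume_cm3: TruncatedNormal = field(
        default_factory=lambda: TruncatedNormal(167.46, 209.64, 10.0, 400.0)
    )
    high_perfusion_fraction: TruncatedNormal = field(
        default_factory=lambda: TruncatedNormal(0.3708, 0.1788, 0.02, 0.95)
    )
    cbf_high: TruncatedNormal = field(default_factory=lambda: TruncatedNormal(66.98, 18.03, 5.0, np.inf))
    cbf_edema: TruncatedNormal = field(default_factory=lambda: TruncatedNormal(35.19, 7.75, 5.0, np.inf))
    cbf_gm: TruncatedNormal = field(default_factory=lambda: TruncatedNormal(33.92, 8.48, 5.0, np.inf))
    cbf_wm: TruncatedNormal = field(default_factory=lambda: TruncatedNormal(22.0, 4.0, 5.0, np.inf))
    # emulated laterality mix: 7 unilateral, 5 midline, 3 bilateral of 15
    laterality_probs: tuple[float, float, float] = (7 / 15, 5 / 15, 3 / 15)
    #: SD of the shared per-subject global perfusion factor.  Tissue CBF
    #: values of one patient are correlated (global perfusion varies with
    #: age and physiology — the stated reason for rCBF normalisation); the
    #: reported paired statistics and the relative-value population rows
    #: both imply an inter-tissue correlation near 0.5, i.e. a shared
    #: factor with SD ~ 0.167 on top of tissue-specific residuals.  The
    #: tissue marginals above are preserved: residual variability is
    #: shrunk so that factor x residual reproduces each marginal SD.
    #: Set to 0 for fully independent tissue draws.
    subject_factor_sd: float = 0.167
    subject_overrides: dict = field(default_factory=dict)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if abs(sum(self.laterality_probs) - 1.0) > 1e-9:
            raise ValueError("laterality_probs must sum to 1")
        if not (0 <= self.subject_factor_sd < 0.5):
            raise ValueError("subject_factor_sd must lie in [0, 0.5)")


@dataclass
class SubjectBundle:
    """All generated artefacts of one synthetic subject."""

    subject_id: str
    spec: SubjectSpec
    labels: LabelMap
    cbf_truth: ImageVolume
    structurals: dict[str, ImageVolume]
    asl: ASLTriplet

    @property
    def brain_mask(self) -> Mask:
        return self.labels.mask(
            _TC.WHITE_MATTER, _TC.GRAY_MATTER, _TC.EDEMA,
            _TC.TUMOR_HIGH_PERFUSION, _TC.CYST_NECROSIS, _TC.VESSEL,
        )

    @property
    def gm_mask(self) -> Mask:
        return self.labels.mask(_TC.GRAY_MATTER)

    @property
    def gtv_truth(self) -> Mask:
        return self.labels.mask(_TC.EDEMA, _TC.TUMOR_HIGH_PERFUSION, _TC.CYST_NECROSIS)

    @property
    def core_truth(self) -> Mask:
        return self.labels.mask(_TC.TUMOR_HIGH_PERFUSION)

    @property
    def exclusion(self) -> Mask:
        return self.labels.mask(_TC.CYST_NECROSIS, _TC.VESSEL)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _smooth_unit_field(shape, corr_vox: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean, unit-SD Gaussian random field with the given correlation length."""
    noise = rng.standard_normal(shape)
    if corr_vox > 0:
        noise = ndimage.gaussian_filter(noise, sigma=corr_vox, mode="wrap")
    sd = noise.std()
    if sd > 0:
        noise = (noise - noise.mean()) / sd
    return noise


def _world_coords(shape, spacing):
    """Voxel-centre coordinates (mm) relative to the grid centre, per axis."""
    axes = [(np.arange(n) - (n - 1) / 2.0) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _brain_semi_axes(shape, spacing) -> tuple[float, float, float]:
    half = [n * s / 2.0 for n, s in zip(shape, spacing)]
    return (0.80 * half[0], 0.85 * half[1], 0.80 * half[2])


def _lesion_centre(spec: SubjectSpec, axes, r_lesion: float) -> tuple[float, float, float]:
    """Place the lesion per laterality, pulling toward the midline if needed to fit."""
    ax, ay, az = axes
    margin = 0.97
    if spec.laterality == "unilateral":
        want = 0.45 * ax
        # conservative feasibility: normalised centre offset + normalised radius <= margin
        max_off = (margin - r_lesion / min(axes)) * ax
        off = min(want, max_off)
        if off < 0:
            raise GeometryInfeasibleError(
                f"GTV of {spec.gtv_volume_cm3:.1f} cm3 cannot fit in the phantom brain"
            )
        return (off, 0.0, 0.0)
    # midline / bilateral lesions sit on the centre
    if r_lesion / min(axes) > margin:
        raise GeometryInfeasibleError(
            f"GTV of {spec.gtv_volume_cm3:.1f} cm3 cannot fit in the phantom brain"
        )
    return (0.0, 0.0, 0.0)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def generate_subject(spec: SubjectSpec) -> SubjectBundle:
    """Generate one synthetic subject (labels, true CBF, ASL triplet, structurals).

    Deterministic given ``spec.seed``.  The GTV (edema plus high-perfusion
    core) honours the prescribed physical volume and core fraction to
    within a voxel; raises :class:`GeometryInfeasibleError` if the lesion
    cannot be placed inside the brain.
    """
    rng = np.random.default_rng(spec.seed)
    shape, spacing = tuple(spec.grid_shape), tuple(spec.spacing_mm)
    voxel_mm3 = float(np.prod(spacing))

    xx, yy, zz = _world_coords(shape, spacing)
    axes = _brain_semi_axes(shape, spacing)
    rho = np.sqrt((xx / axes[0]) ** 2 + (yy / axes[1]) ** 2 + (zz / axes[2]) ** 2)
    brain = rho <= 1.0
    labels = np.zeros(shape, dtype=np.int16)
    labels[brain & (rho > 0.82)] = _TC.GRAY_MATTER
    labels[brain & (rho <= 0.82)] = _TC.WHITE_MATTER

    # --- lesion placement: rank brain voxels by perturbed distance ---
    n_gtv = int(round(spec.gtv_volume_cm3 * 1000.0 / voxel_mm3))
    if n_gtv < 8:
        raise GeometryInfeasibleError("GTV smaller than a few voxels at this resolution")
    if n_gtv > int(brain.sum() * 0.8):
        raise GeometryInfeasibleError("GTV would exceed 80% of the brain volume")
    r_lesion = (3.0 * n_gtv * voxel_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    centre = _lesion_centre(spec, axes, r_lesion)

    dist = np.sqrt((xx - centre[0]) ** 2 + (yy - centre[1]) ** 2 + (zz - centre[2]) ** 2)
    if spec.boundary_perturbation > 0:
        bump = _smooth_unit_field(shape, 3.0 * spec.texture_corr_vox, rng)
        dist = dist * (1.0 + spec.boundary_perturbation * np.clip(bump, -2.0, 2.0) * 0.25)
    dist_brain = np.where(brain, dist, np.inf)
    flat = np.argsort(dist_brain, axis=None)[:n_gtv]
    gtv_idx = np.unravel_index(flat, shape)
    gtv = np.zeros(shape, dtype=bool)
    gtv[gtv_idx] = True

    n_core = int(round(spec.high_perfusion_fraction * n_gtv))
    if n_core < 1 or n_core >= n_gtv:
        # explicit failure rather than silently truncating the fraction
        raise GeometryInfeasibleError(
            f"high_perfusion_fraction {spec.high_perfusion_fraction} not resolvable "
            f"on a {n_gtv}-voxel GTV at this resolution"
        )
    flat_core = np.argsort(np.where(gtv, dist, np.inf), axis=None)[:n_core]
    core = np.zeros(shape, dtype=bool)
    core[np.unravel_index(flat_core, shape)] = True

    labels[gtv] = _TC.EDEMA
    labels[core] = _TC.TUMOR_HIGH_PERFUSION

    if spec.include_cyst:
        # a small exclusion pocket at the core/edema interface
        n_cyst = max(1, n_gtv // 50)
        edge = np.argsort(np.where(gtv & ~core, dist, np.inf), axis=None)[:n_cyst]
        labels[np.unravel_index(edge, shape)] = _TC.CYST_NECROSIS

    label_map = LabelMap(labels, spacing=spacing)

    # --- ground-truth CBF with smooth within-class texture ---
    cbf = np.zeros(shape, dtype=np.float64)
    for cls, value in spec.cbf_true.items():
        cbf[labels == cls] = value
    if spec.texture_rel_sd > 0:
        texture = _smooth_unit_field(shape, spec.texture_corr_vox, rng)
        cbf = cbf * (1.0 + spec.texture_rel_sd * np.clip(texture, -3.0, 3.0))
    np.clip(cbf, 0.0, None, out=cbf)
    cbf[labels == _TC.BACKGROUND] = 0.0
    cbf_truth = ImageVolume(cbf, spacing=spacing, intensity_units=UNITS_CBF)

    # --- structural sequences ---
    bias = 1.0
    if spec.bias_amplitude > 0:
        bias = 1.0 + spec.bias_amplitude * (xx / (shape[0] * spacing[0] / 2.0))
    structurals: dict[str, ImageVolume] = {}
    for seq in STRUCTURAL_SEQUENCES:
        means = spec.structural_means[seq]
        img = np.zeros(shape, dtype=np.float64)
        for cls, value in means.items():
            img[labels == cls] = value
        if spec.texture_rel_sd > 0:
            texture = _smooth_unit_field(shape, spec.texture_corr_vox, rng)
            img = img * (1.0 + spec.texture_rel_sd * np.clip(texture, -3.0, 3.0))
        img = img * bias + rng.normal(0.0, spec.noise_sd.get(seq, 0.0), shape)
        img[labels == _TC.BACKGROUND] = np.clip(img[labels == _TC.BACKGROUND], 0.0, None)
        structurals[seq] = ImageVolume(img, spacing=spacing)

    asl = simulate_asl(
        cbf_truth,
        label_map,
        params=AcquisitionParams(),
        m0_value=spec.m0_value,
        noise_sd=spec.asl_noise_sd,
        seed=int(rng.integers(0, 2**31 - 1)),
    )

    return SubjectBundle(
        subject_id=f"sub-{spec.seed:08d}",
        spec=spec,
        labels=label_map,
        cbf_truth=cbf_truth,
        structurals=structurals,
        asl=asl,
    )


def simulate_asl(
    cbf_truth: ImageVolume,
    labels: LabelMap,
    params: AcquisitionParams | None = None,
    m0_value: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    baseline_gain: float = 1.0,
) -> ASLTriplet:
    """Forward-simulate a control/label/M0 triplet from true CBF.

    Inverts the quantification model exactly: the perfusion-weighted
    difference is ``dS = cbf_truth * SI_PD / scale`` with ``scale`` the
    closed-form CBF-per-unit-(dS/SI_PD) constant, and::

        control = baseline + dS/2 + noise,   label = baseline - dS/2 + noise

    with ``baseline = baseline_gain * SI_PD`` inside the head and zero
    outside.  With ``noise_sd = 0`` the quantification inverse recovers
    ``cbf_truth`` to numerical precision.
    """
    params = params or AcquisitionParams()
    if (cbf_truth.data < 0).any():
        raise ValueError("phantom CBF truth must be non-negative")
    if cbf_truth.intensity_units != UNITS_CBF:
        raise ValueError("cbf_truth must carry ml_per_100g_per_min units")
    rng = np.random.default_rng(seed)
    head = labels.data != _TC.BACKGROUND
    m0_data = np.where(head, float(m0_value), 0.0)
    scale = cbf_scale_factor(params)
    delta = cbf_truth.data * m0_data / scale
    baseline = baseline_gain * m0_data
    control = baseline + delta / 2.0
    label = baseline - delta / 2.0
    if noise_sd > 0:
        control = control + rng.normal(0.0, noise_sd, control.shape)
        label = label + rng.normal(0.0, noise_sd, label.shape)

    def _vol(data: np.ndarray) -> ImageVolume:
        return ImageVolume(
            data,
            spacing=cbf_truth.spacing,
            origin=cbf_truth.origin,
            axis_codes=cbf_truth.axis_codes,
        )

    return ASLTriplet(control=_vol(control), label=_vol(label), m0=_vol(m0_data))


def draw_cohort_parameters(spec: CohortSpec) -> pd.DataFrame:
    """Draw the per-subject ground-truth parameters of a cohort (no images).

    Tissue CBF means are ``population mean x shared subject factor x
    tissue residual`` (residual variability shrunk so each marginal SD
    matches its configured distribution); with ``subject_factor_sd = 0``
    tissues are drawn independently.  High-perfusion and edema draws are
    redrawn jointly until the core exceeds the edema value (the construct
    being modelled); the small conditioning shift this induces is
    documented in the methods note.  Deterministic given ``master_seed``.
    """
    root = np.random.SeedSequence(spec.master_seed)
    children = root.spawn(spec.n_subjects + 1)
    draw_rng = np.random.default_rng(children[0])

    def _tissue_draw(dist: TruncatedNormal, g: float) -> float:
        cv = dist.sd / dist.mean
        resid_cv = np.sqrt(max(cv**2 - spec.subject_factor_sd**2, 0.0))
        for _ in range(100):
            value = dist.mean * g * (1.0 + resid_cv * draw_rng.standard_normal())
            if dist.low < value < dist.high:
                return float(value)
        return float(np.clip(dist.mean * g, dist.low + 1e-6, dist.high - 1e-6))

    rows = []
    for i in range(spec.n_subjects):
        gtv_vol = float(spec.gtv_volume_cm3.sample(draw_rng))
        fraction = float(spec.high_perfusion_fraction.sample(draw_rng))
        if spec.subject_factor_sd > 0:
            g_factor = float(
                TruncatedNormal(1.0, spec.subject_factor_sd, 0.5, 1.5).sample(draw_rng)
            )
            sample_high = lambda: _tissue_draw(spec.cbf_high, g_factor)  # noqa: E731
            sample_edema = lambda: _tissue_draw(spec.cbf_edema, g_factor)  # noqa: E731
            cbf_gm = _tissue_draw(spec.cbf_gm, g_factor)
            cbf_wm = _tissue_draw(spec.cbf_wm, g_factor)
        else:
            g_factor = 1.0
            sample_high = lambda: float(spec.cbf_high.sample(draw_rng))  # noqa: E731
            sample_edema = lambda: float(spec.cbf_edema.sample(draw_rng))  # noqa: E731
            cbf_gm = float(spec.cbf_gm.sample(draw_rng))
            cbf_wm = float(spec.cbf_wm.sample(draw_rng))
        for _ in range(1000):
            cbf_high = sample_high()
            cbf_edema = sample_edema()
            if cbf_high > cbf_edema:
                break
        else:  # pragma: no cover - only reachable with pathological configs
            raise ValueError("could not draw cbf_high > cbf_edema; check distributions")
        laterality = LATERALITIES[draw_rng.choice(3, p=spec.laterality_probs)]
        subj_seed = int(children[i + 1].generate_state(1)[0] % (2**31 - 1))
        rows.append({
            "subject_id": f"sub-{i + 1:03d}",
            "seed": subj_seed,
            "subject_factor": g_factor,
            "laterality": laterality,
            "gtv_volume_cm3": gtv_vol,
            "high_perfusion_fraction": fraction,
            "cbf_true_high": cbf_high,
            "cbf_true_edema": cbf_edema,
            "cbf_true_gm": cbf_gm,
            "cbf_true_wm": cbf_wm,
        })
    return pd.DataFrame(rows)


def generate_cohort(spec: CohortSpec) -> tuple[list[SubjectBundle], pd.DataFrame]:
    """Generate a full cohort of subject bundles plus the ground-truth manifest.

    Per-subject seeds come from a splittable seed stream rooted at
    ``master_seed``, so identical CohortSpecs reproduce identical cohorts
    bit for bit.
    """
    manifest = draw_cohort_parameters(spec)
    bundles: list[SubjectBundle] = []
    for row in manifest.itertuples():
        cbf_true = dict(DEFAULT_CBF_TRUE)
        cbf_true.update({
            _TC.WHITE_MATTER: row.cbf_true_wm,
            _TC.GRAY_MATTER: row.cbf_true_gm,
            _TC.EDEMA: row.cbf_true_edema,
            _TC.TUMOR_HIGH_PERFUSION: row.cbf_true_high,
        })
        subj = SubjectSpec(
            gtv_volume_cm3=row.gtv_volume_cm3,
            high_perfusion_fraction=row.high_perfusion_fraction,
            cbf_true=cbf_true,
            laterality=row.laterality,
            seed=int(row.seed),
            **spec.subject_overrides,
        )
        bundle = generate_subject(subj)
        bundle.subject_id = row.subject_id
        bundles.append(bundle)
    return bundles, manifest
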