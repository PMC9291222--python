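# Methods

`aslsubvol` quantifies perfusion sub-volumes of non-enhancing low-grade
glioma (NE-LGG) radiotherapy targets from 3D arterial spin labeling (ASL)
MRI, and validates every stage of that analysis on a synthetic cohort with
known ground truth. This note documents the models, the parameters that
matter, the numerical conventions, and what the synthetic experiments do
and do not demonstrate.

## 1. CBF quantification

ASL control/label/M0 triplets are converted to cerebral blood flow (CBF)
with the single-compartment pCASL model

```
CBF = 6000 · λ · (SI_control − SI_label) · e^(PLD/T1b)
      ─────────────────────────────────────────────────   [ml/100 g/min]
      2 · α · T1b · SI_PD · (1 − e^(−τ/T1b))
```

with all times in seconds (the factor 6000 converts ml/g/s to
ml/100 g/min, which is why millisecond config inputs are converted
internally). Defaults are the 3-T clinical protocol constants:

| parameter | meaning | default | unit |
|---|---|---|---|
| λ | brain/blood partition coefficient | 0.9 | ml/g |
| α | labeling efficiency | 0.85 | – |
| τ | label duration | 1.5 | s |
| PLD | post-labeling delay | 2.025 | s |
| T1b | longitudinal relaxation of blood | 1.65 | s |

Voxels whose M0 falls below 5% of the median positive M0 are flagged
invalid rather than quantified (the vendor masking rule is not public;
this floor is our choice and is configurable). Negative CBF values
produced by noise are kept by default so QC statistics stay unbiased;
clipping is a flag.

The phantom's forward ASL simulator is the exact algebraic inverse of
this equation plus additive Gaussian noise on control and label, so the
noiseless forward→inverse round trip is an equality test (asserted to
1e−9 relative), not an approximation.

## 2. Synthetic cohort

Each subject is a parametric digital head phantom on one shared lattice
(default 64×64×48 voxels at 3 mm isotropic): a brain ellipsoid with a
gray-matter shell over a white-matter core, and a lesion consisting of a
high-perfusion tumor core nested inside peritumoral edema. Geometry is
deliberately schematic — every downstream quantity is region-statistical,
so class topology (core ⊂ GTV ⊂ brain) is what matters, not anatomy.
Lesion voxels are selected in order of (smoothly perturbed) distance from
the lesion centre, so the prescribed GTV volume and core volume fraction
are honoured to within a voxel. Laterality (unilateral / midline /
bilateral, mixed 7:5:3) moves the lesion centre; unilateral lesions are
pulled toward the midline only as far as needed to fit.

Per-subject ground truth is drawn from the emulated population:

* GTV volume ~ N(167.46, 209.64) cm³ truncated to [10, 400] cm³ (upper
  bound: must fit the phantom brain of ≈1.5 l);
* high-perfusion volume fraction ~ N(0.3708, 0.1788) truncated to
  (0.02, 0.95);
* tissue CBF means (ml/100 g/min): high-perfusion core N(66.98, 18.03),
  edema N(35.19, 7.75), normal gray matter N(33.92, 8.48), white matter
  N(22, 4), all truncated below at 5.

**Within-patient correlation.** Tissue perfusion values of one patient
are not independent: global perfusion varies with age and physiology,
which is the very reason relative CBF (rCBF, normalised by normal gray
matter) is used clinically. The reported region statistics imply an
inter-tissue correlation of ≈0.5 (both from the paired test statistics
and from comparing the absolute and relative population rows). The
generator therefore draws each tissue mean as

```
population mean × g_s × (1 + ε_tissue),   g_s ~ N(1, 0.167) truncated to [0.5, 1.5]
```

with the tissue residual SD shrunk so each *marginal* still matches its
configured row. At large n this reproduces rCBF(core) = 2.09 ± 0.62 and
rCBF(edema) = 1.08 ± 0.28 against the emulated 2.03 ± 0.53 and
1.08 ± 0.32, and an implied paired t ≈ 8.2 at n = 15 (reported: 7.93).
Setting `subject_factor_sd = 0` restores independent draws. Core/edema
pairs violating the defining invariant (core > edema) are redrawn
jointly; with the correlated model this rejects ≈2% of pairs and shifts
the effective core mean by under +1 ml/100 g/min.

Within each tissue class, CBF and structural intensities carry a smooth
correlated texture (10% relative SD, correlation length 2 voxels) so that
texture features are non-degenerate; maps are otherwise constant per
class. Structural sequences (T1WI, T2 Propeller, T2 Flair, CE-T1WI) use
fixed class-mean intensities chosen for the qualitative disease
contrasts: the whole GTV is Flair-hyperintense ≈3 SD above normal brain,
and CE-T1WI equals plain T1WI in the lesion (non-enhancing). ASL noise
defaults to 0.2 a.u. on control and label at SI_PD = 1000, i.e. a
voxel-level CBF noise of ≈3 ml/100 g/min — typical of clinical smoothed
pCASL maps.

**What the phantom does not emulate:** arterial transit-time effects,
partial-volume mixing, motion, k-space artifacts, realistic anatomy, and
infiltrative (non-compact) tumor growth. Passing recovery tests therefore
shows the *pipeline* is unbiased under the stated population model, not
that the thresholds would transfer unchanged to scanner data.

## 3. Target delineation and sub-volume segmentation

The GTV is the Flair-hyperintense abnormality: two-pass thresholding at
μ + 2σ of normal brain (μ, σ re-estimated excluding the candidate
lesion), largest 26-connected component, holes filled. On the phantom
this recovers the true GTV with Dice ≥ 0.95.

The high-perfusion sub-volume GTV-ASL is carved from the GTV by a CBF
threshold rule followed by morphological cleanup (closing radius one
voxel, restricted to the eligible set; components < 0.1 cm³ dropped);
GTV-SUB is the set difference, and cysts/necrosis/vessels are excluded
from GTV-ASL. Both cleanup steps are increasing operators, so raising the
threshold can never grow GTV-ASL. Four rules are available:

* `absolute:t` — fixed cut-off; default `t = 44.16` ml/100 g/min, the
  ROC-derived operating point for discriminating high- from low-perfusion
  regions. This is the package default.
* `relative:r` — `r ×` a gray-matter reference mean (`r = 1.49` is the
  corresponding rCBF operating point).
* `percentile:p` — within-GTV percentile.
* `otsu` — subject-adaptive: the Otsu threshold of the within-GTV CBF
  histogram.

**Which rule for which question.** The clinical construct "high-perfusion
area" is *within-patient*: it was contoured visually as the locally
bright part of the lesion on the CBF map. A fixed absolute cut-off is the
right operating point for *classifying regions across patients* (that is
what the 44.16 figure is), but it is a biased estimator of the
within-patient construct when whole-patient perfusion varies: with the
population rows above, ≈12% of edema draws exceed 44.16 outright
(consistent with the reported ≈93% specificity of that cut-off), which
inflates the measured GTV-ASL/GTV volume ratio by roughly +10 percentage
points and dilutes sub-volume CBF statistics. The adaptive `otsu` rule
estimates the within-GTV split independently of the global level and
recovers the ground-truth sub-volumes essentially unbiased in CBF terms
(core Dice ≈ 0.9 at the default noise level); the measured volume ratio
retains a small systematic excess of ≈ +2 percentage points over the
drawn fraction (the morphological closing only ever adds voxels, and the
histogram split point sits slightly low for unequal cluster weights — a
two-component Gaussian mixture was evaluated and reduces this by only a
fraction of a point), plus ≈ +1 point from truncating the fraction
distribution to (0.02, 0.95). Both components sit well inside the 2-SE
acceptance band of a 30-subject cohort. The cohort-recovery experiments
(`scripts/acceptance.py` and `tests/test_acceptance.py`) therefore use
`otsu`; the absolute rule remains the default for prospective use, where
a fixed, externally specified threshold is operationally desirable.

**ROIs.** Measurement ROIs are single-slice discs (areas 100–150 mm²,
default request 120 mm²) on the axial slice whose mean GTV-ASL perfusion
is highest: ROI-T on the CBF peak within GTV-ASL; four ROI-E discs in
GTV-SUB at 90° spacing around the GTV-ASL centroid (fewer, with a
warning, if they cannot fit at ≥100 mm²); ROI-N in normal gray matter at
the mirror of the lesion centroid across the lattice mid-sagittal plane
for unilateral lesions, else at a fixed standard gray-matter site. The
angular placement of the edema ROIs and the ROI-T area are conventions of
this package (the source protocol does not fix them).

Absolute statistics (CBF max/min/mean) are computed over regions of the
unsmoothed quantified map; relative values divide by the ROI-N mean.

## 4. Radiomics

107 features per (sequence, region): 14 shape, 18 first-order, 24 GLCM,
14 GLDM, 16 GLRLM, 16 GLSZM, 5 NGTDM, under the naming of the widely used
open-source extractor canon (`firstorder_10Percentile`, …). Five
sequences (T1WI, T2 Propeller, T2 Flair, CE-T1WI, ASL/CBF) give 535
columns; shape features are mask-only and identical across sequences but
are replicated to match that published count (`dedupe_shape=True`
deduplicates).

Conventions that matter for reproducibility:

* Discretization — fixed bin width 25 a.u. for structural sequences,
  fixed bin count 32 for CBF maps (the source protocol does not state its
  settings; these are flagged defaults, and the config hash is stored in
  the feature table).
* GLCM — 13 unique distance-1 directions, symmetrised and *summed into a
  single matrix before* feature computation.
* GLRLM — runs along the same 13 directions; out-of-region voxels break
  runs.
* GLSZM — 26-connected zones. GLDM — α = 0, dependence = 1 + number of
  equal-level 26-neighbours (the centre voxel counts itself, so the
  emphasis weights are never divided by zero). NGTDM — 26-neighbourhood
  means; voxels with no in-region neighbour are excluded.
* Empty gray levels are dropped; the surviving bin numbers are the level
  values in the formulas; `Ng` in normalised features is the number of
  levels present.
* First-order Entropy/Uniformity use the discretized histogram (log base
  2); percentiles interpolate linearly; Variance/Skewness/Kurtosis are
  population moments, Kurtosis is not excess-corrected.
* Shape — mesh volume and surface area from a marching-cubes
  triangulation of the 0.5 iso-surface (a voxelised cube therefore reads
  a few percent under its nominal surface area); axis lengths are
  4·√eigenvalue of the physical coordinate covariance; diameters are
  maximum voxel-centre distances (via convex hull for large regions).
* Degenerate regions produce defined conventions, not missing values:
  a one-level matrix has Correlation = MCC = 1, a single voxel has zero
  diameters and Elongation/Flatness 1, zero gray-tone difference caps
  Coarseness at 1e6.

With no reference extractor available as a dependency, correctness is
established by dual routes inside the test suite: brute-force pairwise /
neighbourhood enumerations recompute every matrix on random fixtures, and
closed forms (cube, sphere, textbook percentile) pin the shape and
first-order features.

## 5. Feature selection

Features are min-max scaled to [0, 1] per column (constant columns map to
0 and are flagged). The variance pre-filter quotes its threshold in the
Bernoulli convention of the common feature-selection API: level p = 0.8
means an effective numeric threshold p(1−p) = 0.16 — a [0, 1]-bounded
variable cannot exceed variance 0.25, so a literal 0.8 would discard
everything. A raw-threshold mode is config-selectable.

Selection is L1-penalised logistic regression minimising
`mean log-loss + λ·Σ|β|` (intercept unpenalised) over a descending grid
of 100 log-spaced λ (10⁰ → 10^−2.5; λ_max for scaled features is ≤ 0.5).
λ is tuned by stratified five-fold cross-validation on misclassification
error with a fixed seed; ties resolve to the larger λ (sparser model);
the model is refit on all data at the optimum and non-zero coefficients
are the selected features. The solver is scikit-learn's saga with warm
starts along the path (tol 1e−5 on the CV path, 1e−7 for the final
refits); an independent proximal-gradient solver in the tests confirms
the selected support and coefficients.

## 6. ROC and paired statistics

AUC is the Mann–Whitney estimate (ties counted ½), identical by
construction to the trapezoidal area under the empirical curve (asserted
to 1e−12). The operating point maximises Youden's J over observed
thresholds and is reported as the midpoint of the bracketing observed
values (sub-resolution difference from observed-value reporting; ties
take the lowest midpoint). Sensitivity is defined on the high-perfusion
class. Paired comparisons gate on a Shapiro–Wilk test of the paired
differences at α = 0.05: paired t if normal, Wilcoxon signed-rank
otherwise; all-zero differences return a degenerate record.

## 7. Problem sizes and reproduction

The recovery experiments use 30 subjects on the default 3 mm lattice —
large enough that cohort means are dominated by the population draws, and
a full end-to-end run takes seconds on one core — and 10⁴ draws per class
for the large-sample AUC checks (Monte-Carlo SE ≈ 0.003). Acceptance
bands are two standard errors of the cohort mean for the recovery
statistics, ±0.2 for the rCBF ratio (the ratio-of-correlated-normals
estimator carries an intrinsic bias of order cv²(GM) ≈ +0.06), and ±0.05
for the AUCs (cross-checked against the binormal closed form
Φ(Δμ/√(σ₁²+σ₂²))). Every random quantity descends from a single master
seed through a splittable seed stream; identical configs reproduce
identical cohorts bit for bit.

## 8. Known limitations

* Single-PLD quantification only; no transit-time or partial-volume
  correction.
* Registration/MNI normalisation are interface contracts, not
  implementations: all volumes of a subject must share one lattice.
* Bias-field correction is a log-domain polynomial fit (default degree
  2) intended for multiplicative-field flattening on phantoms, not a
  replacement for a full clinical bias-correction algorithm; the
  interface accepts an externally corrected volume.
* The phantom's schematic geometry means shape features separate regions
  mostly by size; conclusions about shape-feature discriminative power on
  real lesions cannot be drawn from these simulations.
* The 2-SE acceptance bands are stochastic: a single unlucky cohort draw
  (≈5% per statistic) can fall outside them without indicating a defect.
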