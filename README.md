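# aslsubvol

Perfusion-guided sub-volume analysis of non-enhancing low-grade glioma
(NE-LGG) radiotherapy targets from 3D arterial spin labeling (ASL) MRI —
with a fully synthetic, ground-truthed phantom cohort for validating
every stage.

Non-enhancing low-grade gliomas show no gadolinium enhancement; their
radiotherapy target (the gross tumor volume, GTV) is usually the whole
T2-Flair hyperintensity, which lumps tumor together with peritumoral
edema and is often very large. ASL perfusion MRI quantifies cerebral
blood flow (CBF, ml/100 g/min) without contrast agent, and within these
lesions the tumor-enriched core is roughly twice as perfused as the
surrounding edema or normal gray matter. `aslsubvol` implements the
analysis built on that observation, for imaging scientists and
radiotherapy researchers:

1. **CBF quantification** from control/label/M0 triplets with the
   single-compartment pCASL model
   `CBF = 6000·λ·ΔS·e^(PLD/T1b) / (2·α·T1b·SI_PD·(1−e^(−τ/T1b)))`
   (λ = 0.9 ml/g, α = 0.85, τ = 1.5 s, PLD = 2.025 s, T1b = 1.65 s by
   default);
2. **sub-volume segmentation**: the Flair-defined GTV is split into a
   high-perfusion `GTV-ASL` and its low-perfusion complement `GTV-SUB`
   by a CBF threshold rule (fixed absolute cut-off 44.16 ml/100 g/min,
   relative rCBF ≥ 1.49 × gray matter, percentile, or subject-adaptive
   Otsu), plus protocol ROIs and absolute/relative CBF statistics;
3. **multi-sequence radiomics**: 107 features (shape, first-order,
   GLCM/GLDM/GLRLM/GLSZM/NGTDM) per region per sequence — 535 columns
   over T1WI, T2 Propeller, T2 Flair, CE-T1WI and ASL;
4. **feature selection**: [0,1] scaling, variance pre-filter,
   L1-penalised logistic regression (LASSO) with five-fold
   cross-validated λ;
5. **evaluation**: Mann–Whitney AUC, Youden-index cut-offs, and
   Shapiro–Wilk-gated paired comparisons;
6. **a phantom cohort generator** that emulates the study population the
   pipeline was built for (tissue CBF, GTV volumes and high-perfusion
   fractions drawn from published distributions) so that every number
   the pipeline produces can be checked against known truth.

See `docs/methods.md` for the models, conventions and their rationale.

## Worked example

```python
from aslsubvol import (SubjectSpec, generate_subject, compute_cbf, delineate_gtv,
                       segment_gtv_asl, place_rois, perfusion_stats, ThresholdRule)

subject = generate_subject(SubjectSpec(gtv_volume_cm3=120.0,
                                       high_perfusion_fraction=0.37, seed=11))
cbf = compute_cbf(subject.asl)                      # quantify perfusion
gtv = delineate_gtv(subject.structurals["T2_Flair"], subject.brain_mask)
targets = segment_gtv_asl(cbf, gtv, rule=ThresholdRule("absolute", 44.16))
rois = place_rois(cbf, targets, subject.gm_mask, laterality="unilateral")
high = perfusion_stats(cbf, targets.gtv_asl, rois.roi_n)
edema = perfusion_stats(cbf, targets.gtv_sub, rois.roi_n)

print(f"GTV {targets.gtv.volume_cm3:.1f} cm3, "
      f"GTV-ASL {targets.gtv_asl.volume_cm3:.1f} cm3 "
      f"({100*targets.gtv_asl.volume_cm3/targets.gtv.volume_cm3:.1f}%)")
print(f"high-perfusion CBF_mean {high.cbf_mean:.1f} ml/100g/min "
      f"(rCBF {high.r_cbf_mean:.2f})")
print(f"edema CBF_mean {edema.cbf_mean:.1f} ml/100g/min "
      f"(rCBF {edema.r_cbf_mean:.2f})")
```

prints

```
GTV 119.7 cm3, GTV-ASL 48.8 cm3 (40.8%)
high-perfusion CBF_mean 68.0 ml/100g/min (rCBF 1.92)
edema CBF_mean 35.4 ml/100g/min (rCBF 1.00)
```

The phantom was built with a 37% high-perfusion fraction and tissue CBF
of 67 / 35 / 34 ml/100 g/min (core / edema / gray matter): the pipeline
recovers the GTV from the Flair hyperintensity, finds a high-perfusion
sub-volume close to the planted core (the fixed 44.16 cut-off slightly
over-segments this subject — the ratio reads 40.8% against the planted
37%), and measures the roughly two-fold core-to-edema perfusion contrast
the sub-volume split is based on.

## Command line

```bash
aslsubvol run -c config.yaml                 # full cohort pipeline from YAML
aslsubvol quantify --control c.nii.gz --label l.nii.gz --m0 m0.nii.gz --out cbf.nii.gz
aslsubvol segment --cbf cbf.nii.gz --gtv gtv.nii.gz --rule absolute:44.16 --out-dir seg/
aslsubvol select --table features.csv --out selected.json
```

`aslsubvol run` writes per-subject NIfTI volumes and masks, the cohort
manifest and statistics CSVs, the 535-column feature table, selection
and ROC results, figures and a `report.json`, all reproducible bit for
bit from the config and master seed.

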