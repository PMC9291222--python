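"""End-to-end orchestration: simulate -> quantify -> segment -> extract -> select -> evaluate.

A run is fully described by a :class:`RunConfig` (parsed and validated
from YAML by :func:`validate_config`); given the same config and master
seed it reproduces every output.  ``run_cohort_analysis`` is the
perfusion core (generation through region statistics) shared by the CLI,
the tests and the acceptance tooling; ``run_pipeline`` adds radiomics
extraction, LASSO selection, ROC evaluation and artefact writing.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .asl_quant import AcquisitionParams, compute_cbf, qc_summary
from .core_io import write_mask, write_nifti
from .evaluation import evaluate_discriminators, plot_roc
from .phantom import CohortSpec, SubjectBundle, TruncatedNormal, generate_cohort
from .radiomics import DiscretizationConfig, extract_table
from .radiomics.table import REGION_HIGH, REGION_LOW
from .selection import SelectionConfig, lasso_select
from .subvolume import (
    ThresholdRule,
    delineate_gtv,
    perfusion_stats,
    place_rois,
    segment_gtv_asl,
)

__all__ = ["RunConfig", "ConfigError", "validate_config", "run_cohort_analysis", "run_pipeline"]

logger = logging.getLogger("aslsubvol")


class ConfigError(ValueError):
    """A configuration file failed validation; the message names the field."""


@dataclass
class RunConfig:
    """Validated, fully-defaulted description of one pipeline run."""

    cohort: CohortSpec = dc_field(default_factory=CohortSpec)
    acquisition: AcquisitionParams = dc_field(default_factory=AcquisitionParams)
    rule: ThresholdRule = dc_field(default_factory=ThresholdRule)
    min_component_cm3: float = 0.1
    roi_area_mm2: float = 120.0
    discretization: dict[str, DiscretizationConfig] = dc_field(default_factory=dict)
    selection: SelectionConfig = dc_field(default_factory=SelectionConfig)
    output_dir: Path = Path("aslsubvol_run")
    master_seed: int = 0
    extract_features: bool = True
    save_nifti: bool = True


_DIST_FIELDS = ("gtv_volume_cm3", "high_perfusion_fraction", "cbf_high", "cbf_edema", "cbf_gm", "cbf_wm")
_KNOWN_TOP = {"cohort", "acquisition", "segmentation", "discretization", "selection",
              "output_dir", "master_seed", "run"}


def _dist(node: dict, path: str, default: TruncatedNormal) -> TruncatedNormal:
    if not isinstance(node, dict):
        raise ConfigError(f"{path}: expected a mapping with mean/sd[/low/high]")
    try:
        return TruncatedNormal(
            mean=float(node.get("mean", default.mean)),
            sd=float(node.get("sd", default.sd)),
            low=float(node.get("low", default.low)),
            high=float(node.get("high", default.high)),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def validate_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration.

    Missing blocks take the documented defaults (and are logged); every
    violated cross-field constraint is reported with its field path;
    unknown keys warn but do not fail (forward compatibility).
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("top level: expected a mapping")
    for key in raw:
        if key not in _KNOWN_TOP:
            warnings.warn(f"unknown config key {key!r} ignored", RuntimeWarning, stacklevel=2)

    cfg = RunConfig()
    cohort_node = raw.get("cohort", {})
    defaults = CohortSpec()
    try:
        kwargs = {"n_subjects": int(cohort_node.get("n_subjects", defaults.n_subjects)),
                  "master_seed": int(raw.get("master_seed", 0))}
        for name in _DIST_FIELDS:
            if name in cohort_node:
                kwargs[name] = _dist(cohort_node[name], f"cohort.{name}", getattr(defaults, name))
        if "subject" in cohort_node:
            sub = dict(cohort_node["subject"])
            if "grid_shape" in sub:
                sub["grid_shape"] = tuple(int(v) for v in sub["grid_shape"])
            if "spacing_mm" in sub:
                sub["spacing_mm"] = tuple(float(v) for v in sub["spacing_mm"])
            kwargs["subject_overrides"] = sub
        cfg.cohort = CohortSpec(**kwargs)
    except ConfigError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"cohort: {exc}") from exc

    if "acquisition" in raw:
        try:
            cfg.acquisition = AcquisitionParams.from_config(raw["acquisition"])
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"acquisition: {exc}") from exc
    else:
        logger.info("acquisition block missing; using protocol defaults %s", cfg.acquisition)

    seg = raw.get("segmentation", {})
    try:
        rule = seg.get("rule", "absolute:44.16")
        cfg.rule = ThresholdRule.parse(rule, gm_reference=seg.get("gm_reference")) \
            if isinstance(rule, str) else ThresholdRule(**rule)
        cfg.min_component_cm3 = float(seg.get("min_component_cm3", 0.1))
        cfg.roi_area_mm2 = float(seg.get("roi_area_mm2", 120.0))
        if not (100.0 <= cfg.roi_area_mm2 <= 150.0):
            raise ConfigError("segmentation.roi_area_mm2: must lie in [100, 150]")
    except ConfigError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"segmentation: {exc}") from exc

    for seq, node in raw.get("discretization", {}).items():
        try:
            cfg.discretization[seq] = DiscretizationConfig(**node)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"discretization.{seq}: {exc}") from exc

    if "selection" in raw:
        try:
            node = dict(raw["selection"])
            if "lambda_grid" in node:
                node["lambda_grid"] = np.asarray(node["lambda_grid"], dtype=float)
            node.setdefault("seed", int(raw.get("master_seed", 0)))
            cfg.selection = SelectionConfig(**node)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"selection: {exc}") from exc
    else:
        cfg.selection = SelectionConfig(seed=int(raw.get("master_seed", 0)))

    run = raw.get("run", {})
    cfg.extract_features = bool(run.get("extract_features", True))
    cfg.save_nifti = bool(run.get("save_nifti", True))
    cfg.output_dir = Path(raw.get("output_dir", "aslsubvol_run"))
    cfg.master_seed = int(raw.get("master_seed", 0))
    return cfg


# ---------------------------------------------------------------------------
# the perfusion core
# ---------------------------------------------------------------------------

def analyze_subject(
    bundle: SubjectBundle,
    params: AcquisitionParams,
    rule: ThresholdRule,
    min_component_cm3: float = 0.1,
    roi_area_mm2: float = 120.0,
) -> dict:
    """Quantify, delineate, segment and measure one subject.

    Returns a flat record of volumes, absolute/relative CBF statistics and
    QC numbers, plus the intermediate objects under ``"_objects"``.
    """
    cbf = compute_cbf(bundle.asl, params=params)
    gtv = delineate_gtv(bundle.structurals["T2_Flair"], bundle.brain_mask)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        targets = segment_gtv_asl(
            cbf, gtv, exclusion=bundle.exclusion, rule=rule, min_component_cm3=min_component_cm3
        )
    qc = qc_summary(cbf, bundle.brain_mask)

    row: dict = {
        "subject_id": bundle.subject_id,
        "laterality": bundle.spec.laterality,
        "gtv_cm3": targets.gtv.volume_cm3,
        "gtv_asl_cm3": targets.gtv_asl.volume_cm3,
        "gtv_sub_cm3": targets.gtv_sub.volume_cm3,
        "volume_ratio_pct": 100.0 * targets.gtv_asl.volume_cm3 / targets.gtv.volume_cm3,
        "qc_fraction_negative": qc["fraction_negative"],
        "qc_fraction_invalid": qc["fraction_invalid"],
    }
    truth_core = bundle.core_truth
    inter = (targets.gtv.data & bundle.gtv_truth.data).sum()
    row["gtv_dice_vs_truth"] = 2.0 * inter / (targets.gtv.n_voxels + bundle.gtv_truth.n_voxels)

    if targets.gtv_asl.is_empty():
        for key in ("acbf_max", "acbf_min", "acbf_mean", "rcbf_max", "rcbf_min", "rcbf_mean",
                    "edema_acbf_mean", "edema_rcbf_mean", "gm_roi_acbf_mean"):
            row[key] = np.nan
        row["_objects"] = {"cbf": cbf, "targets": targets, "rois": None}
        return row

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rois = place_rois(
            cbf, targets, bundle.gm_mask, laterality=bundle.spec.laterality, area_mm2=roi_area_mm2
        )
    high = perfusion_stats(cbf, targets.gtv_asl, rois.roi_n)
    edema = perfusion_stats(cbf, targets.gtv_sub, rois.roi_n)
    row.update({
        "acbf_max": high.cbf_max,
        "acbf_min": high.cbf_min,
        "acbf_mean": high.cbf_mean,
        "rcbf_max": high.r_cbf_max,
        "rcbf_min": high.r_cbf_min,
        "rcbf_mean": high.r_cbf_mean,
        "edema_acbf_mean": edema.cbf_mean,
        "edema_rcbf_mean": edema.r_cbf_mean,
        "gm_roi_acbf_mean": high.reference_gm_mean,
        "core_dice_vs_truth": 2.0 * (targets.gtv_asl.data & truth_core.data).sum()
        / (targets.gtv_asl.n_voxels + truth_core.n_voxels),
    })
    row["_objects"] = {"cbf": cbf, "targets": targets, "rois": rois}
    return row


def run_cohort_analysis(
    bundles: list[SubjectBundle],
    params: AcquisitionParams | None = None,
    rule: ThresholdRule | None = None,
    min_component_cm3: float = 0.1,
    roi_area_mm2: float = 120.0,
    keep_objects: bool = False,
) -> pd.DataFrame:
    """The perfusion pipeline over a cohort: one record per subject."""
    params = params or AcquisitionParams()
    rule = rule or ThresholdRule()
    rows = []
    for bundle in bundles:
        row = analyze_subject(bundle, params, rule, min_component_cm3, roi_area_mm2)
        if not keep_objects:
            row.pop("_objects")
        rows.append(row)
    return pd.DataFrame(rows)


def _cohort_summary(df: pd.DataFrame) -> dict:
    def ms(col: str) -> dict:
        vals = df[col].dropna()
        return {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1)), "n": int(vals.size)}

    return {
        "gtv_cm3": ms("gtv_cm3"),
        "gtv_asl_cm3": ms("gtv_asl_cm3"),
        "volume_ratio_pct": ms("volume_ratio_pct"),
        "high_perfusion": {k: ms(c) for k, c in
                           (("cbf_max", "acbf_max"), ("cbf_min", "acbf_min"), ("cbf_mean", "acbf_mean"),
                            ("rcbf_max", "rcbf_max"), ("rcbf_min", "rcbf_min"), ("rcbf_mean", "rcbf_mean"))},
        "edema": {"cbf_mean": ms("edema_acbf_mean"), "rcbf_mean": ms("edema_rcbf_mean")},
        "normal_gm": {"cbf_mean": ms("gm_roi_acbf_mean")},
    }


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages and write the run artefacts; returns the report.

    Artefacts under ``cfg.output_dir``: the cohort manifest and per-subject
    stats CSVs, per-subject NIfTI volumes and masks (optional), the feature
    table, selection results, ROC results and figures, and ``report.json``.
    Any stage failure aborts with the stage name and subject id; artefacts
    written so far are retained.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run_pipeline_inner(cfg, out)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run_pipeline_inner(cfg: RunConfig, out: Path) -> dict:
    logger.info("stage=generate n=%d master_seed=%d", cfg.cohort.n_subjects, cfg.master_seed)
    cohort_spec = cfg.cohort
    if cfg.master_seed != cohort_spec.master_seed:
        cohort_spec = CohortSpec(**{**cohort_spec.__dict__, "master_seed": cfg.master_seed})
    bundles, manifest = generate_cohort(cohort_spec)
    manifest.to_csv(out / "manifest.csv", index=False)

    logger.info("stage=quantify+segment rule=%s:%s", cfg.rule.kind, cfg.rule.value)
    records = []
    volumes: dict[str, dict] = {}
    regions: dict[str, dict] = {}
    for bundle in bundles:
        try:
            row = analyze_subject(bundle, cfg.acquisition, cfg.rule,
                                  cfg.min_component_cm3, cfg.roi_area_mm2)
        except Exception as exc:
            raise RuntimeError(f"stage=analyze subject={bundle.subject_id}: {exc}") from exc
        objs = row.pop("_objects")
        records.append(row)
        cbf, targets = objs["cbf"], objs["targets"]
        if cfg.save_nifti:
            sdir = out / bundle.subject_id
            for seq, vol in bundle.structurals.items():
                write_nifti(vol, sdir / f"{seq}.nii.gz")
            write_nifti(cbf.volume, sdir / "CBF.nii.gz")
            write_mask(targets.gtv, sdir / "GTV.nii.gz")
            write_mask(targets.gtv_asl, sdir / "GTV_ASL.nii.gz")
            write_mask(targets.gtv_sub, sdir / "GTV_SUB.nii.gz")
        if not targets.gtv_asl.is_empty() and not targets.gtv_sub.is_empty():
            seq_vols = dict(bundle.structurals)
            seq_vols["ASL"] = cbf.volume
            volumes[bundle.subject_id] = seq_vols
            regions[bundle.subject_id] = {REGION_HIGH: targets.gtv_asl, REGION_LOW: targets.gtv_sub}

    stats_df = pd.DataFrame(records)
    stats_df.to_csv(out / "cohort_stats.csv", index=False)
    report: dict = {
        "n_subjects": len(bundles),
        "n_analyzable": len(volumes),
        "master_seed": cfg.master_seed,
        "cohort_summary": _cohort_summary(stats_df),
    }

    # region-level perfusion discriminators (one score per region per subject)
    analyzable = stats_df.dropna(subset=["acbf_mean"])
    region_scores = pd.DataFrame({
        "aCBF_mean": pd.concat([analyzable["acbf_mean"], analyzable["edema_acbf_mean"]],
                               ignore_index=True),
        "rCBF_mean": pd.concat([analyzable["rcbf_mean"], analyzable["edema_rcbf_mean"]],
                               ignore_index=True),
    })
    region_labels = np.array([1] * len(analyzable) + [0] * len(analyzable))

    if cfg.extract_features and volumes:
        logger.info("stage=radiomics subjects=%d", len(volumes))
        try:
            table = extract_table(volumes, regions, cfg=cfg.discretization or None)
        except Exception as exc:
            raise RuntimeError(f"stage=radiomics: {exc}") from exc
        table.to_csv(out / "features.csv")
        (out / "feature_schema.json").write_text(json.dumps(
            {"n_columns": table.shape[1], "config_hash": table.attrs["config_hash"],
             "columns": table.columns.tolist()}, indent=1))

        labels = (table.index.get_level_values("region") == REGION_HIGH).astype(int)
        logger.info("stage=selection n_rows=%d n_cols=%d", *table.shape)
        try:
            sel = lasso_select(table, labels, cfg.selection)
        except Exception as exc:
            raise RuntimeError(f"stage=selection: {exc}") from exc
        sel.cv_error_curve.to_csv(out / "cv_error_curve.csv")
        (out / "selection.json").write_text(json.dumps({
            "n_retained_after_variance": len(sel.retained_after_variance),
            "retained_counts_per_sequence": sel.counts_per_sequence,
            "optimal_lambda": sel.optimal_lambda,
            "selected": [{"feature": n, "coefficient": c} for n, c in sel.selected_features],
        }, indent=1))
        report["selection"] = {
            "n_retained_after_variance": len(sel.retained_after_variance),
            "optimal_lambda": sel.optimal_lambda,
            "n_selected": len(sel.selected_features),
            "n_selected_from_asl": sum(1 for n, _ in sel.selected_features if n.startswith("ASL|")),
        }

        logger.info("stage=roc")
        candidates = pd.concat([region_scores.reset_index(drop=True),
                                table[sel.selected_names].reset_index(drop=True)], axis=1)
        roc_results = evaluate_discriminators(candidates, region_labels)
    else:
        roc_results = evaluate_discriminators(region_scores, region_labels) if len(analyzable) else []
        report["selection"] = None

    roc_df = pd.DataFrame([r.as_dict() for r in roc_results])
    roc_df.to_csv(out / "roc_results.csv", index=False)
    if roc_results:
        plot_roc(roc_results[: min(5, len(roc_results))], out / "roc_curves.png")
    report["roc"] = roc_df.to_dict(orient="records")

    (out / "report.json").write_text(json.dumps(report, indent=1, default=float))
    logger.info("run complete: %s", out / "report.json")
    return report
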