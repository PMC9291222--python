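"""Cohort-level feature table assembly.

One row per (subject, region), one column per (sequence, feature).
Shape features depend on the mask only and are therefore identical across
sequences; they are replicated per sequence by default so the table holds
the full ``107 x n_sequences`` columns (535 for the five-sequence
protocol), with ``dedupe_shape=True`` available to keep a single copy.
"""

from __future__ import annotations

import hashlib
import json

import pandas as pd

from ..core_io import GeometryError, ImageVolume, Mask
from .discretize import DiscretizationConfig, default_discretization
from .features import compute_features, feature_names

__all__ = ["extract_table"]

REGION_HIGH = "GTV-ASL"
REGION_LOW = "GTV-SUB"


def _config_hash(cfg_by_seq: dict[str, DiscretizationConfig]) -> str:
    payload = json.dumps({k: v.key() for k, v in sorted(cfg_by_seq.items())})
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def extract_table(
    volumes: dict[str, dict[str, ImageVolume]],
    regions: dict[str, dict[str, Mask]],
    cfg: dict[str, DiscretizationConfig] | DiscretizationConfig | None = None,
    sequences: list[str] | None = None,
    dedupe_shape: bool = False,
) -> pd.DataFrame:
    """Extract the full feature table for a cohort.

    Parameters
    ----------
    volumes:
        ``{subject_id: {sequence: ImageVolume}}``, all pre-aligned.
    regions:
        ``{subject_id: {region_name: Mask}}`` — typically the GTV-ASL and
        GTV-SUB masks of each subject.
    cfg:
        Discretization per sequence (a single config applies to all);
        defaults per volume via :func:`default_discretization`.
    sequences:
        Column order; defaults to the sorted union found in ``volumes``.

    Returns a DataFrame indexed by (subject_id, region) whose columns are
    ``"{sequence}|{class}_{name}"`` with the discretization hash stored in
    ``df.attrs["config_hash"]``.  Deterministic given config.
    """
    if not volumes:
        raise ValueError("no subjects supplied")
    if sequences is None:
        seen: list[str] = []
        for per_subj in volumes.values():
            for seq in per_subj:
                if seq not in seen:
                    seen.append(seq)
        sequences = seen

    rows = []
    index = []
    cfg_by_seq: dict[str, DiscretizationConfig] = {}
    for subject_id, per_seq in volumes.items():
        if subject_id not in regions:
            raise ValueError(f"no regions supplied for subject {subject_id!r}")
        for region_name, mask in regions[subject_id].items():
            row: dict[str, float] = {}
            shape_cache: dict[str, float] | None = None
            for seq in sequences:
                if seq not in per_seq:
                    raise ValueError(f"subject {subject_id!r} lacks sequence {seq!r}")
                vol = per_seq[seq]
                if not vol.same_lattice(mask):
                    raise GeometryError(
                        f"subject {subject_id!r}, sequence {seq!r}: volume and "
                        f"region {region_name!r} are on different lattices"
                    )
                if isinstance(cfg, DiscretizationConfig):
                    seq_cfg = cfg
                elif isinstance(cfg, dict):
                    seq_cfg = cfg.get(seq) or default_discretization(vol)
                else:
                    seq_cfg = default_discretization(vol)
                cfg_by_seq[seq] = seq_cfg
                values = compute_features(vol, mask, seq_cfg)
                if dedupe_shape:
                    if shape_cache is None:
                        shape_cache = {k: v for k, v in values.items() if k.startswith("shape_")}
                    else:
                        values = {k: v for k, v in values.items() if not k.startswith("shape_")}
                row.update({f"{seq}|{name}": val for name, val in values.items()})
            rows.append(row)
            index.append((subject_id, region_name))

    df = pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(index, names=["subject_id", "region"]))
    expected = [f"{seq}|{name}" for seq in sequences for name in feature_names()]
    if not dedupe_shape:
        df = df[expected]  # enforce canonical column order
    if df.isna().any().any():
        missing = df.columns[df.isna().any()].tolist()[:5]
        raise AssertionError(f"feature extraction produced missing values, e.g. {missing}")
    df.attrs["config_hash"] = _config_hash(cfg_by_seq)
    return df
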