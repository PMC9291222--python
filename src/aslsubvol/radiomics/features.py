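"""Feature formulas: first-order statistics and the five texture families.

Formulas follow the standard radiomics canon.  Gray-level weights use the
discretization bin numbers (level values), entropies are base-2 over
positive probabilities, population (not sample) moments are used, and
kurtosis is the raw fourth standardised moment (not excess).  Degenerate
regions (single level, single voxel) produce the documented conventions
instead of missing values: Correlation and MCC of a one-level matrix are
1, NGTDM contrast of a one-level region is 0, and coarseness of a region
with zero gray-tone difference is capped at 1e6.
"""

from __future__ import annotations

import numpy as np

from ..core_io import ImageVolume, Mask, require_aligned
from .discretize import DiscretizationConfig, default_discretization, discretize
from .matrices import TextureMatrices, compute_matrices
from .shape import SHAPE_FEATURE_NAMES, shape_features

__all__ = [
    "firstorder_features",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "gldm_features",
    "ngtdm_features",
    "compute_features",
    "feature_names",
    "FEATURE_CLASS_COUNTS",
    "N_FEATURES_PER_SEQUENCE",
]

_COARSENESS_CAP = 1e6


# ---------------------------------------------------------------------------
# first order
# ---------------------------------------------------------------------------

FIRSTORDER_NAMES = (
    "10Percentile", "90Percentile", "Energy", "Entropy", "InterquartileRange",
    "Kurtosis", "Maximum", "MeanAbsoluteDeviation", "Mean", "Median", "Minimum",
    "Range", "RobustMeanAbsoluteDeviation", "RootMeanSquared", "Skewness",
    "TotalEnergy", "Uniformity", "Variance",
)


def firstorder_features(
    vol: ImageVolume,
    region: Mask,
    cfg: DiscretizationConfig | None = None,
) -> dict[str, float]:
    """The 18 first-order intensity features of a region.

    Percentiles use linear interpolation.  Entropy and Uniformity are
    computed on the discretized histogram; everything else on raw
    intensities.
    """
    require_aligned(vol, region, context="firstorder_features")
    if region.is_empty():
        raise ValueError("region is empty")
    x = vol.data[region.data].astype(np.float64)
    n = x.size
    mean = float(x.mean())
    var = float(x.var())  # population variance
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    if var > 0:
        std = np.sqrt(var)
        skew = float(((x - mean) ** 3).mean() / std**3)
        kurt = float(((x - mean) ** 4).mean() / var**2)
    else:
        skew, kurt = 0.0, 0.0

    levels, _ = discretize(vol, region, cfg)
    counts = np.bincount(levels[region.data])[1:]
    p = counts[counts > 0] / n
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p**2).sum())

    energy = float((x**2).sum())
    return {
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Energy": energy,
        "Entropy": entropy,
        "InterquartileRange": float(p75 - p25),
        "Kurtosis": kurt,
        "Maximum": float(x.max()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "Mean": mean,
        "Median": float(p50),
        "Minimum": float(x.min()),
        "Range": float(x.max() - x.min()),
        "RobustMeanAbsoluteDeviation": float(np.abs(robust - robust.mean()).mean())
        if robust.size
        else 0.0,
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "Skewness": skew,
        "TotalEnergy": energy * vol.voxel_volume_mm3,
        "Uniformity": uniformity,
        "Variance": var,
    }


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

GLCM_NAMES = (
    "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
    "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
    "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
    "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy", "MCC",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares",
)


def _entropy2(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def glcm_features(tm: TextureMatrices) -> dict[str, float]:
    counts = tm.glcm.astype(np.float64)
    total = counts.sum()
    if total == 0:  # single-voxel region: no voxel pairs at all
        return {name: (1.0 if name in ("Correlation", "MCC") else 0.0) for name in GLCM_NAMES}
    p = counts / total
    iv = tm.level_values.astype(np.float64)
    ng = iv.size
    ii = iv[:, None]
    jj = iv[None, :]
    px = p.sum(axis=1)  # symmetric: px == py
    mu = float((px * iv).sum())
    sigma2 = float((px * (iv - mu) ** 2).sum())
    diff = np.abs(ii - jj)
    ssum = ii + jj

    diff_vals = np.unique(diff)
    p_diff = np.array([p[diff == d].sum() for d in diff_vals])
    sum_vals = np.unique(ssum)
    p_sum = np.array([p[ssum == s].sum() for s in sum_vals])
    diff_avg = float((diff_vals * p_diff).sum())

    if sigma2 > 0:
        correlation = float(((p * ii * jj).sum() - mu * mu) / sigma2)
    else:
        correlation = 1.0

    hxy = _entropy2(p.ravel())
    outer = px[:, None] * px[None, :]
    pos = (p > 0) & (outer > 0)
    hxy1 = float(-(p[pos] * np.log2(outer[pos])).sum())
    hxy2 = _entropy2(outer.ravel())
    hx = _entropy2(px)
    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))) if hxy2 >= hxy else 0.0

    if ng > 1:
        # Q(i,j) = sum_k p(i,k) p(j,k) / (px(i) py(k)); MCC = sqrt(2nd eigenvalue)
        denom = np.where(px > 0, px, 1.0)
        q = (p @ (p / denom[None, :]).T) / denom[:, None]
        eig = np.sort(np.real(np.linalg.eigvals(q)))[::-1]
        mcc = float(np.sqrt(max(0.0, eig[1])))
    else:
        mcc = 1.0

    off = diff > 0
    inverse_variance = float((p[off] / (ii - jj)[off] ** 2).sum())

    return {
        "Autocorrelation": float((p * ii * jj).sum()),
        "ClusterProminence": float((p * (ssum - 2 * mu) ** 4).sum()),
        "ClusterShade": float((p * (ssum - 2 * mu) ** 3).sum()),
        "ClusterTendency": float((p * (ssum - 2 * mu) ** 2).sum()),
        "Contrast": float((p * (ii - jj) ** 2).sum()),
        "Correlation": correlation,
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": _entropy2(p_diff),
        "DifferenceVariance": float(((diff_vals - diff_avg) ** 2 * p_diff).sum()),
        "Id": float((p / (1.0 + diff)).sum()),
        "Idm": float((p / (1.0 + diff**2)).sum()),
        "Idmn": float((p / (1.0 + diff**2 / ng**2)).sum()),
        "Idn": float((p / (1.0 + diff / ng)).sum()),
        "Imc1": float(imc1),
        "Imc2": imc2,
        "InverseVariance": inverse_variance,
        "JointAverage": mu,
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": float(p.max()),
        "SumAverage": float((sum_vals * p_sum).sum()),
        "SumEntropy": _entropy2(p_sum),
        "SumSquares": float((p * (ii - mu) ** 2).sum()),
    }


# ---------------------------------------------------------------------------
# run-length / size-zone / dependence (shared algebra)
# ---------------------------------------------------------------------------

GLRLM_NAMES = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized", "GrayLevelVariance",
    "HighGrayLevelRunEmphasis", "LongRunEmphasis", "LongRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis", "LowGrayLevelRunEmphasis", "RunEntropy",
    "RunLengthNonUniformity", "RunLengthNonUniformityNormalized", "RunPercentage",
    "RunVariance", "ShortRunEmphasis", "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
)

GLSZM_NAMES = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized", "GrayLevelVariance",
    "HighGrayLevelZoneEmphasis", "LargeAreaEmphasis", "LargeAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis", "LowGrayLevelZoneEmphasis", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "SmallAreaEmphasis", "SmallAreaHighGrayLevelEmphasis",
    "SmallAreaLowGrayLevelEmphasis", "ZoneEntropy", "ZonePercentage", "ZoneVariance",
)

GLDM_NAMES = (
    "DependenceEntropy", "DependenceNonUniformity", "DependenceNonUniformityNormalized",
    "DependenceVariance", "GrayLevelNonUniformity", "GrayLevelVariance",
    "HighGrayLevelEmphasis", "LargeDependenceEmphasis", "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis", "LowGrayLevelEmphasis", "SmallDependenceEmphasis",
    "SmallDependenceHighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
)


def _rl_core(counts: np.ndarray, i_vals: np.ndarray, j_vals: np.ndarray, n_voxels: int) -> dict:
    """Shared statistics of a (gray level x magnitude) count matrix."""
    c = counts.astype(np.float64)
    nr = c.sum()
    ii = i_vals.astype(np.float64)[:, None]
    jj = j_vals.astype(np.float64)[None, :]
    p = c / nr
    mu_i = (p * ii).sum()
    mu_j = (p * jj).sum()
    return {
        "nr": nr,
        "sre": float((c / jj**2).sum() / nr),
        "lre": float((c * jj**2).sum() / nr),
        "gln": float((c.sum(axis=1) ** 2).sum() / nr),
        "glnn": float((c.sum(axis=1) ** 2).sum() / nr**2),
        "rln": float((c.sum(axis=0) ** 2).sum() / nr),
        "rlnn": float((c.sum(axis=0) ** 2).sum() / nr**2),
        "rp": float(nr / n_voxels),
        "glv": float((p * (ii - mu_i) ** 2).sum()),
        "rv": float((p * (jj - mu_j) ** 2).sum()),
        "entropy": _entropy2(p.ravel()),
        "lgle": float((c / ii**2).sum() / nr),
        "hgle": float((c * ii**2).sum() / nr),
        "s_lgle": float((c / (ii**2 * jj**2)).sum() / nr),
        "s_hgle": float((c * ii**2 / jj**2).sum() / nr),
        "l_lgle": float((c * jj**2 / ii**2).sum() / nr),
        "l_hgle": float((c * (ii * jj) ** 2).sum() / nr),
    }


def glrlm_features(tm: TextureMatrices) -> dict[str, float]:
    run_lengths = np.arange(1, tm.glrlm.shape[1] + 1)
    s = _rl_core(tm.glrlm, tm.level_values, run_lengths, tm.n_voxels)
    return {
        "GrayLevelNonUniformity": s["gln"],
        "GrayLevelNonUniformityNormalized": s["glnn"],
        "GrayLevelVariance": s["glv"],
        "HighGrayLevelRunEmphasis": s["hgle"],
        "LongRunEmphasis": s["lre"],
        "LongRunHighGrayLevelEmphasis": s["l_hgle"],
        "LongRunLowGrayLevelEmphasis": s["l_lgle"],
        "LowGrayLevelRunEmphasis": s["lgle"],
        "RunEntropy": s["entropy"],
        "RunLengthNonUniformity": s["rln"],
        "RunLengthNonUniformityNormalized": s["rlnn"],
        "RunPercentage": s["rp"],
        "RunVariance": s["rv"],
        "ShortRunEmphasis": s["sre"],
        "ShortRunHighGrayLevelEmphasis": s["s_hgle"],
        "ShortRunLowGrayLevelEmphasis": s["s_lgle"],
    }


def glszm_features(tm: TextureMatrices) -> dict[str, float]:
    s = _rl_core(tm.glszm, tm.level_values, tm.glszm_sizes, tm.n_voxels)
    return {
        "GrayLevelNonUniformity": s["gln"],
        "GrayLevelNonUniformityNormalized": s["glnn"],
        "GrayLevelVariance": s["glv"],
        "HighGrayLevelZoneEmphasis": s["hgle"],
        "LargeAreaEmphasis": s["lre"],
        "LargeAreaHighGrayLevelEmphasis": s["l_hgle"],
        "LargeAreaLowGrayLevelEmphasis": s["l_lgle"],
        "LowGrayLevelZoneEmphasis": s["lgle"],
        "SizeZoneNonUniformity": s["rln"],
        "SizeZoneNonUniformityNormalized": s["rlnn"],
        "SmallAreaEmphasis": s["sre"],
        "SmallAreaHighGrayLevelEmphasis": s["s_hgle"],
        "SmallAreaLowGrayLevelEmphasis": s["s_lgle"],
        "ZoneEntropy": s["entropy"],
        "ZonePercentage": s["rp"],
        "ZoneVariance": s["rv"],
    }


def gldm_features(tm: TextureMatrices) -> dict[str, float]:
    deps = np.arange(1, tm.gldm.shape[1] + 1)
    s = _rl_core(tm.gldm, tm.level_values, deps, tm.n_voxels)
    return {
        "DependenceEntropy": s["entropy"],
        "DependenceNonUniformity": s["rln"],
        "DependenceNonUniformityNormalized": s["rlnn"],
        "DependenceVariance": s["rv"],
        "GrayLevelNonUniformity": s["gln"],
        "GrayLevelVariance": s["glv"],
        "HighGrayLevelEmphasis": s["hgle"],
        "LargeDependenceEmphasis": s["lre"],
        "LargeDependenceHighGrayLevelEmphasis": s["l_hgle"],
        "LargeDependenceLowGrayLevelEmphasis": s["l_lgle"],
        "LowGrayLevelEmphasis": s["lgle"],
        "SmallDependenceEmphasis": s["sre"],
        "SmallDependenceHighGrayLevelEmphasis": s["s_hgle"],
        "SmallDependenceLowGrayLevelEmphasis": s["s_lgle"],
    }


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

NGTDM_NAMES = ("Busyness", "Coarseness", "Complexity", "Contrast", "Strength")


def ngtdm_features(tm: TextureMatrices) -> dict[str, float]:
    n_i = tm.ngtdm_n.astype(np.float64)
    s_i = tm.ngtdm_s.astype(np.float64)
    iv = tm.level_values.astype(np.float64)
    nvp = n_i.sum()
    if nvp == 0:  # single voxel, no neighbourhood
        return {name: (_COARSENESS_CAP if name == "Coarseness" else 0.0) for name in NGTDM_NAMES}
    p_i = n_i / nvp
    active = p_i > 0
    ngp = int(active.sum())
    pa, ia, sa = p_i[active], iv[active], s_i[active]

    coarse_den = float((pa * sa).sum())
    coarseness = 1.0 / coarse_den if coarse_den > 0 else _COARSENESS_CAP
    coarseness = min(coarseness, _COARSENESS_CAP)

    if ngp > 1:
        pij2 = pa[:, None] * pa[None, :] * (ia[:, None] - ia[None, :]) ** 2
        contrast = float(pij2.sum() / (ngp * (ngp - 1)) * (sa.sum() / nvp))
    else:
        contrast = 0.0

    busy_den = float(np.abs(ia[:, None] * pa[:, None] - ia[None, :] * pa[None, :]).sum())
    busyness = float((pa * sa).sum() / busy_den) if busy_den > 0 else 0.0

    with np.errstate(divide="ignore", invalid="ignore"):
        cmplx = (
            np.abs(ia[:, None] - ia[None, :])
            * (pa[:, None] * sa[:, None] + pa[None, :] * sa[None, :])
            / (pa[:, None] + pa[None, :])
        )
    complexity = float(np.nansum(cmplx) / nvp)

    s_sum = float(sa.sum())
    if s_sum > 0:
        strength = float(
            ((pa[:, None] + pa[None, :]) * (ia[:, None] - ia[None, :]) ** 2).sum() / s_sum
        )
    else:
        strength = 0.0

    return {
        "Busyness": busyness,
        "Coarseness": coarseness,
        "Complexity": complexity,
        "Contrast": contrast,
        "Strength": strength,
    }


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

FEATURE_CLASS_COUNTS = {
    "shape": 14,
    "firstorder": 18,
    "glcm": 24,
    "gldm": 14,
    "glrlm": 16,
    "glszm": 16,
    "ngtdm": 5,
}
N_FEATURES_PER_SEQUENCE = sum(FEATURE_CLASS_COUNTS.values())  # 107

_CLASS_NAMES = {
    "shape": SHAPE_FEATURE_NAMES,
    "firstorder": FIRSTORDER_NAMES,
    "glcm": GLCM_NAMES,
    "gldm": GLDM_NAMES,
    "glrlm": GLRLM_NAMES,
    "glszm": GLSZM_NAMES,
    "ngtdm": NGTDM_NAMES,
}


def feature_names() -> list[str]:
    """The 107 per-sequence feature names, as ``class_Name`` strings."""
    out = []
    for cls, names in _CLASS_NAMES.items():
        out.extend(f"{cls}_{name}" for name in names)
    return out


def compute_features(
    vol: ImageVolume,
    region: Mask,
    cfg: DiscretizationConfig | None = None,
) -> dict[str, float]:
    """All 107 features of one (volume, region) pair, as a flat name map."""
    require_aligned(vol, region, context="compute_features")
    if region.is_empty():
        raise ValueError("region is empty")
    cfg = cfg or default_discretization(vol)
    levels, _ = discretize(vol, region, cfg)
    tm = compute_matrices(levels, region)

    out: dict[str, float] = {}
    for cls, values in (
        ("shape", shape_features(region)),
        ("firstorder", firstorder_features(vol, region, cfg)),
        ("glcm", glcm_features(tm)),
        ("gldm", gldm_features(tm)),
        ("glrlm", glrlm_features(tm)),
        ("glszm", glszm_features(tm)),
        ("ngtdm", ngtdm_features(tm)),
    ):
        for name, value in values.items():
            out[f"{cls}_{name}"] = float(value)
    assert len(out) == N_FEATURES_PER_SEQUENCE
    return out
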