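"""ROC / Youden cut-off analysis and normality-gated paired comparisons.

The AUC is the Mann-Whitney probability estimate (ties counted one half),
which equals the trapezoidal area under the empirical ROC curve; the
reported cut-off maximises the Youden index J = sensitivity +
specificity - 1 over observed thresholds and is reported as the midpoint
of the two adjacent observed values bracketing the optimum (ties resolve
to the lowest such midpoint).  Sensitivity is defined on the positive
(high-perfusion) class.

Paired group comparisons are gated by a Shapiro-Wilk test on the paired
differences: normal differences (p > alpha) take a paired t test,
otherwise the Wilcoxon signed-rank test, matching routine clinical
statistics practice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ROCResult",
    "GroupComparison",
    "roc_analyze",
    "compare_paired",
    "evaluate_discriminators",
    "plot_roc",
]


@dataclass
class ROCResult:
    """ROC analysis of one scalar discriminator."""

    auc: float
    curve: np.ndarray               # (k, 2) of (1 - specificity, sensitivity)
    cutoff: float
    sensitivity: float              # percent, at the cutoff
    specificity: float              # percent, at the cutoff
    n_pos: int
    n_neg: int
    youden_j: float
    name: str = ""

    def as_dict(self) -> dict:
        return {
            "name": self.name,
            "auc": self.auc,
            "cutoff": self.cutoff,
            "sensitivity_pct": self.sensitivity,
            "specificity_pct": self.specificity,
            "youden_j": self.youden_j,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
        }


@dataclass
class GroupComparison:
    """Normality-gated paired comparison record."""

    test_used: str                  # "paired_t" | "wilcoxon_signed_rank" | "degenerate"
    statistic: float
    p_value: float
    normality_p: float
    mean_difference: float


def _mann_whitney_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """P(X_pos > X_neg) + 0.5 P(X_pos = X_neg) via rank sums."""
    combined = np.concatenate([pos, neg])
    ranks = stats.rankdata(combined)  # average ranks: ties counted one half
    r_pos = ranks[: len(pos)].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def roc_analyze(scores_pos, scores_neg, name: str = "") -> ROCResult:
    """Full ROC analysis of positive-class vs negative-class scores.

    Thresholds are the sorted unique observed values (classification rule
    ``score >= threshold`` -> positive); the returned curve includes the
    (0,0) and (1,1) endpoints.
    """
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be non-empty")

    auc = _mann_whitney_auc(pos, neg)

    observed = np.unique(np.concatenate([pos, neg]))
    sens = np.array([(pos >= t).mean() for t in observed])
    spec = np.array([(neg < t).mean() for t in observed])
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # first (lowest threshold) on ties

    # report the midpoint between the bracketing observed values
    if best == 0:
        cutoff = float(observed[0])
    else:
        cutoff = float((observed[best] + observed[best - 1]) / 2.0)

    # curve: sweep thresholds from +inf down; prepend (0,0), append (1,1)
    fpr = 1.0 - spec[::-1]
    tpr = sens[::-1]
    curve = np.vstack([[0.0, 0.0], np.column_stack([fpr, tpr]), [1.0, 1.0]])

    return ROCResult(
        auc=auc,
        curve=curve,
        cutoff=cutoff,
        sensitivity=float(sens[best] * 100.0),
        specificity=float(spec[best] * 100.0),
        n_pos=int(pos.size),
        n_neg=int(neg.size),
        youden_j=float(j[best]),
        name=name,
    )


def trapezoid_auc(curve: np.ndarray) -> float:
    """AUC by trapezoidal integration of a (1-specificity, sensitivity) curve."""
    order = np.lexsort((curve[:, 1], curve[:, 0]))
    c = curve[order]
    return float(np.trapezoid(c[:, 1], c[:, 0]))


def compare_paired(a, b, alpha_normality: float = 0.05) -> GroupComparison:
    """Paired t or Wilcoxon signed-rank comparison, gated by Shapiro-Wilk.

    Positive statistic means ``a`` tends to exceed ``b`` (paired t on
    ``a - b``); two-tailed p values throughout.  All-zero differences
    return a degenerate record (p = 1) instead of crashing.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length 1-D sequences")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    diff = a - b
    if np.allclose(diff, 0.0):
        return GroupComparison("degenerate", 0.0, 1.0, 1.0, 0.0)
    sw_stat, sw_p = stats.shapiro(diff)
    if sw_p > alpha_normality:
        t_stat, p = stats.ttest_rel(a, b)
        return GroupComparison("paired_t", float(t_stat), float(p), float(sw_p), float(diff.mean()))
    w_stat, p = stats.wilcoxon(a, b)
    return GroupComparison(
        "wilcoxon_signed_rank", float(w_stat), float(p), float(sw_p), float(diff.mean())
    )


def evaluate_discriminators(
    table: pd.DataFrame,
    labels,
    candidates: list[str] | None = None,
) -> list[ROCResult]:
    """One ROC analysis per candidate column, ranked by AUC (descending).

    ``labels`` is the binary region class aligned with the table rows
    (1 = high perfusion).  Raises on a missing candidate column.
    """
    y = np.asarray(labels, dtype=int)
    if len(y) != len(table):
        raise ValueError("labels must align with the table rows")
    if candidates is None:
        candidates = table.columns.tolist()
    results = []
    for name in candidates:
        if name not in table.columns:
            raise KeyError(f"candidate column {name!r} not in table")
        scores = table[name].to_numpy(dtype=float)
        res = roc_analyze(scores[y == 1], scores[y == 0], name=name)
        results.append(res)
    return sorted(results, key=lambda r: -r.auc)


def plot_roc(results: list[ROCResult] | ROCResult, path=None):
    """Plot one or more ROC curves; saves to ``path`` if given."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if isinstance(results, ROCResult):
        results = [results]
    fig, ax = plt.subplots(figsize=(5, 5))
    for res in results:
        ax.plot(res.curve[:, 0], res.curve[:, 1], label=f"{res.name or 'score'} (AUC {res.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
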