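"""Binary-classification metrics and group-difference tests.

The positive class is *good perfusion*: TP counts good-perfusion trials
recognized as good, TN counts poor-perfusion trials recognized as poor.
Metrics are reported in percent:

    PPV         = 100 * TP / (TP + FP)
    sensitivity = 100 * TP / (TP + FN)
    F-measure   = 2 * sensitivity * PPV / (sensitivity + PPV)
    accuracy    = 100 * (TP + TN) / (TP + FP + TN + FN)

``reconstruct_confusion`` inverts printed percentages back to the integer
confusion matrices consistent with them, by exhaustive search — useful for
auditing reported results when only rates and totals are given.

Group comparisons wrap the standard two-sided Welch t-test (pairwise) and
the Kruskal-Wallis test (omnibus) at alpha = 0.05.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionMatrix",
    "confusion_from_predictions",
    "metrics",
    "reconstruct_confusion",
    "group_compare",
]

ALPHA = 0.05


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total < 1:
            raise ValueError("confusion matrix must contain at least one trial")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_from_predictions(y_true, y_pred, positive) -> ConfusionMatrix:
    """Confusion counts with ``positive`` as the positive (good-perfusion) class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos_true = y_true == positive
    pos_pred = y_pred == positive
    return ConfusionMatrix(
        tp=int(np.sum(pos_true & pos_pred)),
        fp=int(np.sum(~pos_true & pos_pred)),
        tn=int(np.sum(~pos_true & ~pos_pred)),
        fn=int(np.sum(pos_true & ~pos_pred)),
    )


def f_measure(sensitivity: float, ppv: float) -> float:
    """Harmonic mean of sensitivity and PPV (both in percent)."""
    if sensitivity + ppv <= 0:
        return math.nan
    return 2.0 * sensitivity * ppv / (sensitivity + ppv)


def metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """PPV, sensitivity, F-measure and accuracy in percent (NaN if undefined)."""
    ppv = 100.0 * cm.tp / (cm.tp + cm.fp) if cm.tp + cm.fp else math.nan
    sens = 100.0 * cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn else math.nan
    if not math.isnan(ppv) and not math.isnan(sens) and ppv + sens > 0:
        f_measure = 2.0 * sens * ppv / (sens + ppv)
    else:
        f_measure = math.nan
    accuracy = 100.0 * (cm.tp + cm.tn) / cm.total
    return {
        "ppv": ppv,
        "sensitivity": sens,
        "f_measure": f_measure,
        "accuracy": accuracy,
    }


def format_metrics(values: dict[str, float], decimals: int = 2) -> str:
    """Plain-text metric table rounded for display (internal values stay exact)."""
    lines = [f"{k:<12s} {v:.{decimals}f}%" if not math.isnan(v) else f"{k:<12s} n/a"
             for k, v in values.items()]
    return "\n".join(lines)


def reconstruct_confusion(
    total: int,
    ppv: float,
    sensitivity: float,
    tol: float = 0.005,
) -> list[ConfusionMatrix]:
    """All integer confusion matrices of size ``total`` matching printed rates.

    Exhaustively enumerates (tp, fp, fn, tn >= 0, summing to ``total``) and
    keeps those whose PPV and sensitivity, rounded to two decimals, fall
    within ``tol`` percentage points of the given values. The empty list is a
    legitimate outcome (no integer matrix reproduces the percentages).
    """
    if total < 1:
        raise ValueError("total must be >= 1")
    matches = []
    for tp in range(total + 1):
        for fp in range(total - tp + 1):
            for fn in range(total - tp - fp + 1):
                tn = total - tp - fp - fn
                if tp + fp == 0 or tp + fn == 0:
                    continue
                got_ppv = round(100.0 * tp / (tp + fp), 2)
                got_sens = round(100.0 * tp / (tp + fn), 2)
                if abs(got_ppv - ppv) <= tol and abs(got_sens - sensitivity) <= tol:
                    matches.append(ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn))
    return matches


def group_compare(
    values_by_group: dict[str, np.ndarray],
    equal_var: bool = False,
    alpha: float = ALPHA,
) -> dict:
    """Pairwise t-tests and a Kruskal-Wallis omnibus test across groups.

    ``equal_var=False`` (default) gives Welch t-tests; degenerate groups
    (< 2 values) yield missing entries rather than errors.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    pairwise = {}
    for a, b in itertools.combinations(sorted(groups), 2):
        if groups[a].size < 2 or groups[b].size < 2:
            pairwise[(a, b)] = math.nan
            continue
        pairwise[(a, b)] = float(
            stats.ttest_ind(groups[a], groups[b], equal_var=equal_var).pvalue
        )
    usable = [g for g in groups.values() if g.size >= 2]
    kw_p = float(stats.kruskal(*usable).pvalue) if len(usable) >= 2 else math.nan
    significant = sorted(
        pair for pair, p in pairwise.items() if not math.isnan(p) and p < alpha
    )
    return {
        "pairwise_t_p": pairwise,
        "kruskal_p": kw_p,
        "significant_pairs": significant,
        "alpha": alpha,
    }
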