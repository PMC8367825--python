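"""Diagnostic-accuracy and distributional statistics.

Cutoff-based confusion matrices with sensitivity/specificity (percent) and
PPV/NPV (fractions), threshold-free ROC-AUC via the Mann-Whitney pairwise
statistic, and per-class summaries (median, quartiles, IQR, upper-fence
outliers) in the shape the clinical tables use.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import rankdata

from .classify import ThresholdModel
from .imageset import ScoreRecord


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class DiagnosticSummary:
    """Accuracy report: sensitivity/specificity in percent, PPV/NPV as
    fractions (mirroring the clinical-table conventions), AUC optional.

    ``None`` marks an undefined rate (e.g. PPV with no positive calls).
    Raw values are kept unrounded; :meth:`display` rounds the way the
    tables print (2 decimals for percentages, 3 for PPV/NPV/AUC).
    """

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    cutoff: float | None
    n_pos: int
    n_neg: int
    auc: float | None = None

    def display(self) -> dict:
        def r(x: float | None, nd: int) -> float | None:
            return None if x is None else round(x, nd)

        return {
            "cutoff": self.cutoff,
            "sensitivity_pct": r(self.sensitivity, 2),
            "specificity_pct": r(self.specificity, 2),
            "ppv": r(self.ppv, 3),
            "npv": r(self.npv, 3),
            "roc_auc": r(self.auc, 3),
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
        }


@dataclass(frozen=True)
class ClassSummary:
    median: float
    q1: float
    q3: float
    iqr: float
    min: float
    max: float
    n: int
    n_above_upper_fence: int

    def display(self) -> dict:
        return {
            "median": round(self.median, 2),
            "q1": round(self.q1, 2),
            "q3": round(self.q3, 2),
            "iqr": round(self.iqr, 2),
            "min": round(self.min, 3),
            "max": round(self.max, 3),
            "n": self.n,
            "n_above_upper_fence": self.n_above_upper_fence,
        }


def confusion(
    pos_scores: Sequence[float], neg_scores: Sequence[float], cutoff: float
) -> ConfusionMatrix:
    """Count calls at a cutoff; a score at the cutoff is called positive
    (the same boundary convention the triage display uses)."""
    if not len(pos_scores) or not len(neg_scores):
        raise ValueError("both score lists must be non-empty")
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    tp = int((pos >= cutoff).sum())
    fp = int((neg >= cutoff).sum())
    return ConfusionMatrix(tp=tp, fp=fp, tn=len(neg) - fp, fn=len(pos) - tp)


def diagnostics(
    cm: ConfusionMatrix, cutoff: float | None = None, auc: float | None = None
) -> DiagnosticSummary:
    """Rates from a confusion matrix; division-guard cases yield ``None``."""
    if cm.n_pos == 0 or cm.n_neg == 0:
        raise ValueError("need at least one positive and one negative")

    def frac(num: int, den: int) -> float | None:
        return None if den == 0 else num / den

    sens = frac(cm.tp, cm.n_pos)
    spec = frac(cm.tn, cm.n_neg)
    return DiagnosticSummary(
        sensitivity=None if sens is None else 100.0 * sens,
        specificity=None if spec is None else 100.0 * spec,
        ppv=frac(cm.tp, cm.tp + cm.fp),
        npv=frac(cm.tn, cm.tn + cm.fn),
        cutoff=cutoff,
        n_pos=cm.n_pos,
        n_neg=cm.n_neg,
        auc=auc,
    )


def roc_auc(pos_scores: Sequence[float], neg_scores: Sequence[float]) -> float:
    """ROC-AUC as the Mann-Whitney statistic.

    The fraction of (positive, negative) pairs where the positive scores
    higher, counting ties as half — identical to the trapezoidal area
    under the empirical ROC curve.  Computed via midranks.
    """
    if not len(pos_scores) or not len(neg_scores):
        raise ValueError("both score lists must be non-empty")
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    ranks = rankdata(np.concatenate([pos, neg]))
    rank_sum_pos = ranks[: len(pos)].sum()
    n_pos, n_neg = len(pos), len(neg)
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def class_summary(scores: Sequence[float]) -> ClassSummary:
    """Median/quartile summary with 1.5-IQR upper-fence outlier count.

    Quartiles use linear interpolation between order statistics (the
    quantile at p sits at fractional index p*(n-1)).
    """
    if not len(scores):
        raise ValueError("need at least one score")
    arr = np.asarray(scores, dtype=float)
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75], method="linear")
    iqr = q3 - q1
    fence = q3 + 1.5 * iqr
    return ClassSummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        iqr=float(iqr),
        min=float(arr.min()),
        max=float(arr.max()),
        n=len(arr),
        n_above_upper_fence=int((arr > fence).sum()),
    )


def evaluate_cohort(
    records: Iterable[ScoreRecord],
    cutoff: float | ThresholdModel,
    positive_labels: Sequence[str] = ("OPML", "SCC"),
) -> dict:
    """Full accuracy report for a labelled cohort at one cutoff.

    ``cutoff`` may be a number or a :class:`ThresholdModel` (whose
    normal/suspect boundary is used).  Positives are records whose label
    is in ``positive_labels``; negatives are ``normal`` records.  Returns
    a dict with the diagnostic summary plus a per-class distribution
    summary, in the shape of the clinical report tables.
    """
    records = list(records)
    if isinstance(cutoff, ThresholdModel):
        cutoff_value = cutoff.t_opml
    else:
        cutoff_value = float(cutoff)
    pos = [r.score for r in records if r.label in positive_labels]
    neg = [r.score for r in records if r.label == "normal"]
    if not pos or not neg:
        raise ValueError("cohort lacks a positive or negative class")
    cm = confusion(pos, neg, cutoff_value)
    summary = diagnostics(cm, cutoff=cutoff_value, auc=roc_auc(pos, neg))
    per_class = {}
    for label in ("normal", "OPML", "SCC"):
        scores = [r.score for r in records if r.label == label]
        if scores:
            per_class[label] = class_summary(scores)
    return {
        "positive_labels": list(positive_labels),
        "confusion": {"TP": cm.tp, "FP": cm.fp, "TN": cm.tn, "FN": cm.fn},
        "diagnostics": summary,
        "class_summaries": per_class,
    }
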