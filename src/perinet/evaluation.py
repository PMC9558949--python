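"""Patient-level aggregation and the reported classification metrics.

Per-lesion and per-slice bounding options produce several predictions per
patient; a single subject-level call is obtained by majority voting over the
predicted classes (exact ties resolve to LN-, the prior class).  For ROC and
precision-recall curves a continuous patient score is needed; the mean
positive-class probability over the patient's samples is used.

Metrics: accuracy, sensitivity and specificity in percent (LN+ positive),
AUC by the rank (Mann-Whitney) formulation with tie midranks, and Cohen's
kappa.  Degenerate denominators yield NaN ("undefined"), never silently 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import precision_recall_curve as _sk_pr_curve
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "EvalReport",
    "majority_vote",
    "patient_score",
    "confusion_and_metrics",
    "roc_auc",
    "pr_curve",
    "evaluate_patients",
    "pooled_report",
]


def majority_vote(sample_classes: Sequence[int], tie_value: int = 0) -> int:
    """Modal predicted class over one patient's samples; ties -> ``tie_value``.

    The default tie rule favors LN- (the prior class), mirroring the
    specificity-leaning behavior of multi-sample bounding options.
    """
    classes = list(sample_classes)
    if not classes:
        raise ValueError("majority vote over an empty prediction list")
    pos = sum(1 for c in classes if c == 1)
    neg = len(classes) - pos
    if pos == neg:
        return tie_value
    return 1 if pos > neg else 0


def patient_score(sample_probs: Sequence[float]) -> float:
    """Patient-level positive-class score: mean over sample probabilities."""
    probs = list(sample_probs)
    if not probs:
        raise ValueError("patient score over an empty probability list")
    return float(np.mean(probs))


def confusion_and_metrics(truth: Sequence[int], predicted: Sequence[int]) -> dict:
    """Confusion counts and ACC/SENS/SPE/precision/kappa with LN+ positive.

    ACC, SENS and SPE are returned in percent.  Cohen's kappa is
    ``(p_o - p_e) / (1 - p_e)`` with the chance agreement computed from the
    confusion-table marginals.  Degenerate denominators give NaN.
    """
    t = np.asarray(truth, dtype=int)
    p = np.asarray(predicted, dtype=int)
    if t.shape != p.shape:
        raise ValueError(f"truth and predictions differ in length: {t.shape} vs {p.shape}")
    if t.size == 0:
        raise ValueError("empty prediction list")
    tp = int(np.sum((t == 1) & (p == 1)))
    tn = int(np.sum((t == 0) & (p == 0)))
    fp = int(np.sum((t == 0) & (p == 1)))
    fn = int(np.sum((t == 1) & (p == 0)))
    n = t.size

    def _ratio(num, den):
        return num / den if den > 0 else float("nan")

    p_o = (tp + tn) / n
    p_e = ((tp + fp) * (tp + fn) + (tn + fn) * (tn + fp)) / n**2
    kappa = (p_o - p_e) / (1 - p_e) if p_e < 1 else float("nan")
    return {
        "tp": tp,
        "fp": fp,
        "tn": tn,
        "fn": fn,
        "acc": 100.0 * p_o,
        "sens": 100.0 * _ratio(tp, tp + fn),
        "spe": 100.0 * _ratio(tn, tn + fp),
        "precision": _ratio(tp, tp + fp),
        "kappa": kappa,
    }


def roc_auc(truth: Sequence[int], scores: Sequence[float]):
    """AUC via midrank Mann-Whitney statistic, plus the ROC curve points.

    Returns ``(auc, fpr, tpr, thresholds)``.  A single-class truth vector
    yields NaN for the AUC.
    """
    t = np.asarray(truth, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int((t == 1).sum())
    n_neg = int((t == 0).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan"), np.array([]), np.array([]), np.array([])
    ranks = rankdata(s)  # midranks under ties
    auc = (ranks[t == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    fpr, tpr, thr = _sk_roc_curve(t, s)
    return float(auc), fpr, tpr, thr


def pr_curve(truth: Sequence[int], scores: Sequence[float]):
    """Precision/recall at all score thresholds (recall == sensitivity)."""
    t = np.asarray(truth, dtype=int)
    if (t == 1).sum() == 0:
        raise ValueError("precision-recall curve needs at least one positive")
    precision, recall, thr = _sk_pr_curve(t, np.asarray(scores, dtype=float))
    return precision, recall, thr


@dataclass
class EvalReport:
    """Per-fold and pooled evaluation of one bounding option."""

    option: str
    fold_metrics: list[dict] = field(default_factory=list)
    pooled: dict = field(default_factory=dict)
    mean: dict = field(default_factory=dict)
    roc: dict = field(default_factory=dict)
    pr: dict = field(default_factory=dict)
    truth: list[int] = field(default_factory=list)
    votes: list[int] = field(default_factory=list)
    scores: list[float] = field(default_factory=list)
    patient_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "option": self.option,
            "fold_metrics": self.fold_metrics,
            "mean": self.mean,
            "pooled": self.pooled,
            "n_patients": len(self.truth),
        }


def evaluate_patients(
    patient_ids: Sequence[str],
    truth: Sequence[int],
    votes: Sequence[int],
    scores: Sequence[float],
    fold_of: dict[str, int] | None = None,
    option: str = "",
) -> EvalReport:
    """Build the full report from patient-level truth, votes and scores.

    ``fold_of`` assigns each patient to its test fold; per-fold metrics and
    their mean are computed when it is given, and the pooled confusion
    matrix counts every patient exactly once regardless.
    """
    report = EvalReport(
        option=option,
        truth=list(map(int, truth)),
        votes=list(map(int, votes)),
        scores=list(map(float, scores)),
        patient_ids=list(map(str, patient_ids)),
    )
    report.pooled = confusion_and_metrics(report.truth, report.votes)
    auc, fpr, tpr, _ = roc_auc(report.truth, report.scores)
    report.pooled["auc"] = auc
    report.roc = {"fpr": fpr.tolist(), "tpr": tpr.tolist(), "auc": auc}
    if any(t == 1 for t in report.truth):
        precision, recall, _ = pr_curve(report.truth, report.scores)
        report.pr = {"precision": precision.tolist(), "recall": recall.tolist()}
    if fold_of:
        folds = sorted({fold_of[p] for p in report.patient_ids})
        for f in folds:
            sel = [i for i, p in enumerate(report.patient_ids) if fold_of[p] == f]
            m = confusion_and_metrics(
                [report.truth[i] for i in sel], [report.votes[i] for i in sel]
            )
            m["fold"] = f
            m["auc"], *_ = roc_auc(
                [report.truth[i] for i in sel], [report.scores[i] for i in sel]
            )
            report.fold_metrics.append(m)
        keys = ("acc", "sens", "spe", "kappa", "auc")
        report.mean = {
            k: float(np.nanmean([m[k] for m in report.fold_metrics])) for k in keys
        }
    return report


def pooled_report(report: EvalReport) -> dict:
    """Headline numbers of a report: pooled confusion plus ACC/SENS/SPE/AUC/K."""
    return dict(report.pooled)


def plot_curves(report: EvalReport, out_dir) -> list[str]:
    """Write ROC and PR curve figures; returns the file paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    if report.roc.get("fpr"):
        fig, ax = plt.subplots()
        ax.plot(report.roc["fpr"], report.roc["tpr"])
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("False positive rate")
        ax.set_ylabel("True positive rate")
        ax.set_title(f"{report.option.upper()} ROC (AUC={report.roc['auc']:.3f})")
        f = out_dir / f"roc_{report.option}.png"
        fig.savefig(f, dpi=120)
        plt.close(fig)
        paths.append(str(f))
    if report.pr:
        fig, ax = plt.subplots()
        ax.plot(report.pr["recall"], report.pr["precision"])
        ax.set_xlabel("Recall")
        ax.set_ylabel("Precision")
        ax.set_title(f"{report.option.upper()} precision-recall")
        f = out_dir / f"pr_{report.option}.png"
        fig.savefig(f, dpi=120)
        plt.close(fig)
        paths.append(str(f))
    return paths
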