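"""Evaluation surface: confusion matrix, per-class P/R/F1, macro/weighted
aggregates, per-question-type accuracy, and the seed-stability analysis.

Conventions: per-class precision/recall/F1 are one-vs-rest; 0/0 cases are
reported as 0 (no predicted positives -> precision 0; no true positives ->
recall 0; P=R=0 -> F1 0).  Macro aggregates are unweighted means of the
per-class values; weighted aggregates are support-weighted means.  Weighted
recall therefore equals overall accuracy for every single-label multi-class
problem - asserted on every report.  Internally everything is kept at full
precision; serialization rounds proportions to 4 decimals and percentages
to 2.
"""

from __future__ import annotations

import dataclasses
from typing import Hashable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .core_types import QuestionType


@dataclasses.dataclass
class ConfusionMatrix:
    """Rows = truth, columns = prediction."""

    labels: tuple
    counts: np.ndarray

    @property
    def supports(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion_matrix(
    truths: Sequence[Hashable],
    predictions: Sequence[Hashable],
    labels: Sequence[Hashable],
) -> ConfusionMatrix:
    if len(truths) != len(predictions):
        raise ValueError("truths and predictions differ in length")
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for t, p in zip(truths, predictions):
        if t not in index or p not in index:
            raise ValueError(f"value outside label set: {t!r} / {p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(tuple(labels), counts)


@dataclasses.dataclass
class PerClass:
    precision: float
    recall: float
    f1: float
    support: int


@dataclasses.dataclass
class EvaluationReport:
    confusion: ConfusionMatrix
    per_class: dict  # label -> PerClass
    accuracy: float
    macro: tuple[float, float, float]  # (precision, recall, f1)
    weighted: tuple[float, float, float]
    per_type_accuracy: Optional[dict] = None

    def to_dict(self) -> dict:
        d = {
            "labels": [str(getattr(l, "value", l)) for l in self.confusion.labels],
            "confusion": self.confusion.counts.tolist(),
            "per_class": {
                str(getattr(l, "value", l)): {
                    "precision": round(pc.precision, 4),
                    "recall": round(pc.recall, 4),
                    "f1": round(pc.f1, 4),
                    "support": pc.support,
                }
                for l, pc in self.per_class.items()
            },
            "accuracy": round(self.accuracy, 4),
            "macro": {
                "precision": round(self.macro[0], 4),
                "recall": round(self.macro[1], 4),
                "f1": round(self.macro[2], 4),
            },
            "weighted": {
                "precision": round(self.weighted[0], 4),
                "recall": round(self.weighted[1], 4),
                "f1": round(self.weighted[2], 4),
            },
        }
        if self.per_type_accuracy is not None:
            d["per_type_accuracy_pct"] = {
                k.value: round(100.0 * v, 2) for k, v in self.per_type_accuracy.items()
            }
        return d

    def to_text(self) -> str:
        """Plain-text table in the usual per-class rows + footer layout."""
        rows = [f"{'':>10} {'Precision':>10} {'Recall':>10} {'F1-Score':>10} {'Support':>8}"]
        for lab, pc in self.per_class.items():
            name = str(getattr(lab, "value", lab))
            rows.append(
                f"{name:>10} {pc.precision:>10.4f} {pc.recall:>10.4f} "
                f"{pc.f1:>10.4f} {pc.support:>8d}"
            )
        n = self.confusion.total
        rows.append(f"{'Accuracy':>10} {'':>10} {'':>10} {self.accuracy:>10.4f} {n:>8d}")
        rows.append(
            f"{'Macro Avg':>10} {self.macro[0]:>10.4f} {self.macro[1]:>10.4f} "
            f"{self.macro[2]:>10.4f} {n:>8d}"
        )
        rows.append(
            f"{'Wtd Avg':>10} {self.weighted[0]:>10.4f} {self.weighted[1]:>10.4f} "
            f"{self.weighted[2]:>10.4f} {n:>8d}"
        )
        return "\n".join(rows)


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def aggregate(per_class_values: Sequence[float], supports: Sequence[int]) -> tuple[float, float]:
    """(macro, weighted) aggregate of a per-class metric.

    Macro is the unweighted mean; weighted is the support-weighted mean
    normalized by the total sample count.
    """
    v = np.asarray(per_class_values, dtype=np.float64)
    s = np.asarray(supports, dtype=np.float64)
    if v.shape != s.shape or v.size == 0:
        raise ValueError("per-class values and supports must align and be nonempty")
    return float(v.mean()), float((v * s).sum() / s.sum())


def pooled_accuracy_from_recalls(
    recalls: Sequence[float], supports: Sequence[int]
) -> float:
    """Overall accuracy reconstructed from per-class recalls and supports.

    Per-class correct counts are recall*support rounded to the nearest
    integer (they are counts); accuracy is their sum over the total.
    """
    r = np.asarray(recalls, dtype=np.float64)
    s = np.asarray(supports, dtype=np.int64)
    correct = np.round(r * s).astype(np.int64)
    return float(correct.sum() / s.sum())


def evaluation_report(cm: ConfusionMatrix) -> EvaluationReport:
    counts = cm.counts
    if counts.shape[0] < 2:
        raise ValueError("need at least two classes")
    total = counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(counts).astype(np.float64)
    pred_pos = counts.sum(axis=0).astype(np.float64)
    true_pos = counts.sum(axis=1).astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(pred_pos > 0, tp / pred_pos, 0.0)
        recall = np.where(true_pos > 0, tp / true_pos, 0.0)
    f1 = np.array([f1_score(p, r) for p, r in zip(precision, recall)])
    accuracy = float(tp.sum() / total)
    supports = true_pos.astype(np.int64)
    macro = tuple(aggregate(v, supports)[0] for v in (precision, recall, f1))
    weighted = tuple(aggregate(v, supports)[1] for v in (precision, recall, f1))
    # single-label multi-class identity; holds for every confusion matrix
    assert abs(weighted[1] - accuracy) < 1e-12
    per_class = {
        lab: PerClass(float(p), float(r), float(f), int(s))
        for lab, p, r, f, s in zip(cm.labels, precision, recall, f1, supports)
    }
    return EvaluationReport(cm, per_class, accuracy, macro, weighted)


def per_type_accuracy(
    question_types: Sequence[QuestionType],
    truths: Sequence[Hashable],
    predictions: Sequence[Hashable],
) -> tuple[dict[QuestionType, float], float]:
    """Accuracy restricted to each true question type, plus pooled overall.

    Types with zero samples are omitted (with a warning via logging upstream).
    """
    if not (len(question_types) == len(truths) == len(predictions)):
        raise ValueError("inputs must align")
    qt = list(question_types)
    correct = np.array([t == p for t, p in zip(truths, predictions)], dtype=np.float64)
    out: dict[QuestionType, float] = {}
    for t in QuestionType:
        idx = [i for i, q in enumerate(qt) if q is t]
        if idx:
            out[t] = float(correct[idx].mean())
    overall = float(correct.mean()) if len(correct) else 0.0
    return out, overall


# ---------------------------------------------------------------------------
# Seed-stability analysis


@dataclasses.dataclass
class SeedStudyResult:
    """Across-seed accuracy statistics tested against a fixed baseline.

    The t-test is the one-sample form (a paired test against a constant
    reduces exactly to it): t = (mean - baseline) / (sd / sqrt(n)) with
    n-1 degrees of freedom, two-tailed.  ``degenerate`` flags sd == 0,
    where t and p are undefined.
    """

    per_seed: list[tuple[int, float]]
    mean: float
    sd: float
    baseline: float
    t_statistic: Optional[float]
    p_value: Optional[float]
    degenerate: bool

    def to_dict(self) -> dict:
        return {
            "per_seed": [[s, round(a, 2)] for s, a in self.per_seed],
            "mean": round(self.mean, 2),
            "sd": round(self.sd, 2),
            "baseline": round(self.baseline, 2),
            "t_statistic": None if self.degenerate else round(self.t_statistic, 2),
            "p_value": None if self.degenerate else round(self.p_value, 4),
            "degenerate": self.degenerate,
        }


def seed_stability(
    accuracies: Sequence[float],
    baseline: float,
    seeds: Optional[Sequence[int]] = None,
) -> SeedStudyResult:
    acc = np.asarray(accuracies, dtype=np.float64)
    if acc.size < 2:
        raise ValueError("need at least two accuracies")
    if not np.isfinite(acc).all():
        raise ValueError("non-finite accuracy")
    if seeds is None:
        seeds = list(range(acc.size))
    mean = float(acc.mean())
    sd = float(acc.std(ddof=1))
    per_seed = [(int(s), float(a)) for s, a in zip(seeds, acc)]
    if sd == 0.0:
        return SeedStudyResult(per_seed, mean, sd, float(baseline), None, None, True)
    t = (mean - baseline) / (sd / np.sqrt(acc.size))
    p = 2.0 * stats.t.sf(abs(t), df=acc.size - 1)
    return SeedStudyResult(per_seed, mean, sd, float(baseline), float(t), float(p), False)
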