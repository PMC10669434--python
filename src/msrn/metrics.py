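"""Diagnostic metrics for multi-label OCT classification.

Per class, accuracy / sensitivity / specificity are computed from the
confusion counts:

    Acc = (TP + TN) / (TP + FP + TN + FN)
    Sen = TP / (TP + FN)
    Spe = TN / (TN + FP)

Micro-averages pool the counts across classes first and then apply the
same formulas once.  Patient-level accuracy is exact-match (subset)
accuracy: a scan counts as correct only when its entire predicted label
vector equals the ground truth.  Across-seed comparisons use a two-sided,
equal-variance two-sample Student t-test with significance at p <= 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

ALPHA = 0.05


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-class TP/TN/FP/FN over a batch of multi-hot predictions."""

    tp: np.ndarray
    tn: np.ndarray
    fp: np.ndarray
    fn: np.ndarray

    def __post_init__(self) -> None:
        for f in (self.tp, self.tn, self.fp, self.fn):
            if np.any(np.asarray(f) < 0):
                raise ValueError("confusion counts must be non-negative")
        totals = self.tp + self.tn + self.fp + self.fn
        if len(set(totals.tolist())) > 1:
            raise ValueError("per-class counts must sum to the same batch size")

    @property
    def num_classes(self) -> int:
        return len(self.tp)

    @property
    def batch_size(self) -> int:
        return int(self.tp[0] + self.tn[0] + self.fp[0] + self.fn[0])

    def pooled(self) -> tuple[int, int, int, int]:
        return (int(self.tp.sum()), int(self.tn.sum()),
                int(self.fp.sum()), int(self.fn.sum()))


def _check_binary(a: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(a)
    if not np.isin(a, (0, 1)).all():
        raise ValueError(f"{name} must be binary (0/1)")
    return a.astype(np.int64)


def confusion_counts(predicted: np.ndarray, true: np.ndarray) -> ConfusionCounts:
    """Elementwise per-class counts from (N, C) binary arrays."""
    p = _check_binary(predicted, "predictions")
    y = _check_binary(true, "labels")
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: predictions {p.shape} vs labels {y.shape}")
    tp = ((p == 1) & (y == 1)).sum(axis=0)
    tn = ((p == 0) & (y == 0)).sum(axis=0)
    fp = ((p == 1) & (y == 0)).sum(axis=0)
    fn = ((p == 0) & (y == 1)).sum(axis=0)
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _ratio(num, den) -> float | None:
    # undefined ratios are reported as absent, never coerced to 0 or 1
    return float(num) / float(den) if den > 0 else None


def per_class_metrics(counts: ConfusionCounts) -> list[dict]:
    """Acc/Sen/Spe per class; zero-denominator entries are None."""
    out = []
    for i in range(counts.num_classes):
        tp, tn = int(counts.tp[i]), int(counts.tn[i])
        fp, fn = int(counts.fp[i]), int(counts.fn[i])
        out.append({
            "accuracy": _ratio(tp + tn, tp + fp + tn + fn),
            "sensitivity": _ratio(tp, tp + fn),
            "specificity": _ratio(tn, tn + fp),
        })
    return out


def micro_average(counts: ConfusionCounts):
    """(muAcc, muSen, muSpe): counts pooled over classes, formulas applied once."""
    tp, tn, fp, fn = counts.pooled()
    return (_ratio(tp + tn, tp + fp + tn + fn),
            _ratio(tp, tp + fn),
            _ratio(tn, tn + fp))


def exact_match_accuracy(predicted: np.ndarray, true: np.ndarray,
                         patient_ids=None) -> float:
    """Fraction of scans whose whole label vector is predicted exactly.

    With ``patient_ids`` given, grouping is per patient: a patient counts
    as correct only when every one of their scans matches exactly.
    """
    p = _check_binary(predicted, "predictions")
    y = _check_binary(true, "labels")
    if p.shape != y.shape:
        raise ValueError("shape mismatch")
    match = (p == y).all(axis=1)
    if patient_ids is None:
        return float(match.mean())
    patient_ids = np.asarray(patient_ids)
    patients = np.unique(patient_ids)
    ok = [match[patient_ids == pid].all() for pid in patients]
    return float(np.mean(ok))


@dataclass(frozen=True)
class SignificanceResult:
    metric: str
    t_statistic: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value <= ALPHA


def t_test(group_a, group_b, metric: str = "") -> SignificanceResult:
    """Two-sided, equal-variance two-sample Student t-test.

    Degenerate case: both groups constant with equal means -> t = 0, p = 1.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        return SignificanceResult(metric=metric, t_statistic=0.0, p_value=1.0)
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return SignificanceResult(metric=metric, t_statistic=float(t), p_value=float(p))


@dataclass
class MetricReport:
    """Per-class + micro-average + patient-level metrics for one evaluation."""

    per_class: list[dict]
    micro_accuracy: float | None
    micro_sensitivity: float | None
    micro_specificity: float | None
    patient_level_accuracy: float

    @classmethod
    def from_predictions(cls, predicted: np.ndarray, true: np.ndarray,
                         patient_ids=None) -> "MetricReport":
        counts = confusion_counts(predicted, true)
        mu_acc, mu_sen, mu_spe = micro_average(counts)
        return cls(per_class=per_class_metrics(counts),
                   micro_accuracy=mu_acc, micro_sensitivity=mu_sen,
                   micro_specificity=mu_spe,
                   patient_level_accuracy=exact_match_accuracy(
                       predicted, true, patient_ids=patient_ids))

    def as_flat_dict(self, class_names=None) -> dict:
        out = {
            "micro_accuracy": self.micro_accuracy,
            "micro_sensitivity": self.micro_sensitivity,
            "micro_specificity": self.micro_specificity,
            "patient_level_accuracy": self.patient_level_accuracy,
        }
        for i, m in enumerate(self.per_class):
            name = class_names[i] if class_names else f"class{i}"
            for k, v in m.items():
                out[f"{name}_{k}"] = v
        return out
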