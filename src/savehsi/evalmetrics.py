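"""Classification statistics computed from confusion matrices.

Per-class precision/recall/F1 are one-vs-rest; accuracy is the trace over
the total.  Interval estimation uses the Wilson score method, agreement is
summarised with Cohen's kappa, and two accuracies are compared with a
pooled two-proportion z-test.  All operations take a :class:`ConfusionMatrix`
(rows = true class, columns = predicted class).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionMatrix",
    "classification_report",
    "wilson_ci",
    "cohen_kappa",
    "macro_f1",
    "balanced_accuracy",
    "compare_accuracies",
    "cv_mean_accuracy",
]


@dataclass
class ConfusionMatrix:
    """K x K contingency table of true (rows) versus predicted (columns)."""

    counts: np.ndarray
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if np.any(self.counts < 0) or not np.allclose(self.counts, np.round(self.counts)):
            raise ValueError("counts must be non-negative integers")
        self.counts = self.counts.astype(np.int64)
        k = self.counts.shape[0]
        if not self.class_names:
            self.class_names = [str(i) for i in range(k)]
        if len(self.class_names) != k:
            raise ValueError("class_names length must match matrix size")

    @classmethod
    def from_labels(cls, y_true, y_pred, class_names: list[str] | None = None) -> "ConfusionMatrix":
        names = class_names or sorted(set(y_true) | set(y_pred))
        index = {c: i for i, c in enumerate(names)}
        counts = np.zeros((len(names), len(names)), dtype=np.int64)
        for t, p in zip(y_true, y_pred):
            counts[index[t], index[p]] += 1
        return cls(counts=counts, class_names=list(names))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_correct(self) -> int:
        return int(np.trace(self.counts))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.class_names, columns=self.class_names)


def _require_nonempty(cm: ConfusionMatrix) -> None:
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")


def classification_report(cm: ConfusionMatrix) -> dict:
    """One-vs-rest precision, recall and F1 per class, plus accuracy.

    A class with neither predicted nor true positives gets precision 0
    (with a warning), matching common reporting of degenerate classes.
    """
    _require_nonempty(cm)
    tp = np.diag(cm.counts).astype(float)
    pred_pos = cm.counts.sum(axis=0).astype(float)
    true_pos = cm.counts.sum(axis=1).astype(float)

    per_class = {}
    for i, name in enumerate(cm.class_names):
        if pred_pos[i] == 0:
            if tp[i] == 0:
                warnings.warn(f"class {name!r} has no predicted positives; precision set to 0", stacklevel=2)
            precision = 0.0
        else:
            precision = tp[i] / pred_pos[i]
        recall = tp[i] / true_pos[i] if true_pos[i] > 0 else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
        per_class[name] = {
            "precision": float(precision),
            "recall": float(recall),
            "f1": float(f1),
            "support": int(true_pos[i]),
        }
    return {"per_class": per_class, "accuracy": cm.n_correct / cm.total}


def wilson_ci(p_hat: float, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion.

    Closed form with the two-sided normal quantile; bounds lie in [0, 1]
    and bracket the shrunk centre ``(p + z^2/2n) / (1 + z^2/n)``.
    """
    if not 0.0 <= p_hat <= 1.0:
        raise ValueError("p_hat must lie in [0, 1]")
    if n < 1:
        raise ValueError("n must be at least 1")
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    denom = 1.0 + z**2 / n
    center = (p_hat + z**2 / (2 * n)) / denom
    half = (z / denom) * np.sqrt(p_hat * (1 - p_hat) / n + z**2 / (4 * n**2))
    return (max(0.0, center - half), min(1.0, center + half))


def cohen_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e) from marginals."""
    _require_nonempty(cm)
    total = cm.total
    p_o = cm.n_correct / total
    p_e = float(np.sum(cm.counts.sum(axis=0) * cm.counts.sum(axis=1))) / total**2
    if p_e >= 1.0:
        raise ValueError("kappa undefined: expected agreement is 1 (degenerate matrix)")
    return (p_o - p_e) / (1.0 - p_e)


def macro_f1(cm: ConfusionMatrix) -> float:
    """Unweighted mean of per-class F1 scores."""
    report = classification_report(cm)
    return float(np.mean([c["f1"] for c in report["per_class"].values()]))


def balanced_accuracy(cm: ConfusionMatrix) -> float:
    """Unweighted mean of per-class recalls."""
    report = classification_report(cm)
    return float(np.mean([c["recall"] for c in report["per_class"].values()]))


def compare_accuracies(correct1: int, n1: int, correct2: int, n2: int) -> float:
    """Two-sided pooled two-proportion z-test p-value.

    When the pooled proportion is 0 or 1 (no variance) the comparison is
    vacuous and p = 1.0 is returned by convention.
    """
    for c, n in ((correct1, n1), (correct2, n2)):
        if n < 1 or not 0 <= c <= n:
            raise ValueError("counts must satisfy 0 <= correct <= n, n >= 1")
    p1, p2 = correct1 / n1, correct2 / n2
    pooled = (correct1 + correct2) / (n1 + n2)
    if pooled <= 0.0 or pooled >= 1.0:
        return 1.0
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (p1 - p2) / se
    return float(2 * stats.norm.sf(abs(z)))


def cv_mean_accuracy(fold_accuracies) -> float:
    """Mean of per-fold accuracies (the cross-validation score)."""
    vals = np.asarray(list(fold_accuracies), dtype=float)
    if vals.size == 0:
        raise ValueError("need at least one fold accuracy")
    return float(vals.mean())
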