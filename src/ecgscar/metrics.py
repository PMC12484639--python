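"""Classification metrics from confusion counts.

Sp = TN/(TN+FP), Se = TP/(TP+FN), PPV = TP/(TP+FP),
F1 = TP/(TP + (FP+FN)/2); undefined ratios (0/0) are reported as NaN rather
than 0.  The 95% confidence interval around accuracy is the Wilson score
interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


@dataclass(frozen=True)
class ConfusionMetrics:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def sensitivity(self) -> float:
        return _safe_div(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return _safe_div(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float:
        return _safe_div(self.tp, self.tp + self.fp)

    @property
    def f1(self) -> float:
        return _safe_div(self.tp, self.tp + 0.5 * (self.fp + self.fn))

    @property
    def accuracy(self) -> float:
        return _safe_div(self.tp + self.tn, self.n)

    def accuracy_ci(self, z: float = 1.959964) -> tuple[float, float]:
        """Wilson score interval for accuracy."""
        n = self.n
        if n == 0:
            return (float("nan"), float("nan"))
        p = (self.tp + self.tn) / n
        denom = 1 + z**2 / n
        center = (p + z**2 / (2 * n)) / denom
        half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
        return (center - half, center + half)

    def as_dict(self) -> dict[str, float]:
        lo, hi = self.accuracy_ci()
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "ppv": self.ppv, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "f1": self.f1,
            "accuracy": self.accuracy, "acc_ci_low": lo, "acc_ci_high": hi,
        }


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMetrics:
    t = np.asarray(y_true).astype(bool)
    p = np.asarray(y_pred).astype(bool)
    if t.shape != p.shape:
        raise ValueError("y_true and y_pred must align")
    return ConfusionMetrics(
        tp=int(np.sum(t & p)),
        fp=int(np.sum(~t & p)),
        fn=int(np.sum(t & ~p)),
        tn=int(np.sum(~t & ~p)),
    )
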