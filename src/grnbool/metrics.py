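"""Static evaluation of an inferred influence graph against a gold standard.

Edges are treated as a binary classification over the n(n-1) ordered gene
pairs (self-pairs excluded, matching the no-self-loop genotype).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .netcore import DirectedNetwork

__all__ = ["ConfusionCounts", "confusion_counts", "static_metrics"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_counts(pred: DirectedNetwork, gold: DirectedNetwork) -> ConfusionCounts:
    if list(pred.gene_names) != list(gold.gene_names):
        raise ValueError("prediction and gold standard must share the gene set")
    off = ~np.eye(pred.n, dtype=bool)
    p = pred.adjacency.astype(bool) & off
    g = gold.adjacency.astype(bool) & off
    return ConfusionCounts(
        tp=int((p & g).sum()),
        fp=int((p & ~g & off).sum()),
        tn=int((~p & ~g & off).sum()),
        fn=int((~p & g).sum()),
    )


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


def static_metrics(pred: DirectedNetwork, gold: DirectedNetwork) -> dict[str, float]:
    """Accuracy, precision, recall, F1, bookmaker informedness and MCC.

    BM = TPR + TNR - 1; MCC is the Matthews correlation of the 2x2 counts.
    Ratios with an undefined (zero) denominator evaluate to 0 and the
    returned dict flags that under ``"degenerate"``.
    """
    c = confusion_counts(pred, gold)
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    degenerate = 0 in (tp + fp, tp + fn, tn + fp, tn + fn)
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    tnr = _safe_div(tn, tn + fp)
    f1 = _safe_div(2 * precision * recall, precision + recall)
    mcc_den = math.sqrt(
        float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    )
    mcc = _safe_div(tp * tn - fp * fn, mcc_den)
    return {
        "accuracy": _safe_div(tp + tn, c.total),
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "bm": recall + tnr - 1.0,
        "mcc": mcc,
        "degenerate": float(degenerate),
    }
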