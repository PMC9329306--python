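"""Agreement statistics between reference and predicted hypnograms.

With E(s, u) the number of epochs scored stage s by the expert and u by the
model, and M the total:

    Accuracy   = sum_s E(s,s) / M
    kappa      = (Accuracy - p_e) / (1 - p_e),
    p_e        = sum_s [row_s/M] * [col_s/M]     (chance agreement)
    Recall_s   = E(s,s) / row_s
    Precision_s= E(s,s) / col_s

Cohen's kappa corrects the raw agreement for the chance agreement implied
by the two raters' stage distributions; kappa > 0.8 is conventionally read
as almost-perfect agreement. Cross-validation folds are pooled by summing
confusion matrices before computing metrics (never by averaging per-fold
metrics), so every test epoch carries equal weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import EmptyMatrix, LengthMismatch
from .io import NS, STAGES

_STAGE_IDX = {s: i for i, s in enumerate(STAGES)}


@dataclass
class ConfusionMatrix:
    """5x5 epoch counts, rows = expert stage, columns = model stage."""

    counts: np.ndarray
    stage_order: tuple[str, ...] = STAGES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.stage_order),) * 2:
            raise ValueError(f"expected square matrix, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion_matrix(reference, predicted) -> ConfusionMatrix:
    """Tabulate expert-vs-model stage pairs; NS pairs are excluded.

    Accepts Hypnogram objects or plain label sequences of equal length.
    """
    ref = list(reference)
    pred = list(predicted)
    if len(ref) != len(pred):
        raise LengthMismatch(f"lengths differ: {len(ref)} vs {len(pred)}")
    counts = np.zeros((5, 5), dtype=np.int64)
    for r, p in zip(ref, pred):
        if r == NS or p == NS:
            continue
        counts[_STAGE_IDX[r], _STAGE_IDX[p]] += 1
    return ConfusionMatrix(counts)


@dataclass
class MetricsReport:
    """Accuracy, Cohen's kappa and per-stage recall/precision.

    Stages with an empty reference row (recall) or predicted column
    (precision) are reported as None and listed in ``undefined`` rather
    than silently coerced to 0.
    """

    accuracy: float
    kappa: float
    recall: dict[str, float | None]
    precision: dict[str, float | None]
    M: int
    undefined: list[str] = field(default_factory=list)
    kappa_interpretation: str = ""

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "kappa": self.kappa,
            "kappa_interpretation": self.kappa_interpretation,
            "M": self.M,
            "recall": self.recall,
            "precision": self.precision,
            "undefined": self.undefined,
        }


def interpret_kappa(kappa: float) -> str:
    """Conventional qualitative reading of a kappa value (annotation only)."""
    for lo, label in ((0.8, "almost perfect"), (0.6, "substantial"),
                      (0.4, "moderate"), (0.2, "fair"), (0.0, "slight")):
        if kappa > lo:
            return label
    return "poor"


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Apply the agreement formulas to one confusion matrix."""
    e = cm.counts.astype(np.float64)
    m = e.sum()
    if m <= 0:
        raise EmptyMatrix("confusion matrix has zero total epochs")
    rows = e.sum(axis=1)
    cols = e.sum(axis=0)
    diag = np.diag(e)
    accuracy = float(diag.sum() / m)
    p_e = float(((rows / m) * (cols / m)).sum())
    kappa = 1.0 if p_e >= 1.0 else float((accuracy - p_e) / (1.0 - p_e))

    recall: dict[str, float | None] = {}
    precision: dict[str, float | None] = {}
    undefined: list[str] = []
    for i, s in enumerate(cm.stage_order):
        recall[s] = float(diag[i] / rows[i]) if rows[i] > 0 else None
        precision[s] = float(diag[i] / cols[i]) if cols[i] > 0 else None
        if rows[i] == 0 or cols[i] == 0:
            undefined.append(s)
    return MetricsReport(
        accuracy=accuracy, kappa=kappa, recall=recall, precision=precision,
        M=int(m), undefined=undefined, kappa_interpretation=interpret_kappa(kappa),
    )


def pooled_metrics(folds: Sequence[ConfusionMatrix]) -> MetricsReport:
    """Sum fold confusion matrices element-wise, then compute metrics."""
    folds = list(folds)
    if not folds:
        raise EmptyMatrix("no folds to pool")
    counts = np.sum([f.counts for f in folds], axis=0)
    return compute_metrics(ConfusionMatrix(counts))
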