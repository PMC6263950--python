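"""Confusion matrices, recognition rates, and model comparison tables."""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .errors import LabelError, UndefinedRateError
from .synthetic import CLASS_ORDER


def round_half_up(x: float, digits: int = 2) -> float:
    """Display rounding matching the tables' style: 95.238... -> 95.24."""
    q = Decimal(10) ** -digits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """4x4 counts, true class (rows) by predicted class (columns), in the
    fixed order normal / germinated / moldy / worm-eaten."""

    counts: np.ndarray
    split: str = "test"  # train | test
    labels: tuple[str, ...] = CLASS_ORDER

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", c)
        k = len(self.labels)
        if c.shape != (k, k) or np.any(c < 0):
            raise ValueError("counts must be a non-negative square matrix")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    split: str = "test",
) -> ConfusionMatrix:
    """Tally a confusion matrix from label lists."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label lists differ in length")
    known = set(CLASS_ORDER)
    for lab in list(true_labels) + list(predicted_labels):
        if lab not in known:
            raise LabelError(f"unknown class label {lab!r}")
    counts = _sk_confusion(true_labels, predicted_labels, labels=list(CLASS_ORDER))
    return ConfusionMatrix(counts=counts, split=split)


@dataclass(frozen=True)
class RecognitionReport:
    """Per-class and overall recognition rates in percent.

    Rates are stored unrounded; :meth:`display` applies two-decimal
    round-half-up for table output.
    """

    counts: np.ndarray
    per_class_rate: dict[str, float]
    overall_rate: float
    false_judgments: dict[str, int]
    split: str = "test"
    uncertain_count: int = 0

    def display(self) -> dict[str, float]:
        out = {c: round_half_up(r) for c, r in self.per_class_rate.items()}
        out["overall"] = round_half_up(self.overall_rate)
        return out

    def to_dict(self) -> dict:
        return {
            "split": self.split,
            "counts": self.counts.tolist(),
            "per_class_rate": self.display(),
            "overall_rate": round_half_up(self.overall_rate),
            "false_judgments": dict(self.false_judgments),
            "uncertain_count": self.uncertain_count,
        }


def rates(cm: ConfusionMatrix, uncertain_count: int = 0) -> RecognitionReport:
    """Recognition rates: 100 * diagonal / row-sum per class, 100 * trace /
    total overall."""
    row_sums = cm.counts.sum(axis=1)
    if np.any(row_sums == 0):
        empty = [cm.labels[i] for i in np.nonzero(row_sums == 0)[0]]
        raise UndefinedRateError(f"no samples for class(es) {empty}")
    diag = np.diag(cm.counts)
    per_class = {
        lab: 100.0 * diag[i] / row_sums[i] for i, lab in enumerate(cm.labels)
    }
    overall = 100.0 * diag.sum() / cm.total
    false_j = {
        lab: int(row_sums[i] - diag[i]) for i, lab in enumerate(cm.labels)
    }
    return RecognitionReport(
        counts=cm.counts,
        per_class_rate=per_class,
        overall_rate=overall,
        false_judgments=false_j,
        split=cm.split,
        uncertain_count=uncertain_count,
    )


def compare_models(
    reports: Mapping[str, RecognitionReport],
) -> pd.DataFrame:
    """Comparison table sorted by overall rate, best first; ties keep the
    original insertion order."""
    if len(reports) < 2:
        raise ValueError("need at least two models to compare")
    rows = []
    for name, rep in reports.items():
        row = {"model": name, "overall_rate": round_half_up(rep.overall_rate)}
        row.update(
            {c: round_half_up(r) for c, r in rep.per_class_rate.items()}
        )
        row["uncertain_count"] = rep.uncertain_count
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values(
        "overall_rate", ascending=False, kind="stable"
    ).reset_index(drop=True)


def format_table(report: RecognitionReport, model: str = "") -> str:
    """Plain-text table in the style of the published result tables."""
    lines = [
        f"Model: {model}  ({report.split} set)",
        "Type         N    False  Rate(%)",
    ]
    disp = report.display()
    row_sums = report.counts.sum(axis=1)
    for i, lab in enumerate(CLASS_ORDER):
        lines.append(
            f"{lab:<12} {row_sums[i]:<4} {report.false_judgments[lab]:<6} "
            f"{disp[lab]:.2f}"
        )
    lines.append(f"Overall: {disp['overall']:.2f}%")
    if report.uncertain_count:
        lines.append(f"(deferred as uncertain: {report.uncertain_count})")
    return "\n".join(lines)
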