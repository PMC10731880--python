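"""Confusion matrices and micro / per-class precision, recall, F1.

The micro-averaged metrics sum true/false positives and false negatives
over the *evaluated positive classes only* — the catch-all negative
label contributes to errors of positive classes but is itself excluded
from the sums. A prediction counts as a true positive only when the
sentence is classified as exactly its gold relation type.

Percentages are rounded to two decimals at the report boundary; all
internal arithmetic is full precision. Matrices can be read from TSV
(rows = predictions, columns = gold), so printed result tables are
checkable without any model run.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = ["ConfusionMatrix", "EvalReport", "confusion_matrix",
           "micro_metrics", "per_class_metrics", "build_report",
           "read_matrix_tsv", "write_matrix_tsv"]


@dataclass(frozen=True)
class ConfusionMatrix:
    """counts[p][g] = number of instances predicted `labels[p]` whose gold
    label is `labels[g]`."""

    labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts)
        k = len(self.labels)
        if c.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {c.shape}")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"label {label!r} not in matrix") from None


@dataclass(frozen=True)
class EvalReport:
    """Micro and per-class (precision %, recall %, F1 %) plus the matrix."""

    micro: tuple[float, float, float]
    per_class: dict[str, tuple[float, float, float]]
    matrix: ConfusionMatrix

    def to_json(self) -> str:
        return json.dumps({
            "micro": {"precision": self.micro[0], "recall": self.micro[1],
                      "f1": self.micro[2]},
            "per_class": {lab: {"precision": p, "recall": r, "f1": f}
                          for lab, (p, r, f) in self.per_class.items()},
            "labels": list(self.matrix.labels),
            "counts": self.matrix.counts.astype(int).tolist(),
        }, indent=1)

    def to_text(self) -> str:
        lines = [f"{'label':<10}{'P%':>8}{'R%':>8}{'F1%':>8}"]
        for lab, (p, r, f) in self.per_class.items():
            lines.append(f"{lab:<10}{p:>8.2f}{r:>8.2f}{f:>8.2f}")
        p, r, f = self.micro
        lines.append(f"{'micro':<10}{p:>8.2f}{r:>8.2f}{f:>8.2f}")
        return "\n".join(lines)


def confusion_matrix(predictions: Sequence[str], golds: Sequence[str],
                     labels: Sequence[str]) -> ConfusionMatrix:
    if len(predictions) != len(golds):
        raise ValueError("predictions and golds differ in length")
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for p, g in zip(predictions, golds):
        if p not in index or g not in index:
            raise KeyError(f"label not covered by matrix labels: {p!r}/{g!r}")
        counts[index[p], index[g]] += 1
    return ConfusionMatrix(tuple(labels), counts)


def _prf(tp: float, fp: float, fn: float) -> tuple[float, float, float]:
    if tp + fp == 0:
        warnings.warn("zero predicted positives; precision defined as 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        warnings.warn("zero gold positives; recall defined as 0")
        recall = 0.0
    else:
        recall = tp / (tp + fn)
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return (round(100 * precision, 2), round(100 * recall, 2),
            round(100 * f1, 2))


def micro_metrics(matrix: ConfusionMatrix, positive_labels: Sequence[str]
                  ) -> tuple[float, float, float]:
    """Micro P/R/F1 with TP/FP/FN summed over the positive classes only."""
    c = matrix.counts.astype(np.float64)
    tp = fp = fn = 0.0
    for lab in positive_labels:
        i = matrix.index(lab)
        tp += c[i, i]
        fp += c[i, :].sum() - c[i, i]   # predicted i, gold something else
        fn += c[:, i].sum() - c[i, i]   # gold i, predicted something else
    return _prf(tp, fp, fn)


def per_class_metrics(matrix: ConfusionMatrix
                      ) -> dict[str, tuple[float, float, float]]:
    """One-vs-rest P/R/F1 for every label in the matrix."""
    c = matrix.counts.astype(np.float64)
    out = {}
    for i, lab in enumerate(matrix.labels):
        tp = c[i, i]
        out[lab] = _prf(tp, c[i, :].sum() - tp, c[:, i].sum() - tp)
    return out


def build_report(matrix: ConfusionMatrix, positive_labels: Sequence[str]
                 ) -> EvalReport:
    per_class = {lab: m for lab, m in per_class_metrics(matrix).items()
                 if lab in positive_labels}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        micro = micro_metrics(matrix, positive_labels)
        # re-run per-class quietly; warnings already surfaced above if any
    return EvalReport(micro, per_class, matrix)


# ---------------------------------------------------------------------------
# Matrix TSV I/O: header row/column carry the labels


def read_matrix_tsv(path: str | Path) -> ConfusionMatrix:
    lines = Path(path).read_text(encoding="utf-8").strip().splitlines()
    header = lines[0].split("\t")
    labels = tuple(header[1:])
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for r, line in enumerate(lines[1:]):
        cols = line.split("\t")
        if cols[0] != labels[r]:
            raise ValueError(f"row label {cols[0]!r} != column label "
                             f"{labels[r]!r}; matrix must be label-aligned")
        counts[r] = [int(x.replace(",", "")) for x in cols[1:]]
    return ConfusionMatrix(labels, counts)


def write_matrix_tsv(matrix: ConfusionMatrix, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("pred\\gold\t" + "\t".join(matrix.labels) + "\n")
        for lab, row in zip(matrix.labels, matrix.counts):
            fh.write(lab + "\t" + "\t".join(str(int(x)) for x in row) + "\n")
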