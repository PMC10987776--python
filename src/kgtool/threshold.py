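"""Time-sliced calibration of the decision threshold on the gene-pair score.

Known gene–gene associations (two genes documented to regulate a common
trait) are split by discovery year: pairs discovered up to a cutoff year
form the training slice, later pairs the validation slice. On the
training slice every distinct observed score is tried as a threshold —
the F1 score of the resulting classifier is piecewise constant between
observed scores, so this grid is exact — and the score maximizing F1
becomes the threshold. A pair is predicted positive when its score is
*greater than or equal to* the threshold.

Evaluation uses the four standard confusion-matrix summaries: accuracy,
precision, recall and F1 (harmonic mean of precision and recall).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import KGError


@dataclass(frozen=True)
class LabeledPair:
    """A scored gene pair with its positive/negative label and year."""

    g1: str
    g2: str
    score: float
    label: bool  # True = the genes are documented to regulate a common trait
    year: int

    def __post_init__(self) -> None:
        if self.score < 0:
            raise KGError(f"pair score must be >= 0, got {self.score}")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise KGError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class EvaluationMetrics:
    """Accuracy, precision, recall, F1 — all in [0, 1].

    A metric whose denominator is zero is reported as 0.0 and listed in
    ``undefined`` so degenerate slices are visible, not silent.
    """

    accuracy: float
    precision: float
    recall: float
    f1: float
    undefined: tuple[str, ...] = ()


@dataclass
class ThresholdSweepResult:
    threshold: float
    best_f1: float
    curve: list[tuple[float, float]] = field(default_factory=list)

    def write_curve(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("threshold\tf1\n")
            for t, f1 in self.curve:
                fh.write(f"{t:.6g}\t{f1:.6f}\n")


def time_slice_split(
    pairs: list[LabeledPair], cutoff_year: int
) -> tuple[list[LabeledPair], list[LabeledPair]]:
    """Partition pairs into (train: year <= cutoff, validation: year > cutoff)."""
    train = [p for p in pairs if p.year <= cutoff_year]
    validation = [p for p in pairs if p.year > cutoff_year]
    return train, validation


def classify(pairs: list[LabeledPair], threshold: float) -> ConfusionCounts:
    """Tally the confusion matrix at a threshold (score >= threshold ⇒ positive)."""
    if threshold < 0:
        raise KGError(f"threshold must be >= 0, got {threshold}")
    tp = tn = fp = fn = 0
    for p in pairs:
        predicted = p.score >= threshold
        if predicted and p.label:
            tp += 1
        elif predicted and not p.label:
            fp += 1
        elif not predicted and p.label:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp, tn, fp, fn)


def metrics(counts: ConfusionCounts) -> EvaluationMetrics:
    """Accuracy, precision, recall and F1 from confusion counts."""
    if counts.total == 0:
        raise KGError("cannot compute metrics on zero pairs")
    undefined: list[str] = []
    accuracy = (counts.TP + counts.TN) / counts.total
    if counts.TP + counts.FP > 0:
        precision = counts.TP / (counts.TP + counts.FP)
    else:
        precision = 0.0
        undefined.append("precision")
    if counts.TP + counts.FN > 0:
        recall = counts.TP / (counts.TP + counts.FN)
    else:
        recall = 0.0
        undefined.append("recall")
    if precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = 0.0
        undefined.append("f1")
    return EvaluationMetrics(accuracy, precision, recall, f1, tuple(undefined))


def sweep_threshold(train_pairs: list[LabeledPair]) -> ThresholdSweepResult:
    """Pick the threshold maximizing F1 on the training pairs.

    Candidates are the sorted distinct observed scores (F1 is piecewise
    constant between them, so the sweep is exact). Ties are broken toward
    the smallest threshold, which maximizes recall at equal F1. The full
    (threshold, F1) curve is returned for plotting.
    """
    if not train_pairs:
        raise KGError("cannot sweep an empty training set")
    if not any(p.label for p in train_pairs):
        raise KGError("training set has no positive pairs; F1 is undefined everywhere")
    candidates = sorted({p.score for p in train_pairs})
    curve = [(t, metrics(classify(train_pairs, t)).f1) for t in candidates]
    best_threshold, best_f1 = max(curve, key=lambda tf: (tf[1], -tf[0]))
    return ThresholdSweepResult(best_threshold, best_f1, curve)


def sample_negative_pairs(
    traits_by_gene: dict[str, set[str]],
    n: int,
    rng: np.random.Generator,
) -> list[tuple[str, str]]:
    """Sample *n* gene pairs sharing no trait, uniformly without replacement.

    How non-associated pairs are constructed is a modelling choice; this
    utility draws them from the same gene population as the positives,
    seeded for reproducibility.
    """
    genes = sorted(traits_by_gene)
    negatives = [
        (g1, g2)
        for i, g1 in enumerate(genes)
        for g2 in genes[i + 1 :]
        if not (traits_by_gene[g1] & traits_by_gene[g2])
    ]
    if n > len(negatives):
        raise KGError(f"requested {n} negatives but only {len(negatives)} exist")
    idx = rng.choice(len(negatives), size=n, replace=False)
    return [negatives[i] for i in sorted(idx)]


def load_labeled_pairs(path: str | Path) -> list[LabeledPair]:
    """Read a ``g1  g2  score  label  year`` TSV (label 1/0)."""
    out: list[LabeledPair] = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"g1", "g2", "score", "label", "year"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise KGError(f"{path}: labeled-pair TSV must have columns {sorted(required)}")
        for row in reader:
            out.append(
                LabeledPair(
                    row["g1"],
                    row["g2"],
                    float(row["score"]),
                    bool(int(row["label"])),
                    int(row["year"]),
                )
            )
    return out


def write_labeled_pairs(pairs: list[LabeledPair], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("g1\tg2\tscore\tlabel\tyear\n")
        for p in pairs:
            fh.write(f"{p.g1}\t{p.g2}\t{p.score:.6f}\t{int(p.label)}\t{p.year}\n")
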