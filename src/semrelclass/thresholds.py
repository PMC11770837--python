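"""Per-class decision-threshold calibration and application.

Each non-null relation type gets a one-vs-rest probability cutoff chosen on
validation predictions to maximise that class's one-vs-rest F1, floored at
0.5.  At inference a class is eligible only if its probability reaches its
cutoff; if no class is eligible the null label is assigned.  The null label
never competes via a threshold — its entry is fixed at 0.5 and it acts
purely as the fallback.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .schema import N_LABELS, POSITIVE_LABELS, RelationLabel

logger = logging.getLogger(__name__)

__all__ = ["ThresholdTable", "fit_thresholds", "apply_thresholds"]


@dataclass(frozen=True)
class ThresholdTable:
    """label -> decision threshold, every value in [0.5, 1.0]."""

    thresholds: Mapping[RelationLabel, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        table = dict(self.thresholds)
        table.setdefault(RelationLabel.no_rel, 0.5)
        if table[RelationLabel.no_rel] != 0.5:
            raise ValueError("the no_rel threshold is fixed at 0.5")
        for lab in POSITIVE_LABELS:
            if lab not in table:
                raise ValueError(f"missing threshold for {lab.name}")
        for lab, t in table.items():
            if not 0.5 <= t <= 1.0:
                raise ValueError(f"threshold for {lab.name} outside [0.5, 1]: {t}")
        object.__setattr__(self, "thresholds", table)

    def __getitem__(self, label: RelationLabel) -> float:
        return self.thresholds[label]

    @classmethod
    def uniform(cls, value: float = 0.5) -> "ThresholdTable":
        return cls({lab: value for lab in POSITIVE_LABELS})

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["label", "threshold"])
            for lab in RelationLabel.ordered():
                writer.writerow([lab.name, f"{self.thresholds[lab]:.6g}"])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ThresholdTable":
        table: dict[RelationLabel, float] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.reader(fh, delimiter="\t")
            next(reader, None)
            for row in reader:
                if len(row) >= 2 and row[0]:
                    table[RelationLabel.from_name(row[0])] = float(row[1])
        return cls(table)


def _ovr_f1(p_c: np.ndarray, is_c: np.ndarray, threshold: float) -> float:
    pred = p_c >= threshold
    tp = int(np.sum(pred & is_c))
    fp = int(np.sum(pred & ~is_c))
    fn = int(np.sum(~pred & is_c))
    if 2 * tp + fp + fn == 0:
        return 0.0
    return 2 * tp / (2 * tp + fp + fn)


def fit_thresholds(
    val_probs: np.ndarray, val_labels: Sequence[RelationLabel]
) -> ThresholdTable:
    """Calibrate one threshold per non-null class on validation predictions.

    Candidates for class c are the sorted unique values of p_c over the
    validation set plus 0.5; the candidate maximising one-vs-rest F1
    (predict c iff p_c >= t) wins, ties broken toward the smallest
    candidate, and the result is floored at 0.5.  A class with no positive
    validation instance defaults to 0.5 with a warning.
    """
    probs = np.asarray(val_probs, dtype=float)
    if probs.ndim != 2 or probs.shape[1] != N_LABELS:
        raise ValueError(f"val_probs must be (n, {N_LABELS})")
    if probs.shape[0] == 0:
        raise ValueError("need at least one validation instance")
    if probs.shape[0] != len(val_labels):
        raise ValueError("probabilities and labels are misaligned")
    gold = np.array([lab.index for lab in val_labels])

    table: dict[RelationLabel, float] = {}
    for lab in POSITIVE_LABELS:
        is_c = gold == lab.index
        p_c = probs[:, lab.index]
        if not is_c.any():
            logger.warning("no positive validation instances for %s; threshold 0.5", lab.name)
            table[lab] = 0.5
            continue
        candidates = np.unique(np.concatenate([p_c, [0.5]]))
        best_t, best_f1 = 0.5, -1.0
        for t in candidates:  # ascending, so ties keep the smallest
            f1 = _ovr_f1(p_c, is_c, float(t))
            if f1 > best_f1:
                best_t, best_f1 = float(t), f1
        table[lab] = max(best_t, 0.5)
    return ThresholdTable(table)


def apply_thresholds(probs: np.ndarray, table: ThresholdTable) -> RelationLabel:
    """Decision rule for one probability vector.

    Eligible classes are the non-null ones whose probability reaches their
    threshold (inclusive).  If none is eligible the null label is assigned;
    otherwise the eligible class with maximal probability wins, ties broken
    toward the earlier label order.
    """
    p = np.asarray(probs, dtype=float)
    if p.shape != (N_LABELS,):
        raise ValueError(f"expected a {N_LABELS}-vector, got shape {p.shape}")
    best: RelationLabel | None = None
    best_p = -1.0
    for lab in POSITIVE_LABELS:
        pc = p[lab.index]
        if pc >= table[lab] and pc > best_p:
            best, best_p = lab, float(pc)
    return best if best is not None else RelationLabel.no_rel
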