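"""Evaluation: per-class and aggregate precision/recall/F1 excluding the
null label, one-vs-rest AUC over all 23 classes, McNemar's paired test, and
two-system overlap decomposition of gold relations.

The null label participates as a source of false positives/negatives for
the other classes but contributes no class of its own to the micro/macro
aggregates — a model that labels everything no_rel scores zero recall.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import precision_recall_fscore_support, roc_auc_score
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from .schema import (
    BIDIRECTIONAL_LABELS,
    INVERSE_LABELS,
    N_LABELS,
    POSITIVE_LABELS,
    RelationLabel,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ClassMetrics",
    "EvalReport",
    "OverlapReport",
    "prf",
    "auc_ovr",
    "mcnemar",
    "overlap",
    "f1_from_pr",
    "macro_f1_of",
]


def f1_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision < 0 or recall < 0:
        raise ValueError("precision and recall must be non-negative")
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def macro_f1_of(per_class_f1: Mapping["RelationLabel", float]) -> float:
    """Unweighted mean F1 over the 22 non-null classes."""
    missing = [lab.name for lab in POSITIVE_LABELS if lab not in per_class_f1]
    if missing:
        raise ValueError(f"missing per-class F1 for: {missing}")
    return float(np.mean([per_class_f1[lab] for lab in POSITIVE_LABELS]))


@dataclass(frozen=True)
class ClassMetrics:
    precision: float
    recall: float
    f1: float
    support: int
    zero_division: bool = False


@dataclass(frozen=True)
class EvalReport:
    per_class: Mapping[RelationLabel, ClassMetrics]
    micro_precision: float
    micro_recall: float
    micro_f1: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    auc: float | None = None
    confusion: Mapping[tuple[RelationLabel, RelationLabel], int] = field(default_factory=dict)

    def summary_rows(self) -> list[dict]:
        rows = [
            {
                "label": lab.name,
                "precision": m.precision,
                "recall": m.recall,
                "f1": m.f1,
                "support": m.support,
            }
            for lab, m in self.per_class.items()
        ]
        rows.append(
            {"label": "macro", "precision": self.macro_precision,
             "recall": self.macro_recall, "f1": self.macro_f1,
             "support": sum(m.support for m in self.per_class.values())}
        )
        rows.append(
            {"label": "micro", "precision": self.micro_precision,
             "recall": self.micro_recall, "f1": self.micro_f1,
             "support": sum(m.support for m in self.per_class.values())}
        )
        return rows


def prf(
    gold: Sequence[RelationLabel],
    pred: Sequence[RelationLabel],
    probs: np.ndarray | None = None,
) -> EvalReport:
    """Per-class and aggregate precision/recall/F1 over the 22 non-null
    classes.  Micro aggregates pool TP/FP/FN over non-null classes; macro
    is the unweighted mean over them.  Zero-division yields 0, flagged per
    class.  If ``probs`` is supplied the macro one-vs-rest AUC is included.
    """
    if len(gold) != len(pred):
        raise ValueError(f"gold/pred length mismatch: {len(gold)} vs {len(pred)}")
    y_true = np.array([g.index for g in gold])
    y_pred = np.array([p.index for p in pred])
    pos_idx = [lab.index for lab in POSITIVE_LABELS]

    p, r, f, s = precision_recall_fscore_support(
        y_true, y_pred, labels=pos_idx, zero_division=0
    )
    per_class = {}
    for lab, pi, ri, fi, si in zip(POSITIVE_LABELS, p, r, f, s):
        zd = (not np.any(y_pred == lab.index)) or si == 0
        per_class[lab] = ClassMetrics(float(pi), float(ri), float(fi), int(si), bool(zd))

    micro_p, micro_r, micro_f, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=pos_idx, average="micro", zero_division=0
    )
    macro_p, macro_r, macro_f, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=pos_idx, average="macro", zero_division=0
    )
    confusion: dict[tuple[RelationLabel, RelationLabel], int] = {}
    order = RelationLabel.ordered()
    for g, q in zip(gold, pred):
        confusion[(g, q)] = confusion.get((g, q), 0) + 1

    auc = auc_ovr(probs, gold) if probs is not None else None
    return EvalReport(
        per_class=per_class,
        micro_precision=float(micro_p),
        micro_recall=float(micro_r),
        micro_f1=float(micro_f),
        macro_precision=float(macro_p),
        macro_recall=float(macro_r),
        macro_f1=float(macro_f),
        auc=auc,
        confusion=confusion,
    )


def auc_ovr(probs: np.ndarray, gold: Sequence[RelationLabel]) -> float:
    """Macro-average one-vs-rest AUC over all 23 classes (null included).

    Classes lacking either a positive or a negative gold instance are
    skipped with a log message; at least two distinct gold labels are
    required overall.
    """
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 2 or probs.shape[1] != N_LABELS:
        raise ValueError(f"probs must be (n, {N_LABELS})")
    y = np.array([g.index for g in gold])
    if len(set(y.tolist())) < 2:
        raise ValueError("AUC undefined for single-class gold")
    aucs = []
    for lab in RelationLabel.ordered():
        is_c = y == lab.index
        if is_c.all() or not is_c.any():
            logger.info("AUC: skipping %s (no positives or no negatives)", lab.name)
            continue
        aucs.append(roc_auc_score(is_c, probs[:, lab.index]))
    return float(np.mean(aucs))


def mcnemar(
    correct_a: Sequence[bool], correct_b: Sequence[bool]
) -> tuple[float | None, float]:
    """McNemar's paired test on aligned per-instance correctness.

    With discordant counts b (A correct, B wrong) and c (A wrong, B
    correct): the exact two-sided binomial p when b + c < 25, otherwise the
    continuity-corrected chi-square statistic (|b-c|-1)^2/(b+c).  Returns
    (statistic or None, p); b + c = 0 gives (None, 1.0).
    """
    a = np.asarray(correct_a, dtype=bool)
    bb = np.asarray(correct_b, dtype=bool)
    if a.shape != bb.shape:
        raise ValueError("correctness vectors are misaligned")
    b = int(np.sum(a & ~bb))
    c = int(np.sum(~a & bb))
    if b + c == 0:
        return None, 1.0
    table = [[0, b], [c, 0]]  # only the discordant cells matter
    if b + c < 25:
        res = _sm_mcnemar(table, exact=True)
        return None, float(min(res.pvalue, 1.0))
    res = _sm_mcnemar(table, exact=False, correction=True)
    return float(res.statistic), float(res.pvalue)


RelationKey = tuple[str, str, str, str, str]  # doc, sent, subj, pred, obj


def canonical_relation_key(key: RelationKey) -> RelationKey:
    """Canonical form under the bidirectional / inverse equivalences:
    symmetric predicates order their arguments lexicographically; inverse
    pairs are rewritten to the alphabetically first predicate."""
    doc, sent, subj, pred, obj = key
    label = RelationLabel.from_name(pred)
    if label in BIDIRECTIONAL_LABELS and obj < subj:
        subj, obj = obj, subj
    elif label in INVERSE_LABELS:
        inv = INVERSE_LABELS[label]
        if inv.name < label.name:
            subj, obj, label = obj, subj, inv
    return (doc, sent, subj, label.name, obj)


@dataclass(frozen=True)
class OverlapReport:
    """Per-category partition of gold relations by which system found them."""

    both: Mapping[RelationLabel, int]
    a_only: Mapping[RelationLabel, int]
    b_only: Mapping[RelationLabel, int]
    neither: Mapping[RelationLabel, int]

    def totals(self) -> dict[str, int]:
        return {
            "both": sum(self.both.values()),
            "a_only": sum(self.a_only.values()),
            "b_only": sum(self.b_only.values()),
            "neither": sum(self.neither.values()),
        }


def overlap(
    gold: set[RelationKey],
    preds_a: set[RelationKey],
    preds_b: set[RelationKey],
) -> OverlapReport:
    """Partition each gold relation into found-by-both / A-only / B-only /
    neither, matching under the bidirectional and inverse equivalences."""
    ca = {canonical_relation_key(k) for k in preds_a}
    cb = {canonical_relation_key(k) for k in preds_b}
    both: dict[RelationLabel, int] = {}
    a_only: dict[RelationLabel, int] = {}
    b_only: dict[RelationLabel, int] = {}
    neither: dict[RelationLabel, int] = {}
    for key in gold:
        canon = canonical_relation_key(key)
        label = RelationLabel.from_name(key[3])
        in_a, in_b = canon in ca, canon in cb
        bucket = both if (in_a and in_b) else a_only if in_a else b_only if in_b else neither
        bucket[label] = bucket.get(label, 0) + 1
    return OverlapReport(both, a_only, b_only, neither)
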