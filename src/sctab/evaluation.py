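"""Ontology-corrected classification metrics.

Cell-type annotations differ in granularity across datasets: an author may
label a cell "T cell" while a classifier predicts the finer
"CD4-positive, alpha-beta T cell". The scoring rule here treats a prediction
as correct when it equals the annotated label or is a strict is_a descendant
of it (the prediction agrees with the truth up to the author's granularity),
and wrong when it is an ancestor of the truth or unrelated.

The metric is realized by relabeling descendant predictions to the truth term
and then accumulating an ordinary confusion matrix, which reproduces the
per-pair verdicts while keeping per-class fp/fn well defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import precision_recall_fscore_support

from .io import LabelSpace, OntologyDAG

__all__ = [
    "MatchDecision",
    "ClassScores",
    "EvaluationReport",
    "ontology_match",
    "corrected_macro_f1",
    "grouped_scores",
]


class MatchDecision(str, Enum):
    correct_exact = "correct_exact"
    correct_descendant = "correct_descendant"
    wrong_ancestor = "wrong_ancestor"
    wrong_other = "wrong_other"

    @property
    def is_correct(self) -> bool:
        return self in (MatchDecision.correct_exact, MatchDecision.correct_descendant)


@dataclass
class ClassScores:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float


@dataclass
class EvaluationReport:
    per_class: dict[str, ClassScores]
    macro_f1: float
    group_scores: dict[str, float] | None = None

    def to_dict(self) -> dict:
        return {
            "macro_f1": self.macro_f1,
            "per_class": {
                c: {"tp": s.tp, "fp": s.fp, "fn": s.fn, "precision": s.precision,
                    "recall": s.recall, "f1": s.f1}
                for c, s in self.per_class.items()
            },
            "group_scores": self.group_scores,
        }


def ontology_match(pred: str, truth: str, ontology: OntologyDAG) -> MatchDecision:
    """Classify a (prediction, truth) pair under the granularity-aware rule."""
    for term in (pred, truth):
        if term not in ontology:
            raise KeyError(f"term {term!r} not in ontology")
    if pred == truth:
        return MatchDecision.correct_exact
    if ontology.is_strict_descendant(pred, truth):
        return MatchDecision.correct_descendant
    if ontology.is_strict_descendant(truth, pred):
        return MatchDecision.wrong_ancestor
    return MatchDecision.wrong_other


def corrected_macro_f1(
    preds: Sequence[str],
    truths: Sequence[str],
    ontology: OntologyDAG,
    label_space: LabelSpace | None = None,
) -> EvaluationReport:
    """Macro-averaged F1 after ontology correction.

    Predictions that are strict descendants of their truth are relabeled to the
    truth term, then per-class precision/recall/F1 = 2tp/(2tp+fp+fn) are
    computed over the classes occurring in truths or (corrected) predictions,
    and averaged without class weights.
    """
    if len(preds) != len(truths):
        raise ValueError(f"length mismatch: {len(preds)} predictions vs {len(truths)} truths")
    corrected = [
        t if ontology_match(p, t, ontology).is_correct else p
        for p, t in zip(preds, truths)
    ]
    classes = sorted(set(truths) | set(corrected))
    if label_space is not None:
        unknown = set(classes) - set(label_space.classes)
        if unknown:
            raise KeyError(f"labels outside label space: {sorted(unknown)}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-division classes score 0 by definition
        prec, rec, f1, support = precision_recall_fscore_support(
            truths, corrected, labels=classes, average=None, zero_division=0
        )
    per_class: dict[str, ClassScores] = {}
    truths_arr = np.asarray(truths, dtype=object)
    corr_arr = np.asarray(corrected, dtype=object)
    for i, c in enumerate(classes):
        tp = int(np.sum((truths_arr == c) & (corr_arr == c)))
        fp = int(np.sum((truths_arr != c) & (corr_arr == c)))
        fn = int(np.sum((truths_arr == c) & (corr_arr != c)))
        per_class[c] = ClassScores(tp, fp, fn, float(prec[i]), float(rec[i]), float(f1[i]))
    return EvaluationReport(per_class=per_class, macro_f1=float(np.mean(f1)))


def grouped_scores(
    preds: Sequence[str],
    truths: Sequence[str],
    ontology: OntologyDAG,
    groups: Mapping[int, str] | Sequence[str],
) -> dict[str, float]:
    """Corrected macro F1 within each caller-supplied group of cells.

    ``groups`` assigns a group id to every cell (e.g. organ system); empty
    groups are omitted with a warning.
    """
    if not isinstance(groups, Mapping):
        groups = dict(enumerate(groups))
    if len(groups) != len(preds):
        raise ValueError("every cell needs a group assignment")
    out: dict[str, float] = {}
    for gid in sorted(set(groups.values())):
        idx = [i for i in range(len(preds)) if groups[i] == gid]
        if not idx:
            warnings.warn(f"group {gid!r} is empty; omitted", stacklevel=2)
            continue
        rep = corrected_macro_f1([preds[i] for i in idx], [truths[i] for i in idx], ontology)
        out[gid] = rep.macro_f1
    return out
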