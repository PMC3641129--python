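"""Scoring predicted complexes against a reference catalogue.

Two metric families are produced:

* **Match-based.**  A prediction P and a reference B match when their
  neighborhood affinity NA(P, B) = |P∩B|² / (|P|·|B|) reaches the
  threshold ω (default 0.2, comparison >=).  Precision is the fraction
  of predictions matching at least one reference, recall the fraction of
  references matched by at least one prediction, F1 their harmonic mean.

* **Contingency-based.**  With overlap counts t_ij = |ref_i ∩ pred_j|
  and reference sizes n_i: Sn = Σ_i max_j t_ij / Σ_i n_i measures how
  well references are covered; PPV = Σ_j max_i t_ij / Σ_j Σ_i t_ij
  measures how concentrated each prediction's overlap mass is (columns
  with zero total overlap are excluded from the denominator); accuracy
  is their geometric mean sqrt(Sn·PPV).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

from coan.errors import UsageError
from coan.io_formats import ComplexSet

logger = logging.getLogger(__name__)

__all__ = [
    "EvalReport",
    "neighborhood_affinity",
    "match_counts",
    "precision_recall_f1",
    "sn_ppv_acc",
    "evaluate",
]


@dataclass(frozen=True)
class EvalReport:
    """One row of evaluation results for a (predicted, reference) pair of sets."""

    n_predicted: int
    n_reference: int
    n_cp: int
    n_cb: int
    precision: float
    recall: float
    f1: float
    sensitivity: float
    ppv: float
    accuracy: float
    omega: float
    largest_predicted_size: int

    COLUMNS = (
        "n_predicted", "largest_predicted_size", "precision", "recall", "f1",
        "sensitivity", "ppv", "accuracy", "n_reference", "n_cp", "n_cb", "omega",
    )

    def as_row(self) -> dict[str, float | int]:
        return {k: getattr(self, k) for k in self.COLUMNS}

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t".join(self.COLUMNS) + "\n")
            fh.write("\t".join(_fmt(getattr(self, k)) for k in self.COLUMNS) + "\n")


def _fmt(x: float | int) -> str:
    return str(x) if isinstance(x, int) else f"{x:.6g}"


def neighborhood_affinity(p: frozenset[str] | set[str], b: frozenset[str] | set[str]) -> float:
    """NA(P, B) = |P∩B|² / (|P|·|B|); symmetric, in [0, 1]."""
    if not p or not b:
        raise UsageError("neighborhood affinity needs nonempty sets")
    inter = len(set(p) & set(b))
    return inter * inter / (len(p) * len(b))


def match_counts(pred: ComplexSet, ref: ComplexSet, omega: float = 0.2) -> tuple[int, int]:
    """(n_cp, n_cb): predictions matching >= 1 reference and vice versa."""
    if not (0.0 < omega <= 1.0):
        raise UsageError(f"omega must lie in (0, 1], got {omega}")
    preds, refs = pred.as_sets(), ref.as_sets()
    matched_pred = [False] * len(preds)
    matched_ref = [False] * len(refs)
    for i, p in enumerate(preds):
        for j, b in enumerate(refs):
            if neighborhood_affinity(p, b) >= omega:
                matched_pred[i] = True
                matched_ref[j] = True
    return sum(matched_pred), sum(matched_ref)


def precision_recall_f1(
    pred: ComplexSet, ref: ComplexSet, omega: float = 0.2
) -> tuple[float, float, float]:
    """Match-based precision, recall and F1 (zero when denominators vanish)."""
    n_cp, n_cb = match_counts(pred, ref, omega)
    precision = n_cp / len(pred) if len(pred) else 0.0
    recall = n_cb / len(ref) if len(ref) else 0.0
    f1 = (
        2.0 * precision * recall / (precision + recall)
        if precision + recall > 0.0
        else 0.0
    )
    return precision, recall, f1


def sn_ppv_acc(pred: ComplexSet, ref: ComplexSet) -> tuple[float, float, float]:
    """Contingency-table sensitivity, positive predictive value, accuracy."""
    preds, refs = pred.as_sets(), ref.as_sets()
    if not preds or not refs:
        logger.warning("empty predicted or reference set; Sn/PPV/Acc reported as 0")
        return 0.0, 0.0, 0.0
    t = [[len(b & p) for p in preds] for b in refs]
    sn_num = sum(max(row) for row in t)
    sn_den = sum(len(b) for b in refs)
    ppv_num = 0
    ppv_den = 0
    for j in range(len(preds)):
        col = [t[i][j] for i in range(len(refs))]
        tot = sum(col)
        if tot == 0:  # prediction disjoint from every reference: excluded
            continue
        ppv_num += max(col)
        ppv_den += tot
    sn = sn_num / sn_den if sn_den else 0.0
    ppv = ppv_num / ppv_den if ppv_den else 0.0
    return sn, ppv, math.sqrt(sn * ppv)


def evaluate(pred: ComplexSet, ref: ComplexSet, omega: float = 0.2) -> EvalReport:
    """Full report combining both metric families."""
    n_cp, n_cb = match_counts(pred, ref, omega)
    precision, recall, f1 = precision_recall_f1(pred, ref, omega)
    sn, ppv, acc = sn_ppv_acc(pred, ref)
    return EvalReport(
        n_predicted=len(pred),
        n_reference=len(ref),
        n_cp=n_cp,
        n_cb=n_cb,
        precision=precision,
        recall=recall,
        f1=f1,
        sensitivity=sn,
        ppv=ppv,
        accuracy=acc,
        omega=omega,
        largest_predicted_size=pred.largest_size,
    )
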