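"""Ranking and prediction metrics.

Patient recommendations are scored with a pooled precision-recall curve
(and its area, PRAUC) and mean average precision (MAP); top-1 disease
predictions are scored with per-disease precision/recall/F and their
unweighted macro-average, all under a configurable disease-matching
criterion.

Conventions (the input data never dictates these, so they are fixed
here and documented):

* The PR curve pools every (query, candidate) pair across queries and
  sweeps descending distinct score thresholds.  The recall denominator
  counts all relevant retrieved items plus one unreached relevant item
  for each query whose list contains none — a query whose true disease
  is never retrieved therefore holds recall below 1 instead of silently
  vanishing.  PRAUC is the trapezoid over the achieved (recall,
  precision) points, anchored at (0, precision of the first point).
* Average precision is the mean of precision@rank over the ranks of
  relevant items, 0 for a query that retrieves nothing relevant; MAP
  averages over all queries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .matching import DiseaseMatcher


@dataclass(frozen=True)
class RankedResult:
    """One query's ranked candidate diseases with relevance flags."""

    query_id: str
    ranking: tuple[tuple[str, float], ...]  # (disease_id, score), descending
    relevant: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.ranking) != len(self.relevant):
            raise ValueError("relevance flags must align with the ranking")


def ranked_result(
    query_id: str,
    ranking: Sequence[tuple[str, float]],
    truth: str,
    matcher: DiseaseMatcher,
) -> RankedResult:
    """Flag each ranked disease as relevant iff it matches the true diagnosis."""
    return RankedResult(
        query_id=query_id,
        ranking=tuple(ranking),
        relevant=tuple(matcher.match(d, truth) for d, _ in ranking),
    )


def pr_curve(results: Sequence[RankedResult]) -> tuple[list[tuple[float, float]], float]:
    """Pooled precision-recall points and trapezoidal PRAUC.

    Returns ``(points, prauc)`` with points as (recall, precision) in
    sweep order.  Raises when no relevant item exists anywhere (the
    curve would be undefined).
    """
    pooled: list[tuple[float, bool]] = []
    total_relevant = 0
    for res in results:
        n_rel = sum(res.relevant)
        total_relevant += n_rel if n_rel else 1  # unreached truth still counts
        pooled.extend((score, rel) for (_, score), rel in zip(res.ranking, res.relevant))
    if not pooled or all(not rel for _, rel in pooled):
        raise ValueError("pr_curve undefined: no relevant item in any ranking")
    thresholds = sorted({s for s, _ in pooled}, reverse=True)
    points: list[tuple[float, float]] = []
    for t in thresholds:
        retrieved = [rel for s, rel in pooled if s >= t]
        tp = sum(retrieved)
        points.append((tp / total_relevant, tp / len(retrieved)))
    recalls = np.array([0.0] + [r for r, _ in points])
    precisions = np.array([points[0][1]] + [p for _, p in points])
    prauc = float(np.trapezoid(precisions, recalls))
    return points, prauc


def average_precision(result: RankedResult) -> float:
    """Mean precision@rank over the ranks of relevant items (0 when none)."""
    hits = 0
    precisions = []
    for rank, rel in enumerate(result.relevant, start=1):
        if rel:
            hits += 1
            precisions.append(hits / rank)
    return float(np.mean(precisions)) if precisions else 0.0


def mean_average_precision(results: Sequence[RankedResult]) -> float:
    """MAP over all queries."""
    if not results:
        raise ValueError("mean_average_precision needs at least one result")
    return float(np.mean([average_precision(r) for r in results]))


@dataclass(frozen=True)
class DiseaseScore:
    """One row of the per-disease prediction table."""

    disease_id: str
    n_affected: int
    precision: float
    recall: float
    f_measure: float


def disease_prf(
    predictions: Sequence[tuple[str, str | None, str]],
    matcher: DiseaseMatcher,
    min_patients: int = 3,
) -> tuple[list[DiseaseScore], float]:
    """Per-disease precision/recall/F over top-1 predictions, plus macro-F.

    ``predictions`` holds (query_id, predicted_disease_or_None,
    true_disease).  A disease is evaluated when at least ``min_patients``
    queries carry it as truth.  For disease d:

    * TP — queries whose truth matches d and whose prediction matches
      the truth under the criterion;
    * FP — queries whose prediction matches d but not their own truth;
    * FN — queries whose truth matches d but whose prediction misses.

    Zero-denominator cells score 0.  Macro-F is the unweighted mean F
    over evaluated diseases.
    """
    affected: dict[str, int] = {}
    for _, _, truth in predictions:
        affected[truth] = affected.get(truth, 0) + 1
    evaluated = sorted(d for d, n in affected.items() if n >= min_patients)
    if not evaluated:
        return [], 0.0

    scores: list[DiseaseScore] = []
    for d in evaluated:
        tp = fp = fn = 0
        for _, pred, truth in predictions:
            correct = pred is not None and matcher.match(pred, truth)
            if matcher.match(truth, d):
                if correct:
                    tp += 1
                else:
                    fn += 1
            if pred is not None and matcher.match(pred, d) and not correct:
                fp += 1
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        scores.append(DiseaseScore(d, affected[d], precision, recall, f))
    macro_f = float(np.mean([s.f_measure for s in scores]))
    return scores, macro_f


@dataclass
class EvaluationReport:
    """Everything one evaluation run produces, JSON-serializable."""

    criterion: str
    pr_points: list[tuple[float, float]]
    prauc: float
    map: float
    disease_scores: list[DiseaseScore] = field(default_factory=list)
    macro_f: float = 0.0

    def to_dict(self) -> dict:
        return {
            "criterion": self.criterion,
            "pr_points": [[round(r, 12), round(p, 12)] for r, p in self.pr_points],
            "prauc": round(self.prauc, 12),
            "map": round(self.map, 12),
            "disease_scores": [
                {
                    "disease_id": s.disease_id,
                    "n_affected": s.n_affected,
                    "precision": round(s.precision, 12),
                    "recall": round(s.recall, 12),
                    "f_measure": round(s.f_measure, 12),
                }
                for s in self.disease_scores
            ],
            "macro_f": round(self.macro_f, 12),
        }


def evaluate_rankings(
    results: Sequence[RankedResult],
    predictions: Sequence[tuple[str, str | None, str]],
    matcher: DiseaseMatcher,
    min_patients: int = 3,
) -> EvaluationReport:
    """Bundle PR curve, MAP, and per-disease P/R/F into one report."""
    points, prauc = pr_curve(results)
    scores, macro_f = disease_prf(predictions, matcher, min_patients)
    return EvaluationReport(
        criterion=str(matcher.criterion.tag.value),
        pr_points=points,
        prauc=prauc,
        map=mean_average_precision(results),
        disease_scores=scores,
        macro_f=macro_f,
    )
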