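"""User-based collaborative-filtering recommender for disease diagnosis.

:class:`NeighborhoodRecommender` is a scikit-learn-style estimator.  It
is fit on binary phenotype profiles with disease labels, and for a query
phenotype set it (1) scores every training profile with the configured
similarity measure, (2) selects a neighborhood with KNN or TPN, and
(3) aggregates neighbor labels into a ranked disease recommendation by
similarity-weighted voting:

    score(d) = sum of similarities of selected neighbors labeled d
             / sum of similarities of all selected neighbors

so the scores form a probability-like vector (non-negative, summing to 1
whenever the neighborhood is non-empty).  Negative similarities (possible
under Fager & McGowan) are clamped to zero for weighting; if every
selected neighbor has zero weight the vote falls back to uniform weights.

Neighborhood parameters (k for KNN, the threshold t for TPN) are tuned
by root-mean-square error over leave-one-out rating predictions with
sampled negative diseases — see :func:`rmse` and :func:`tune`.
"""

from __future__ import annotations

from dataclasses import dataclass
import math
import random
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, clone

from .neighborhood import Rule, knn_neighbors, tpn_neighbors
from .similarity import MEASURES, SimilarityContext, score_all
from .types import AssociationTable, EntityProfile, Source


@dataclass(frozen=True)
class Recommendation:
    """Ranked (disease, score) list with per-disease contributing neighbors."""

    ranked: tuple[tuple[str, float], ...]
    provenance: dict[str, tuple[str, ...]]

    def __len__(self) -> int:
        return len(self.ranked)

    @property
    def top(self) -> str | None:
        return self.ranked[0][0] if self.ranked else None

    def score_of(self, disease_id: str) -> float:
        for d, s in self.ranked:
            if d == disease_id:
                return s
        return 0.0


EvalPair = tuple[str | None, frozenset, str]  # (query entity id, phenotypes, truth)


class NeighborhoodRecommender(BaseEstimator):
    """Phenotype-profile collaborative filtering with KNN or TPN neighborhoods.

    Parameters
    ----------
    measure : {"tani", "ll", "ol", "fmg"}
        Profile similarity coefficient.
    neighborhood : {"knn", "tpn"}
        Neighborhood rule; ``k`` applies to KNN, ``t`` to TPN, and the
        inactive parameter is ignored.
    k : int
        Neighbor count for KNN.
    t : float
        Strict similarity threshold for TPN.

    Attributes
    ----------
    table_ : AssociationTable
        The fitted training profiles.
    context_ : SimilarityContext
        Phenotype-universe size, fixed at fit time (used by "ll").
    classes_ : ndarray of str
        Sorted distinct disease labels seen at fit.
    """

    def __init__(
        self,
        measure: str = "tani",
        neighborhood: str = "knn",
        k: int = 5,
        t: float = 0.5,
    ) -> None:
        self.measure = measure
        self.neighborhood = neighborhood
        self.k = k
        self.t = t

    # -- fitting --------------------------------------------------------

    def _validate_params_(self) -> None:
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}; expected one of {MEASURES}")
        Rule(self.neighborhood)
        if self.neighborhood == "knn" and self.k < 0:
            raise ValueError(f"k must be non-negative, got {self.k}")

    def fit(self, X: Iterable[Iterable[str]], y: Sequence[str]) -> "NeighborhoodRecommender":
        """Fit from parallel sequences of phenotype sets and disease labels."""
        X = list(X)
        y = list(y)
        if len(X) != len(y):
            raise ValueError(f"X and y length mismatch: {len(X)} vs {len(y)}")
        width = max(5, len(str(max(len(X) - 1, 0))))
        table = AssociationTable(
            EntityProfile(f"E{i:0{width}d}", Source.EMR, frozenset(xs), label)
            for i, (xs, label) in enumerate(zip(X, y))
        )
        return self.fit_table(table)

    def fit_table(self, table: AssociationTable) -> "NeighborhoodRecommender":
        """Fit directly from an association table, keeping its entity ids."""
        self._validate_params_()
        if len(table) == 0:
            raise ValueError("cannot fit on an empty table")
        self.table_ = table
        self.context_ = SimilarityContext(len(table.phenotype_universe))
        self.classes_ = np.asarray(sorted(table.disease_ids), dtype=object)
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "table_"):
            raise RuntimeError("recommender is not fitted; call fit or fit_table first")

    # -- recommendation -------------------------------------------------

    def _neighbors(self, query: frozenset, exclude_id: str | None):
        ctx = self.context_
        universe = len(self.table_.phenotype_universe | frozenset(query))
        if universe > ctx.universe_size:
            ctx = SimilarityContext(universe)
        smap = score_all(query, self.table_, self.measure, ctx, query_id=exclude_id)
        if self.neighborhood == "knn":
            selected = knn_neighbors(smap, self.k)
        else:
            selected = tpn_neighbors(smap, self.t)
        scores = dict(smap.entries)
        return [(nid, scores[nid]) for nid in selected.neighbor_ids]

    def recommend(
        self,
        query: Iterable[str],
        top_n: int | None = None,
        exclude_id: str | None = None,
    ) -> Recommendation:
        """Ranked disease recommendation for one query phenotype set.

        ``exclude_id`` removes the named training entity from the
        candidate neighborhood (leave-one-out hygiene).  An empty
        neighborhood yields an empty recommendation.
        """
        self._check_fitted()
        query = frozenset(query)
        if not query:
            raise ValueError("query phenotype set must be non-empty")
        selected = self._neighbors(query, exclude_id)
        if not selected:
            return Recommendation(ranked=(), provenance={})
        weights = [max(s, 0.0) for _, s in selected]
        denom = sum(weights)
        if denom <= 0.0:
            weights = [1.0] * len(selected)  # uniform fallback, keeps sum == 1
            denom = float(len(selected))
        votes: dict[str, float] = {}
        contributors: dict[str, list[str]] = {}
        for (nid, _), w in zip(selected, weights):
            d = self.table_[nid].disease
            votes[d] = votes.get(d, 0.0) + w
            contributors.setdefault(d, []).append(nid)
        ranked = sorted(((d, v / denom) for d, v in votes.items()), key=lambda e: (-e[1], e[0]))
        if top_n is not None:
            ranked = ranked[:top_n]
        return Recommendation(
            ranked=tuple(ranked),
            provenance={d: tuple(contributors[d]) for d, _ in ranked},
        )

    def predict_top1(self, query: Iterable[str], exclude_id: str | None = None) -> str | None:
        """Top-ranked disease for a query, or None when no neighbor qualifies."""
        return self.recommend(query, top_n=1, exclude_id=exclude_id).top

    def predict(self, X: Iterable[Iterable[str]]) -> np.ndarray:
        """Top-1 disease per query (object array; None for empty neighborhoods)."""
        self._check_fitted()
        return np.asarray([self.predict_top1(q) for q in X], dtype=object)

    def score(self, X: Iterable[Iterable[str]], y: Sequence[str]) -> float:
        """Top-1 accuracy (exact disease-id match)."""
        preds = self.predict(X)
        y = list(y)
        if not y:
            raise ValueError("empty evaluation set")
        return float(sum(p == t for p, t in zip(preds, y)) / len(y))


# -- parameter tuning by RMSE ------------------------------------------


def loo_eval_pairs(table: AssociationTable) -> list[EvalPair]:
    """Leave-one-out evaluation pairs over the EMR-source profiles."""
    return [
        (prof.entity_id, prof.phenotypes, prof.disease)
        for prof in table
        if prof.source is Source.EMR
    ]


def rmse(
    model: NeighborhoodRecommender,
    eval_pairs: Sequence[EvalPair],
    negatives_per_positive: int = 4,
    seed: int = 0,
) -> float:
    """Root-mean-square rating error over held-out (patient, disease) cells.

    For each evaluation pair the patient's true diagnosis is rated 1 and
    ``negatives_per_positive`` uniformly sampled other diseases are
    rated 0; the predicted rating of a disease is its recommendation
    score (0 when unranked).  The query entity is excluded from its own
    neighborhood.
    """
    if negatives_per_positive < 0:
        raise ValueError("negatives_per_positive must be non-negative")
    if not eval_pairs:
        raise ValueError("eval_pairs must be non-empty")
    model._check_fitted()
    rng = random.Random(seed)
    diseases = sorted(model.table_.disease_ids)
    sq_errors: list[float] = []
    for query_id, phenotypes, truth in eval_pairs:
        rec = model.recommend(phenotypes, exclude_id=query_id)
        sq_errors.append((1.0 - rec.score_of(truth)) ** 2)
        candidates = [d for d in diseases if d != truth]
        n_neg = min(negatives_per_positive, len(candidates))
        for neg in rng.sample(candidates, n_neg):
            sq_errors.append(rec.score_of(neg) ** 2)
    return math.sqrt(sum(sq_errors) / len(sq_errors))


@dataclass(frozen=True)
class TuningResult:
    """RMSE profile over a parameter grid; optimal = argmin (first on ties)."""

    grid: tuple[float, ...]
    rmse: tuple[float, ...]
    optimal: float

    def as_dict(self) -> dict[float, float]:
        return dict(zip(self.grid, self.rmse))


def tune(
    model: NeighborhoodRecommender,
    grid: Sequence[float],
    eval_pairs: Sequence[EvalPair],
    negatives_per_positive: int = 4,
    seed: int = 0,
) -> TuningResult:
    """Evaluate RMSE at every grid point of the active neighborhood parameter.

    Every grid point sees the identical evaluation pairs and negative
    samples (same seed), so the curve isolates the parameter's effect.
    """
    if not list(grid):
        raise ValueError("grid must be non-empty")
    model._check_fitted()
    param = "k" if model.neighborhood == "knn" else "t"
    errors: list[float] = []
    for value in grid:
        candidate = clone(model)
        candidate.set_params(**{param: int(value) if param == "k" else float(value)})
        candidate.fit_table(model.table_)
        errors.append(rmse(candidate, eval_pairs, negatives_per_positive, seed))
    best = grid[int(np.argmin(errors))]
    return TuningResult(
        grid=tuple(float(g) for g in grid),
        rmse=tuple(errors),
        optimal=float(best),
    )
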