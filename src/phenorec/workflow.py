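"""End-to-end experiment groups: simulate/load -> fuse -> fit -> evaluate.

An evaluation *group* is one cell of the experiment grid: a similarity
measure x a neighborhood rule x a fusion strategy, evaluated under a
disease-matching criterion.  The full grid of 4 measures x 2 rules x 3
strategies enumerates 24 groups; :func:`sweep` runs them all on one
corpus and returns a deterministic, JSON-serializable report per group.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

from .evaluation import EvaluationReport, evaluate_rankings, ranked_result
from .fusion import FusionStrategy, Strategy, filter_predications, fuse, merge_literature
from .matching import CRITERIA, DiseaseMatcher
from .recommender import NeighborhoodRecommender
from .similarity import MEASURES
from .simulate import SyntheticCorpus, holdout_queries, split_table
from .types import AssociationTable

NEIGHBORHOODS = ("knn", "tpn")
STRATEGIES = ("emr", "emr_l", "emr_pl")

# operating defaults for the TPN threshold, matched to each coefficient's scale
DEFAULT_T = {"tani": 0.1, "ll": 0.3, "ol": 0.3, "fmg": 0.05}
DEFAULT_K_GRID = tuple(range(1, 16))
DEFAULT_T_GRID = tuple(round(0.05 * i, 2) for i in range(1, 20))


@dataclass(frozen=True)
class GroupConfig:
    """One evaluation group: model, fusion, matching, and split settings."""

    measure: str = "tani"
    neighborhood: str = "knn"
    strategy: str = "emr"
    k: int = 5
    t: float | None = None
    criterion: str = "string"
    test_fraction: float = 0.2
    top_n: int = 10
    min_patients_eval: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}")
        if self.neighborhood not in NEIGHBORHOODS:
            raise ValueError(f"unknown neighborhood {self.neighborhood!r}")
        Strategy(self.strategy)
        if self.criterion not in CRITERIA:
            raise ValueError(f"unknown criterion {self.criterion!r}")

    @property
    def name(self) -> str:
        return f"{self.measure}_{self.neighborhood}_{self.strategy}"

    @property
    def threshold(self) -> float:
        return DEFAULT_T[self.measure] if self.t is None else self.t


def literature_table(corpus: SyntheticCorpus) -> AssociationTable:
    """Ingest the corpus predications into merged literature profiles."""
    triples = filter_predications(
        corpus.predications, corpus.phenotype_vocab, corpus.disease_vocab
    )
    return merge_literature(triples)


def run_group(
    corpus: SyntheticCorpus, config: GroupConfig
) -> tuple[EvaluationReport, dict]:
    """Run one group end to end; returns the report plus a manifest.

    The EMR table is split disease-stratified before fusion so that
    held-out queries never leak into the literature mixing; the fused
    training table feeds the recommender, and every held-out patient is
    queried for a ranked recommendation and a top-1 prediction.
    """
    train_emr, test_emr = split_table(corpus.emr, config.test_fraction, config.seed)
    lit = literature_table(corpus)
    fused = fuse(FusionStrategy(Strategy(config.strategy), config.seed), train_emr, lit)
    model = NeighborhoodRecommender(
        measure=config.measure,
        neighborhood=config.neighborhood,
        k=config.k,
        t=config.threshold,
    ).fit_table(fused)
    matcher = DiseaseMatcher(corpus.disease_vocab, config.criterion)

    results = []
    predictions = []
    for query_id, phenotypes, truth in holdout_queries(test_emr):
        rec = model.recommend(phenotypes, top_n=config.top_n)
        results.append(ranked_result(query_id, rec.ranked, truth, matcher))
        predictions.append((query_id, rec.top, truth))
    report = evaluate_rankings(results, predictions, matcher, config.min_patients_eval)

    cfg_dict = asdict(config)
    manifest = {
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest()[:16],
        "sim_seed": corpus.config.seed,
        "fused_stats": asdict(fused.stats(corpus.disease_vocab)),
        "n_queries": len(test_emr),
    }
    return report, manifest


@dataclass
class SweepResult:
    """All 24 group reports plus their manifests, keyed by group name."""

    reports: dict[str, EvaluationReport] = field(default_factory=dict)
    manifests: dict[str, dict] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            name: {"report": rep.to_dict(), "manifest": self.manifests[name]}
            for name, rep in self.reports.items()
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def sweep(
    corpus: SyntheticCorpus,
    criterion: str = "string",
    seed: int = 0,
    measures: Sequence[str] = MEASURES,
    neighborhoods: Sequence[str] = NEIGHBORHOODS,
    strategies: Sequence[str] = STRATEGIES,
    **group_kwargs,
) -> SweepResult:
    """Run the full measure x neighborhood x strategy grid on one corpus."""
    out = SweepResult()
    for measure in measures:
        for neighborhood in neighborhoods:
            for strategy in strategies:
                config = GroupConfig(
                    measure=measure,
                    neighborhood=neighborhood,
                    strategy=strategy,
                    criterion=criterion,
                    seed=seed,
                    **group_kwargs,
                )
                report, manifest = run_group(corpus, config)
                out.reports[config.name] = report
                out.manifests[config.name] = manifest
    return out
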