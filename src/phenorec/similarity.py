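"""Binary-profile similarity measures.

Four set-similarity coefficients over binary phenotype profiles, written
for two profiles ``P_m`` and ``P_n`` with intersection ``c``:

* Tanimoto (TANI):  ``c / (|P_m| + |P_n| - c)`` — the Jaccard index.
* Overlap (OL):     ``c / min(|P_m|, |P_n|)``.
* Fager & McGowan (FMG): ``c / sqrt(|P_m|·|P_n|) - 1 / (2·sqrt(max(|P_m|, |P_n|)))``.
* Log-likelihood ratio (LL): Dunning's G² statistic of the 2x2
  phenotype-co-occurrence contingency table, squashed to [0, 1) by
  ``1 - 1/(1 + G²)`` so it is comparable with the bounded coefficients.

The LL contingency table needs the size ``N`` of the phenotype universe
(the distinct phenotypes of the fused training table), carried by
:class:`SimilarityContext`:

====  =============  ==================
cell  value          meaning
====  =============  ==================
k11   |P_m ∩ P_n|    shared phenotypes
k12   |P_m \\ P_n|    only in m
k21   |P_n \\ P_m|    only in n
k22   N - |P_m ∪ P_n|  in neither
====  =============  ==================

Every measure is total: an empty operand yields 0 rather than an error,
since ingest guarantees non-empty profiles and a defined zero avoids NaN
propagation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .types import AssociationTable

MEASURES = ("tani", "ol", "fmg", "ll")


@dataclass(frozen=True)
class SimilarityContext:
    """Phenotype-universe size for the log-likelihood contingency table."""

    universe_size: int

    def __post_init__(self) -> None:
        if self.universe_size < 0:
            raise ValueError("universe_size must be non-negative")


def tanimoto(p_m: frozenset[str] | set[str], p_n: frozenset[str] | set[str]) -> float:
    if not p_m or not p_n:
        return 0.0
    c = len(p_m & p_n)
    return c / (len(p_m) + len(p_n) - c)


def overlap(p_m: frozenset[str] | set[str], p_n: frozenset[str] | set[str]) -> float:
    if not p_m or not p_n:
        return 0.0
    return len(p_m & p_n) / min(len(p_m), len(p_n))


def fmg(p_m: frozenset[str] | set[str], p_n: frozenset[str] | set[str]) -> float:
    if not p_m or not p_n:
        return 0.0
    c = len(p_m & p_n)
    return c / math.sqrt(len(p_m) * len(p_n)) - 1.0 / (
        2.0 * math.sqrt(max(len(p_m), len(p_n)))
    )


def g2_statistic(k11: int, k12: int, k21: int, k22: int) -> float:
    """Dunning's G² for a 2x2 contingency table; zero-count cells contribute 0."""
    n = k11 + k12 + k21 + k22
    if n == 0:
        return 0.0
    rows = (k11 + k12, k21 + k22)
    cols = (k11 + k21, k12 + k22)
    cells = ((k11, 0, 0), (k12, 0, 1), (k21, 1, 0), (k22, 1, 1))
    total = 0.0
    for k, i, j in cells:
        if k > 0:
            total += k * math.log(k * n / (rows[i] * cols[j]))
    # independence can leave a tiny negative residual in floating point
    return max(2.0 * total, 0.0)


def log_likelihood_sim(
    p_m: frozenset[str] | set[str],
    p_n: frozenset[str] | set[str],
    ctx: SimilarityContext,
) -> float:
    if not p_m or not p_n:
        return 0.0
    union = len(p_m | p_n)
    if ctx.universe_size < union:
        raise ValueError(
            f"universe_size {ctx.universe_size} smaller than |P_m ∪ P_n| = {union}"
        )
    k11 = len(p_m & p_n)
    k12 = len(p_m) - k11
    k21 = len(p_n) - k11
    k22 = ctx.universe_size - union
    g2 = g2_statistic(k11, k12, k21, k22)
    return 1.0 - 1.0 / (1.0 + g2)


_FUNCS = {"tani": tanimoto, "ol": overlap, "fmg": fmg}


def compute_similarity(
    measure: str,
    p_m: frozenset[str] | set[str],
    p_n: frozenset[str] | set[str],
    ctx: SimilarityContext | None = None,
) -> float:
    """Dispatch on the measure token ``tani | ol | fmg | ll``."""
    if measure == "ll":
        if ctx is None:
            raise ValueError("measure 'll' requires a SimilarityContext")
        return log_likelihood_sim(p_m, p_n, ctx)
    try:
        return _FUNCS[measure](p_m, p_n)
    except KeyError:
        raise ValueError(f"unknown measure {measure!r}; expected one of {MEASURES}") from None


@dataclass(frozen=True)
class ScoreMap:
    """Per-query similarity scores against every neighbor, sorted.

    Entries are (neighbor_id, score), descending by score with ascending
    neighbor id as the tie-break; the query entity itself never appears.
    """

    query_id: str | None
    entries: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        ids = [nid for nid, _ in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate neighbor ids in ScoreMap")
        keys = [(-s, nid) for nid, s in self.entries]
        if keys != sorted(keys):
            raise ValueError("ScoreMap entries must be sorted by descending score")

    def __len__(self) -> int:
        return len(self.entries)


def score_all(
    query: frozenset[str] | set[str],
    table: AssociationTable,
    measure: str,
    ctx: SimilarityContext | None = None,
    query_id: str | None = None,
) -> ScoreMap:
    """Score ``query`` against every profile in ``table``.

    ``query_id`` names the query entity so it can be excluded from its
    own neighborhood (leave-one-out hygiene).  For the LL measure the
    context defaults to the table's own phenotype universe enlarged to
    cover the query.
    """
    if measure == "ll" and ctx is None:
        universe = table.phenotype_universe | frozenset(query)
        ctx = SimilarityContext(len(universe))
    scored = [
        (prof.entity_id, compute_similarity(measure, query, prof.phenotypes, ctx))
        for prof in table
        if prof.entity_id != query_id
    ]
    scored.sort(key=lambda e: (-e[1], e[0]))
    return ScoreMap(query_id=query_id, entries=tuple(scored))
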