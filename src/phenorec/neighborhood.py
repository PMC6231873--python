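"""Neighborhood identification: k-nearest neighbors and threshold neighbors.

Both rules consume a sorted :class:`~phenorec.similarity.ScoreMap` and
walk it greedily, exactly once:

* KNN keeps the first ``min(k, n)`` entries — the sorted prefix.  Ties
  at the k-th score are resolved by the map's own ordering (descending
  score, ascending entity id); the list never grows beyond ``k``.
* TPN keeps every entry whose score is *strictly* greater than the
  threshold ``t``; boundary scores equal to ``t`` are excluded.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .similarity import ScoreMap


class Rule(str, enum.Enum):
    KNN = "knn"
    TPN = "tpn"


@dataclass(frozen=True)
class NeighborList:
    """Selected neighbors in selection order, with the rule that chose them."""

    neighbor_ids: tuple[str, ...]
    rule: Rule
    parameter: float

    def __len__(self) -> int:
        return len(self.neighbor_ids)


def knn_neighbors(score_map: ScoreMap, k: int) -> NeighborList:
    """The top-``min(k, n)`` neighbors of the sorted score map."""
    if k < 0:
        raise ValueError(f"k must be non-negative, got {k}")
    ids = tuple(nid for nid, _ in score_map.entries[:k])
    return NeighborList(ids, Rule.KNN, float(k))


def tpn_neighbors(score_map: ScoreMap, t: float) -> NeighborList:
    """All neighbors with similarity strictly above ``t``, in order."""
    ids = tuple(nid for nid, score in score_map.entries if score > t)
    return NeighborList(ids, Rule.TPN, float(t))
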