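"""Disease-equivalence criteria for evaluation.

Three increasingly relaxed notions of "the predicted disease is right":

* ``string`` — the normalized names are equal, or either disease's
  normalized name appears among the other's synonyms.
* ``concept`` — both diseases carry a semantic-equivalence key
  (SNOMED-like concept class) and the keys are equal.  A disease with
  no key matches only itself.
* ``category`` — the diseases' category sets (GARD-like disease-system
  groups) intersect.  Reflexive and symmetric but not transitive, since
  a disease may sit in several categories.

Identity (same disease id) matches under every criterion.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .text import normalize
from .types import DiseaseTerm

CRITERIA = ("string", "concept", "category")


class Criterion(str, enum.Enum):
    STRING = "string"
    CONCEPT = "concept"
    CATEGORY = "category"


@dataclass(frozen=True)
class MatchCriterion:
    """A criterion tag plus the maps the relaxed criteria require.

    ``concept_map`` and ``category_map`` override the fields on the
    :class:`DiseaseTerm` objects when provided; by default the terms'
    own ``concept_key`` / ``categories`` are used.
    """

    tag: Criterion
    concept_map: dict[str, str] = field(default_factory=dict)
    category_map: dict[str, frozenset[str]] = field(default_factory=dict)


def diseases_match(
    d1: DiseaseTerm, d2: DiseaseTerm, criterion: MatchCriterion | Criterion | str
) -> bool:
    """Whether two diseases count as equivalent under the criterion."""
    if not isinstance(criterion, MatchCriterion):
        criterion = MatchCriterion(Criterion(criterion))
    if d1.disease_id == d2.disease_id:
        return True
    if criterion.tag is Criterion.STRING:
        n1, n2 = normalize(d1.name), normalize(d2.name)
        syn1 = {normalize(s) for s in d1.synonyms}
        syn2 = {normalize(s) for s in d2.synonyms}
        return n1 == n2 or n1 in syn2 or n2 in syn1
    if criterion.tag is Criterion.CONCEPT:
        k1 = criterion.concept_map.get(d1.disease_id, d1.concept_key)
        k2 = criterion.concept_map.get(d2.disease_id, d2.concept_key)
        return bool(k1) and k1 == k2
    c1 = criterion.category_map.get(d1.disease_id, d1.categories)
    c2 = criterion.category_map.get(d2.disease_id, d2.categories)
    return bool(frozenset(c1) & frozenset(c2))


class DiseaseMatcher:
    """Id-level matching against a disease vocabulary, with memoization."""

    def __init__(
        self,
        vocab: dict[str, DiseaseTerm],
        criterion: MatchCriterion | Criterion | str,
    ) -> None:
        self.vocab = vocab
        if not isinstance(criterion, MatchCriterion):
            criterion = MatchCriterion(Criterion(criterion))
        self.criterion = criterion
        self._cache: dict[tuple[str, str], bool] = {}

    def match(self, id1: str, id2: str) -> bool:
        if id1 == id2:
            return True
        key = (id1, id2) if id1 < id2 else (id2, id1)
        hit = self._cache.get(key)
        if hit is None:
            try:
                t1, t2 = self.vocab[id1], self.vocab[id2]
            except KeyError as exc:
                raise KeyError(f"disease {exc.args[0]!r} not in vocabulary") from None
            hit = diseases_match(t1, t2, self.criterion)
            self._cache[key] = hit
        return hit
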