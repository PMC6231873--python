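"""Domain types: vocabulary terms, entity profiles, and the association table.

An *entity* is either a patient (one EMR record) or a merged literature
document; both carry a binary phenotype profile (a set of phenotype term
ids) and exactly one rare-disease label.  The association table is the
training container consumed by the recommender: a keyed collection of
profiles from which the distinct (phenotype, disease) pair set and the
phenotype universe are derived.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator


class Source(str, enum.Enum):
    """Provenance of a profile: patient record or merged literature document."""

    EMR = "EMR"
    LIT = "LIT"


@dataclass(frozen=True)
class PhenotypeTerm:
    """A phenotype vocabulary entry (HPO-like)."""

    term_id: str
    name: str
    synonyms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.term_id:
            raise ValueError("phenotype term_id must be non-empty")
        if not self.name:
            raise ValueError(f"phenotype {self.term_id!r}: name must be non-empty")


@dataclass(frozen=True)
class DiseaseTerm:
    """A rare-disease vocabulary entry (GARD-like).

    ``concept_key`` is a flat semantic-equivalence class (SNOMED-like):
    two diseases with the same non-empty key are considered the same
    concept.  ``categories`` is the set of disease-system categories the
    disease belongs to; it may be empty.
    """

    disease_id: str
    name: str
    synonyms: frozenset[str] = frozenset()
    concept_key: str | None = None
    categories: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.disease_id:
            raise ValueError("disease_id must be non-empty")
        if not self.name:
            raise ValueError(f"disease {self.disease_id!r}: name must be non-empty")


@dataclass(frozen=True)
class EntityProfile:
    """One patient or merged literature document: binary phenotype set plus label."""

    entity_id: str
    source: Source
    phenotypes: frozenset[str]
    disease: str

    def __post_init__(self) -> None:
        if not self.entity_id:
            raise ValueError("entity_id must be non-empty")
        if not self.disease:
            raise ValueError(f"entity {self.entity_id!r}: disease label required")
        if not self.phenotypes:
            raise ValueError(
                f"entity {self.entity_id!r}: phenotype set must be non-empty"
            )
        object.__setattr__(self, "phenotypes", frozenset(self.phenotypes))
        object.__setattr__(self, "source", Source(self.source))


@dataclass(frozen=True)
class Predication:
    """A subject-predicate-object triple extracted from one document."""

    doc_id: str
    subject: str
    predicate: str
    object: str

    def __post_init__(self) -> None:
        for f in ("doc_id", "subject", "predicate", "object"):
            if not getattr(self, f):
                raise ValueError(f"predication field {f!r} must be non-empty")


@dataclass(frozen=True)
class TableStats:
    """Corpus statistics: one row of a dataset-statistics table."""

    entities: int
    phenotypes: int
    diseases: int
    associations: int
    categories_covered: int


class AssociationTable:
    """Ordered collection of :class:`EntityProfile`, keyed by entity id.

    Storage order is preserved (it matters only for serialization; all
    model outputs are order-invariant).  Equality compares the id ->
    profile mapping, ignoring storage order.
    """

    def __init__(self, profiles: Iterable[EntityProfile] = ()) -> None:
        self._profiles: dict[str, EntityProfile] = {}
        for p in profiles:
            self.add(p)

    def add(self, profile: EntityProfile) -> None:
        existing = self._profiles.get(profile.entity_id)
        if existing is not None:
            if existing.disease != profile.disease:
                raise ValueError(
                    f"entity {profile.entity_id!r}: conflicting disease labels "
                    f"{existing.disease!r} vs {profile.disease!r} "
                    "(multi-label profiles are rejected)"
                )
            profile = EntityProfile(
                profile.entity_id,
                profile.source,
                existing.phenotypes | profile.phenotypes,
                profile.disease,
            )
        self._profiles[profile.entity_id] = profile

    # -- access ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self._profiles)

    def __iter__(self) -> Iterator[EntityProfile]:
        return iter(self._profiles.values())

    def __contains__(self, entity_id: str) -> bool:
        return entity_id in self._profiles

    def __getitem__(self, entity_id: str) -> EntityProfile:
        return self._profiles[entity_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AssociationTable):
            return NotImplemented
        return self._profiles == other._profiles

    @property
    def entity_ids(self) -> list[str]:
        return list(self._profiles)

    # -- derived sets ---------------------------------------------------

    @property
    def pair_set(self) -> frozenset[tuple[str, str]]:
        """All distinct (phenotype_id, disease_id) association pairs."""
        return frozenset(
            (p, prof.disease) for prof in self for p in prof.phenotypes
        )

    @property
    def phenotype_universe(self) -> frozenset[str]:
        return frozenset(p for prof in self for p in prof.phenotypes)

    @property
    def disease_ids(self) -> frozenset[str]:
        return frozenset(prof.disease for prof in self)

    def stats(self, disease_vocab: dict[str, DiseaseTerm] | None = None) -> TableStats:
        """Corpus counts; category coverage needs the disease vocabulary."""
        categories: set[str] = set()
        if disease_vocab is not None:
            for d in self.disease_ids:
                term = disease_vocab.get(d)
                if term is not None:
                    categories |= term.categories
        return TableStats(
            entities=len(self),
            phenotypes=len(self.phenotype_universe),
            diseases=len(self.disease_ids),
            associations=len(self.pair_set),
            categories_covered=len(categories),
        )

    def __repr__(self) -> str:  # pragma: no cover
        s = self.stats()
        return (
            f"AssociationTable(entities={s.entities}, phenotypes={s.phenotypes}, "
            f"diseases={s.diseases}, associations={s.associations})"
        )


def table_stats(
    table: AssociationTable, disease_vocab: dict[str, DiseaseTerm] | None = None
) -> TableStats:
    """Functional alias for :meth:`AssociationTable.stats`."""
    return table.stats(disease_vocab)
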