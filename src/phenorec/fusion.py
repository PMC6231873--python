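"""Heterogeneous data fusion: literature ingest and EMR-literature mixing.

Three strategies prepare the training table:

* ``emr`` — patient profiles only.
* ``emr_l`` — literature predications are filtered to phenotype-disease
  pairs, all documents sharing a disease are merged into one large
  document, and the merged documents are mixed with the patients under a
  seeded random permutation (storage order only; the model is
  order-invariant).
* ``emr_pl`` — as ``emr_l``, but a literature (phenotype, disease) pair
  is retained only if it also occurs in the EMR pair set ("pruned
  literature").  Merged documents left empty by pruning are dropped, so
  the fused pair set equals the EMR pair set exactly.
"""

from __future__ import annotations

import enum
import logging
import random
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

from .text import normalize
from .types import (
    AssociationTable,
    DiseaseTerm,
    EntityProfile,
    PhenotypeTerm,
    Predication,
    Source,
)

logger = logging.getLogger(__name__)

LIT_ID_PREFIX = "LIT::"


class Strategy(str, enum.Enum):
    EMR_ONLY = "emr"
    EMR_L = "emr_l"
    EMR_PL = "emr_pl"


@dataclass(frozen=True)
class FusionStrategy:
    """Which fusion case runs, plus the seed for the permutation step."""

    tag: Strategy
    seed: int = 0


def _name_index(terms: Iterable[PhenotypeTerm | DiseaseTerm]) -> dict[str, str]:
    """Normalized name/synonym -> term id. First writer wins on collisions."""
    index: dict[str, str] = {}
    for term in terms:
        term_id = getattr(term, "term_id", None) or getattr(term, "disease_id")
        for name in (term.name, *sorted(term.synonyms)):
            index.setdefault(normalize(name), term_id)
    return index


def filter_predications(
    preds: Sequence[Predication],
    pheno_vocab: dict[str, PhenotypeTerm],
    disease_vocab: dict[str, DiseaseTerm],
) -> list[tuple[str, str, str]]:
    """Keep predications linking one phenotype term to one disease term.

    Each side of a predication is looked up (by normalized name or
    synonym) in both vocabularies.  A predication survives iff exactly
    one side maps into the phenotype vocabulary and the other into the
    disease vocabulary; same-vocabulary pairs (disease-disease,
    phenotype-phenotype) and unmappable sides are dropped.  Returns
    (doc_id, phenotype_id, disease_id) triples.
    """
    pheno_index = _name_index(pheno_vocab.values())
    disease_index = _name_index(disease_vocab.values())
    kept: list[tuple[str, str, str]] = []
    dropped = 0
    for pred in preds:
        s, o = normalize(pred.subject), normalize(pred.object)
        s_ph, s_di = pheno_index.get(s), disease_index.get(s)
        o_ph, o_di = pheno_index.get(o), disease_index.get(o)
        if s_ph and o_di and not (s_di or o_ph):
            kept.append((pred.doc_id, s_ph, o_di))
        elif o_ph and s_di and not (o_di or s_ph):
            kept.append((pred.doc_id, o_ph, s_di))
        else:
            dropped += 1
    if dropped:
        logger.info("filter_predications: dropped %d of %d predications", dropped, len(preds))
    return kept


def merge_literature(triples: Sequence[tuple[str, str, str]]) -> AssociationTable:
    """Merge per-document triples into one large document per disease.

    Each publication typically asserts a single phenotype for a single
    disease, so documents sharing a disease are unioned into one profile
    with the deterministic id ``LIT::<disease_id>``.
    """
    by_disease: dict[str, set[str]] = defaultdict(set)
    for _doc, pheno, disease in triples:
        by_disease[disease].add(pheno)
    table = AssociationTable()
    for disease in sorted(by_disease):
        table.add(
            EntityProfile(
                entity_id=f"{LIT_ID_PREFIX}{disease}",
                source=Source.LIT,
                phenotypes=frozenset(by_disease[disease]),
                disease=disease,
            )
        )
    return table


def _mix(emr: AssociationTable, lit: AssociationTable, seed: int) -> AssociationTable:
    collisions = set(emr.entity_ids) & set(lit.entity_ids)
    if collisions:
        raise ValueError(f"entity id collision between EMR and literature: {sorted(collisions)[:5]}")
    profiles = list(emr) + list(lit)
    random.Random(seed).shuffle(profiles)
    return AssociationTable(profiles)


def fuse_emr_l(emr: AssociationTable, lit: AssociationTable, seed: int = 0) -> AssociationTable:
    """Raw mix: union of profiles, storage order randomly permuted."""
    return _mix(emr, lit, seed)


def fuse_emr_pl(emr: AssociationTable, lit: AssociationTable, seed: int = 0) -> AssociationTable:
    """Pruned mix: literature pairs absent from the EMR are filtered out.

    Pruning operates at (phenotype, disease) pair granularity; merged
    documents whose phenotype set empties are dropped entirely, so the
    fused pair set always equals the EMR pair set.
    """
    emr_pairs = emr.pair_set
    pruned = AssociationTable()
    for prof in lit:
        retained = frozenset(p for p in prof.phenotypes if (p, prof.disease) in emr_pairs)
        if retained:
            pruned.add(EntityProfile(prof.entity_id, prof.source, retained, prof.disease))
    return _mix(emr, pruned, seed)


def fuse(
    strategy: FusionStrategy | Strategy | str,
    emr: AssociationTable,
    lit: AssociationTable | None = None,
) -> AssociationTable:
    """Dispatch on the strategy tag ``emr | emr_l | emr_pl``."""
    if not isinstance(strategy, FusionStrategy):
        strategy = FusionStrategy(Strategy(strategy))
    if strategy.tag is Strategy.EMR_ONLY:
        return AssociationTable(list(emr))
    if lit is None:
        raise ValueError(f"strategy {strategy.tag.value} requires a literature table")
    if strategy.tag is Strategy.EMR_L:
        return fuse_emr_l(emr, lit, strategy.seed)
    return fuse_emr_pl(emr, lit, strategy.seed)


def min_support_filter(table: AssociationTable, min_patients: int) -> AssociationTable:
    """Drop diseases affecting fewer than ``min_patients`` patients.

    Support is counted over EMR-source profiles only; literature
    documents for an eliminated disease are removed as well.
    """
    if min_patients < 1:
        raise ValueError(f"min_patients must be >= 1, got {min_patients}")
    support: dict[str, int] = defaultdict(int)
    for prof in table:
        if prof.source is Source.EMR:
            support[prof.disease] += 1
    keep = {d for d, n in support.items() if n >= min_patients}
    return AssociationTable(p for p in table if p.disease in keep)
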