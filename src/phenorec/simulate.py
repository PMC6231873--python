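"""Synthetic corpus generator with planted disease-phenotype structure.

The generator emulates the statistical shape the recommender assumes:
each disease owns a characteristic phenotype *signature*; a patient
manifests a noisy draw of their disease's signature (each signature
phenotype survives with probability ``1 - phenotype_dropout``, plus a
few off-signature noise phenotypes); literature documents each assert a
single phenotype-disease predication, drawn from the true signature
with probability ``lit_fidelity`` and at random otherwise.  Vocabularies
are wired for the three matching criteria: unique names (string),
concept-key twin pairs (concept), and shared disease categories
(category), nested so that every concept match is also a category match.

Signatures are laid out over the phenotype universe by a sliding
window: consecutive diseases share ``signature_overlap`` of their
signature phenotypes (0 gives a disjoint partition), so task difficulty
is controllable.

All randomness flows through per-stage ``random.Random`` instances
seeded from ``cfg.seed``, so a fixed config reproduces byte-identical
output files on any platform.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from typing import Sequence

from .types import (
    AssociationTable,
    DiseaseTerm,
    EntityProfile,
    PhenotypeTerm,
    Predication,
    Source,
)

ASSOC_PREDICATE = "ASSOCIATED_WITH"


@dataclass(frozen=True)
class SimConfig:
    """Generator knobs; defaults describe the standard benchmark corpus."""

    n_diseases: int = 10
    signature_size: int = 8
    signature_overlap: float = 0.0
    patients_per_disease: int = 20
    phenotype_dropout: float = 0.1
    noise_phenotypes_per_patient: int = 1
    n_lit_docs: int = 200
    lit_fidelity: float = 1.0
    decoy_fraction: float = 0.0
    n_categories: int = 4
    synonym_rate: float = 0.3
    concept_twin_fraction: float = 0.2
    extra_phenotypes: int = 20
    seed: int = 11

    def __post_init__(self) -> None:
        for name in (
            "signature_overlap",
            "phenotype_dropout",
            "lit_fidelity",
            "decoy_fraction",
            "synonym_rate",
            "concept_twin_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "n_diseases",
            "signature_size",
            "patients_per_disease",
            "noise_phenotypes_per_patient",
            "n_lit_docs",
            "n_categories",
            "extra_phenotypes",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_diseases and self.signature_size < 1:
            raise ValueError("signature_size must be >= 1")

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


def _rng(cfg: SimConfig, stage: str) -> random.Random:
    # string seeds hash platform-independently in random.Random
    return random.Random(f"{cfg.seed}:{stage}")


def _phenotype_ids(cfg: SimConfig) -> list[str]:
    stride = max(1, round(cfg.signature_size * (1.0 - cfg.signature_overlap)))
    needed = stride * max(cfg.n_diseases - 1, 0) + cfg.signature_size
    return [f"HP:{i:07d}" for i in range(needed + cfg.extra_phenotypes)]


def disease_ids(cfg: SimConfig) -> list[str]:
    return [f"RD:{i:04d}" for i in range(cfg.n_diseases)]


def disease_signatures(cfg: SimConfig) -> dict[str, tuple[str, ...]]:
    """Planted signature per disease: sliding window over the universe."""
    phenos = _phenotype_ids(cfg)
    stride = max(1, round(cfg.signature_size * (1.0 - cfg.signature_overlap)))
    return {
        did: tuple(phenos[i * stride : i * stride + cfg.signature_size])
        for i, did in enumerate(disease_ids(cfg))
    }


def generate_vocabularies(
    cfg: SimConfig,
) -> tuple[dict[str, PhenotypeTerm], dict[str, DiseaseTerm]]:
    """Phenotype and disease vocabularies wired for all matching criteria.

    A ``concept_twin_fraction`` of diseases come in consecutive pairs
    sharing a concept key and a category set (so concept matches nest
    inside category matches); every other disease gets a private key.
    """
    rng = _rng(cfg, "vocab")
    pheno_vocab: dict[str, PhenotypeTerm] = {}
    for pid in _phenotype_ids(cfg):
        idx = int(pid.split(":")[1])
        synonyms = (
            frozenset({f"phenotype synonym {idx}"})
            if rng.random() < cfg.synonym_rate
            else frozenset()
        )
        pheno_vocab[pid] = PhenotypeTerm(pid, f"Phenotype {idx}", synonyms)

    n_twin_pairs = int(cfg.n_diseases * cfg.concept_twin_fraction) // 2
    twin_of: dict[int, int] = {}
    for j in range(n_twin_pairs):
        twin_of[2 * j + 1] = 2 * j

    categories = [f"Category {c}" for c in range(cfg.n_categories)]
    disease_vocab: dict[str, DiseaseTerm] = {}
    cat_by_index: dict[int, frozenset[str]] = {}
    for i, did in enumerate(disease_ids(cfg)):
        if i in twin_of:  # twin copies its partner's categories and key
            cats = cat_by_index[twin_of[i]]
            concept_key = f"CK:{twin_of[i]:04d}"
        else:
            n_cat = rng.randint(1, 2) if categories else 0
            cats = frozenset(rng.sample(categories, min(n_cat, len(categories))))
            concept_key = f"CK:{i:04d}"
        cat_by_index[i] = cats
        synonyms = (
            frozenset({f"disease synonym {i}"})
            if rng.random() < cfg.synonym_rate
            else frozenset()
        )
        disease_vocab[did] = DiseaseTerm(
            disease_id=did,
            name=f"Disease {i}",
            synonyms=synonyms,
            concept_key=concept_key,
            categories=cats,
        )
    return pheno_vocab, disease_vocab


def generate_patients(
    cfg: SimConfig,
    vocabs: tuple[dict[str, PhenotypeTerm], dict[str, DiseaseTerm]] | None = None,
) -> AssociationTable:
    """EMR-source profiles: noisy signature draws, guaranteed non-empty."""
    del vocabs  # signatures derive from cfg alone; kept for interface symmetry
    rng = _rng(cfg, "patients")
    signatures = disease_signatures(cfg)
    universe = _phenotype_ids(cfg)
    table = AssociationTable()
    counter = 0
    for did in disease_ids(cfg):
        sig = signatures[did]
        off_signature = [p for p in universe if p not in set(sig)]
        for _ in range(cfg.patients_per_disease):
            while True:
                kept = [p for p in sig if rng.random() >= cfg.phenotype_dropout]
                if kept:
                    break
            n_noise = min(cfg.noise_phenotypes_per_patient, len(off_signature))
            noise = rng.sample(off_signature, n_noise)
            table.add(
                EntityProfile(
                    entity_id=f"PAT{counter:05d}",
                    source=Source.EMR,
                    phenotypes=frozenset(kept) | frozenset(noise),
                    disease=did,
                )
            )
            counter += 1
    return table


def generate_literature(
    cfg: SimConfig,
    vocabs: tuple[dict[str, PhenotypeTerm], dict[str, DiseaseTerm]],
) -> list[Predication]:
    """Predication triples, one per document, with optional decoys.

    A decoy is a same-vocabulary predication (phenotype-phenotype or
    disease-disease) that the ingest filter must reject.
    """
    pheno_vocab, disease_vocab = vocabs
    rng = _rng(cfg, "literature")
    signatures = disease_signatures(cfg)
    dids = disease_ids(cfg)
    pids = list(pheno_vocab)
    preds: list[Predication] = []
    for d in range(cfg.n_lit_docs):
        doc_id = f"PMID{d:07d}"
        if rng.random() < cfg.decoy_fraction:
            if rng.random() < 0.5 and len(pids) >= 2:
                a, b = rng.sample(pids, 2)
                preds.append(
                    Predication(doc_id, pheno_vocab[a].name, ASSOC_PREDICATE, pheno_vocab[b].name)
                )
            elif len(dids) >= 2:
                a, b = rng.sample(dids, 2)
                preds.append(
                    Predication(doc_id, disease_vocab[a].name, ASSOC_PREDICATE, disease_vocab[b].name)
                )
            continue
        did = rng.choice(dids)
        if rng.random() < cfg.lit_fidelity:
            pid = rng.choice(list(signatures[did]))
        else:
            pid = rng.choice(pids)
        preds.append(
            Predication(doc_id, pheno_vocab[pid].name, ASSOC_PREDICATE, disease_vocab[did].name)
        )
    return preds


@dataclass
class SyntheticCorpus:
    """Everything one simulation run produces."""

    config: SimConfig
    phenotype_vocab: dict[str, PhenotypeTerm]
    disease_vocab: dict[str, DiseaseTerm]
    signatures: dict[str, tuple[str, ...]] = field(default_factory=dict)
    emr: AssociationTable = field(default_factory=AssociationTable)
    predications: list[Predication] = field(default_factory=list)


def simulate_corpus(cfg: SimConfig) -> SyntheticCorpus:
    """Run all three generators under one config."""
    vocabs = generate_vocabularies(cfg)
    return SyntheticCorpus(
        config=cfg,
        phenotype_vocab=vocabs[0],
        disease_vocab=vocabs[1],
        signatures=disease_signatures(cfg),
        emr=generate_patients(cfg, vocabs),
        predications=generate_literature(cfg, vocabs),
    )


def split_table(
    table: AssociationTable, test_fraction: float, seed: int
) -> tuple[AssociationTable, AssociationTable]:
    """Disease-stratified train/test split of an association table."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = random.Random(f"{seed}:split")
    by_disease: dict[str, list[str]] = {}
    for prof in table:
        by_disease.setdefault(prof.disease, []).append(prof.entity_id)
    test_ids: set[str] = set()
    for did in sorted(by_disease):
        ids = sorted(by_disease[did])
        rng.shuffle(ids)
        n_test = int(round(len(ids) * test_fraction))
        test_ids.update(ids[:n_test])
    train = AssociationTable(p for p in table if p.entity_id not in test_ids)
    test = AssociationTable(p for p in table if p.entity_id in test_ids)
    return train, test


def holdout_queries(test: AssociationTable) -> list[tuple[str, frozenset, str]]:
    """(query_id, phenotypes, true disease) triples from a test table."""
    return [(p.entity_id, p.phenotypes, p.disease) for p in test]
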