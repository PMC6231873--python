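"""Readers and writers for the on-disk formats.

All files are UTF-8, tab-separated with a header row.  Set-valued cells
(phenotypes, synonyms, categories) are ``|``-separated.  JSONL with the
same field names is accepted as an alternate profile format (one object
per line).  Writers emit deterministic bytes: profile storage order and
sorted set elements.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable

from .types import (
    AssociationTable,
    DiseaseTerm,
    EntityProfile,
    PhenotypeTerm,
    Predication,
    Source,
)

PROFILE_COLUMNS = ["entity_id", "source", "disease_id", "phenotypes"]
VOCAB_COLUMNS = ["term_id", "name", "synonyms", "concept_key", "categories"]
PREDICATION_COLUMNS = ["doc_id", "subject", "predicate", "object"]


class ParseError(ValueError):
    """A malformed record, annotated with file and line number."""


def _split_set(cell: str) -> frozenset[str]:
    return frozenset(x for x in cell.split("|") if x)


def _join_set(items: Iterable[str]) -> str:
    return "|".join(sorted(items))


def read_profiles(path: str | Path, source: Source | str | None = None) -> AssociationTable:
    """Read an association table from TSV (or JSONL, by ``.jsonl`` suffix).

    ``source`` overrides the per-row source tag when given.  Duplicate
    phenotype mentions within an entity collapse to the set; a duplicate
    entity id with a conflicting disease label is an error.
    """
    path = Path(path)
    if path.suffix == ".jsonl":
        return _read_profiles_jsonl(path, source)
    table = AssociationTable()
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:  # empty file
            return table
        missing = set(PROFILE_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise ParseError(f"{path}: missing columns {sorted(missing)}")
        for row in reader:
            lineno = reader.line_num
            try:
                profile = EntityProfile(
                    entity_id=row["entity_id"],
                    source=Source(source) if source is not None else Source(row["source"]),
                    phenotypes=_split_set(row["phenotypes"]),
                    disease=row["disease_id"],
                )
                table.add(profile)
            except (ValueError, KeyError, TypeError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return table


def _read_profiles_jsonl(path: Path, source: Source | str | None) -> AssociationTable:
    table = AssociationTable()
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
                profile = EntityProfile(
                    entity_id=rec["entity_id"],
                    source=Source(source) if source is not None else Source(rec["source"]),
                    phenotypes=frozenset(rec["phenotypes"]),
                    disease=rec["disease_id"],
                )
                table.add(profile)
            except (ValueError, KeyError, TypeError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return table


def write_profiles(table: AssociationTable, path: str | Path) -> None:
    """Write a table as TSV; ``read_profiles(write_profiles(t)) == t``."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(PROFILE_COLUMNS)
        for prof in table:
            writer.writerow(
                [prof.entity_id, prof.source.value, prof.disease, _join_set(prof.phenotypes)]
            )


def read_phenotype_vocab(path: str | Path) -> dict[str, PhenotypeTerm]:
    """Read a phenotype vocabulary TSV keyed by term id."""
    vocab: dict[str, PhenotypeTerm] = {}
    for row, lineno, path_ in _iter_vocab_rows(path):
        term = PhenotypeTerm(
            term_id=row["term_id"],
            name=row["name"],
            synonyms=_split_set(row.get("synonyms", "")),
        )
        if term.term_id in vocab:
            raise ParseError(f"{path_}:{lineno}: duplicate term_id {term.term_id!r}")
        vocab[term.term_id] = term
    return vocab


def read_disease_vocab(path: str | Path) -> dict[str, DiseaseTerm]:
    """Read a disease vocabulary TSV keyed by disease id."""
    vocab: dict[str, DiseaseTerm] = {}
    for row, lineno, path_ in _iter_vocab_rows(path):
        term = DiseaseTerm(
            disease_id=row["term_id"],
            name=row["name"],
            synonyms=_split_set(row.get("synonyms", "")),
            concept_key=row.get("concept_key") or None,
            categories=_split_set(row.get("categories", "")),
        )
        if term.disease_id in vocab:
            raise ParseError(f"{path_}:{lineno}: duplicate term_id {term.disease_id!r}")
        vocab[term.disease_id] = term
    return vocab


def _iter_vocab_rows(path: str | Path):
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return
        if "term_id" not in reader.fieldnames or "name" not in reader.fieldnames:
            raise ParseError(f"{path}: vocabulary needs term_id and name columns")
        for row in reader:
            try:
                yield row, reader.line_num, path
            except ValueError as exc:
                raise ParseError(f"{path}:{reader.line_num}: {exc}") from exc


def write_phenotype_vocab(vocab: dict[str, PhenotypeTerm], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(VOCAB_COLUMNS)
        for term in vocab.values():
            writer.writerow([term.term_id, term.name, _join_set(term.synonyms), "", ""])


def write_disease_vocab(vocab: dict[str, DiseaseTerm], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(VOCAB_COLUMNS)
        for term in vocab.values():
            writer.writerow(
                [
                    term.disease_id,
                    term.name,
                    _join_set(term.synonyms),
                    term.concept_key or "",
                    _join_set(term.categories),
                ]
            )


def read_predications(path: str | Path) -> list[Predication]:
    preds: list[Predication] = []
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return preds
        missing = set(PREDICATION_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise ParseError(f"{path}: missing columns {sorted(missing)}")
        for row in reader:
            try:
                preds.append(
                    Predication(row["doc_id"], row["subject"], row["predicate"], row["object"])
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{reader.line_num}: {exc}") from exc
    return preds


def write_predications(preds: Iterable[Predication], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(PREDICATION_COLUMNS)
        for p in preds:
            writer.writerow([p.doc_id, p.subject, p.predicate, p.object])
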