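import random

import pytest

from phenorec.types import AssociationTable, EntityProfile, Source


def make_table(rows, source=Source.EMR):
    """rows: iterable of (entity_id, disease, phenotypes)."""
    return AssociationTable(
        EntityProfile(eid, source, frozenset(phenos), disease)
        for eid, disease, phenos in rows
    )


def random_table(rng: random.Random, n_entities=8, n_phenos=12, n_diseases=4, prefix="E"):
    phenos = [f"h{i}" for i in range(n_phenos)]
    rows = []
    for i in range(n_entities):
        size = rng.randint(1, n_phenos)
        rows.append(
            (
                f"{prefix}{i:03d}",
                f"D{rng.randrange(n_diseases)}",
                rng.sample(phenos, size),
            )
        )
    return make_table(rows)


@pytest.fixture
def toy_table():
    return make_table(
        [
            ("patA", "D1", {"h1", "h2"}),
            ("patB", "D2", {"h2"}),
        ]
    )


@pytest.fixture
def rng():
    return random.Random(20260930)
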