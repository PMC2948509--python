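from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from its2eval import (
    SequenceRecord,
    SimulationParams,
    build_profile,
    simulate_dataset,
)


def make_taxonomy_table(rows):
    """rows: iterable of (id, group, family, genus, species)."""
    return pd.DataFrame(rows, columns=["id", "group", "family", "genus", "species"])


def random_dna(length: int, rng: np.random.Generator, gc: float = 0.5) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))


@pytest.fixture(scope="session")
def small_dataset():
    """A clean 2-family / 6-genus / 12-species dataset shared across tests."""
    params = SimulationParams(seed=11, n_families=2, genera_per_family=3,
                              species_per_genus=2, seqs_per_species=3)
    return simulate_dataset(params)


@pytest.fixture(scope="session")
def anchor_profiles(small_dataset):
    return (build_profile(small_dataset.alignment_5_8S),
            build_profile(small_dataset.alignment_28S))


@pytest.fixture
def curation_fixture():
    """Six records exercising one rule each: two clean congeners, a short
    record, an N-rich record, an unnamed species, and a monotypic genus."""
    rng = np.random.default_rng(5)
    clean = random_dna(200, rng)
    records = [
        SequenceRecord("r1", clean),
        SequenceRecord("r2", random_dna(200, rng)),
        SequenceRecord("r3", random_dna(90, rng)),
        SequenceRecord("r4", "A" + "NNN" + random_dna(196, rng)),
        SequenceRecord("r5", random_dna(200, rng)),
        SequenceRecord("r6", random_dna(200, rng)),
    ]
    taxonomy = make_taxonomy_table([
        ("r1", "plants", "Cyperaceae", "Carex", "Carex alpha"),
        ("r2", "plants", "Cyperaceae", "Carex", "Carex beta"),
        ("r3", "plants", "Cyperaceae", "Carex", "Carex gamma"),
        ("r4", "plants", "Cyperaceae", "Carex", "Carex delta"),
        ("r5", "plants", "Cyperaceae", "Carex", "Carex sp."),
        ("r6", "plants", "Rosaceae", "Rosa", "Rosa sola"),
    ])
    return records, taxonomy
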