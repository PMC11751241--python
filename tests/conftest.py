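import numpy as np
import pytest

from scatdiet.records import (
    AvailabilityTable,
    PreySpecies,
    ScatDataset,
    ScatRecord,
    study_prey_attributes,
)


@pytest.fixture(scope="session")
def study_registry():
    return study_prey_attributes()


@pytest.fixture
def toy_dataset():
    """Two predators, three prey, known counts."""
    registry = [
        PreySpecies("blue_sheep", "wild"),
        PreySpecies("domestic_goat", "domestic"),
        PreySpecies("yak", "domestic"),
    ]
    records = [
        ScatRecord("s1", "snow_leopard", frozenset({"blue_sheep", "yak"})),
        ScatRecord("s2", "snow_leopard", frozenset({"blue_sheep"})),
        ScatRecord("s3", "wolf", frozenset({"domestic_goat"})),
        ScatRecord("s4", "wolf", frozenset({"yak", "domestic_goat"})),
    ]
    return ScatDataset(records, registry)


def make_single_prey_dataset(predator, prey_names, counts):
    """n_i scats each containing exactly {prey_i} — fully deterministic."""
    records = []
    i = 0
    for prey, n in zip(prey_names, counts):
        for _ in range(n):
            i += 1
            records.append(ScatRecord(f"{predator}_{i}", predator, frozenset({prey})))
    return ScatDataset(records)


@pytest.fixture
def uniform_availability():
    return AvailabilityTable({f"p{i}": 100 for i in range(4)})


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
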