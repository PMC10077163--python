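import numpy as np
import pytest

from planktraits import (
    AbundanceTable,
    Station,
    TraitAssignment,
    encode_traits,
    gower,
    table3_fixture,
    ward_cluster,
)


@pytest.fixture(scope="session")
def fixture_matrix():
    """The 98-species trait matrix with its planted group assignment."""
    return table3_fixture()


@pytest.fixture(scope="session")
def fixture_dendrogram(fixture_matrix):
    matrix, _planted = fixture_matrix
    d = gower(matrix, "categorical_traits")
    return d, ward_cluster(d)


@pytest.fixture
def eight_profile_matrix():
    """Eight distinct trait profiles, each repeated; zero within-group spread."""
    profiles = [
        ("small", "current", "omnivore_herbivore", "free_spawner"),
        ("giant", "active_ambush", "carnivore", "free_spawner"),
        ("large", "passive_ambush", "carnivore", "free_spawner"),
        ("medium", "active_ambush", "omnivore_carnivore", "egg_brooding"),
        ("small", "current", "omnivore_detritivore", "egg_brooding"),
        ("medium", "active_ambush", "omnivore_herbivore", "parthenogenesis"),
        ("large", "current", "omnivore_herbivore", "alternation_of_generations"),
        ("giant", "mixed", "omnivore", "free_spawner"),
    ]
    sizes = (5, 4, 4, 3, 3, 2, 2, 2)
    assignments, planted = [], []
    for g, ((body, feed, troph, rep), size) in enumerate(zip(profiles, sizes), start=1):
        for i in range(size):
            assignments.append(
                TraitAssignment(f"P{g}_{i}", body, feed, troph, rep)
            )
            planted.append(g)
    return encode_traits(assignments), np.array(planted)


def make_abundance(values, seasons=None, species=None):
    """Small helper to build an AbundanceTable from a matrix."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    seasons = seasons or ["spring"] * n
    species = species or [f"sp{j + 1}" for j in range(m)]
    stations = [
        Station(id=f"st{i + 1}", season=seasons[i], latitude=34.0, longitude=122.0, tow_depth=30.0)
        for i in range(n)
    ]
    return AbundanceTable(stations=stations, species=species, values=values)


@pytest.fixture
def abundance_factory():
    return make_abundance
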