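import numpy as np
import pytest

from trophonet.species_table import SpeciesRecord, SpeciesTable


def record(
    taxon_id,
    mass=None,
    size=None,
    diet=(),
    habitat=("terrestrial",),
    producer=False,
    **taxonomy,
):
    return SpeciesRecord(
        taxon_id=taxon_id,
        name=taxon_id.replace("_", " ").title(),
        taxonomy={k: v for k, v in taxonomy.items() if v},
        body_mass=mass,
        body_size=size,
        diet=set(diet),
        habitat=set(habitat),
        is_producer=producer,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_table():
    """Plant -> herbivorous insect -> insectivore -> carnivore."""
    return SpeciesTable(
        "toy",
        [
            record("reed", mass=50.0, producer=True, phylum="Tracheophyta", **{"class": "Magnoliopsida"}),
            record("grasshopper", mass=0.5, diet=("herbivore",), phylum="Arthropoda", **{"class": "Insecta"}),
            record("shrew", mass=10.0, diet=("insectivore",), phylum="Chordata", **{"class": "Mammalia"}),
            record("fox", mass=5000.0, diet=("carnivore",), phylum="Chordata", **{"class": "Mammalia"}),
        ],
    )


@pytest.fixture
def wetland_table():
    from trophonet.synthetic import CommunityConfig, generate_community

    return generate_community(CommunityConfig(n=60, seed=42))
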