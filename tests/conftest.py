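import pytest

from geomine import datasets
from geomine.sequence_mining import identity_matrix
from geomine.synthetic_data import FamilySimSpec, simulate_family


@pytest.fixture(scope="session")
def small_family():
    """A 16-leaf simulated family with a planted functional clade."""
    spec = FamilySimSpec(
        n_sequences=16, root_length=120, functional_clade_fraction=0.25,
        eukaryote_fraction=0.0, seed=11,
    )
    return simulate_family(spec)


@pytest.fixture(scope="session")
def small_family_matrix(small_family):
    records, _ = small_family
    return identity_matrix(records)


@pytest.fixture(scope="session")
def reference_efficiencies():
    """Published catalytic efficiencies keyed [enzyme][substrate]."""
    return datasets.efficiency_map()
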