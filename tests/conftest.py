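import numpy as np
import pytest
from hypothesis import settings

from verifid import simulate as sim
from verifid.refdb_io import (
    BarcodePrimers,
    PrimerPanel,
    Taxonomy,
    TaxonomyNode,
    default_panel,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def panel() -> PrimerPanel:
    return default_panel()


@pytest.fixture(scope="session")
def refset() -> sim.ReferenceSet:
    """Five synthetic species, no numts, seed fixed."""
    return sim.generate_reference_set(sim.SimulationConfig(n_species=5, seed=7))


@pytest.fixture(scope="session")
def numt_refset() -> sim.ReferenceSet:
    """Five synthetic species, every one carrying a numt at 8% divergence."""
    return sim.generate_reference_set(
        sim.SimulationConfig(n_species=5, numt_rate=1.0, numt_divergence=0.08, seed=11)
    )


@pytest.fixture(scope="session")
def toy_taxonomy() -> Taxonomy:
    """Two genera in one tribe, two species per genus, plus an outgroup genus."""
    return Taxonomy(
        [
            TaxonomyNode(1, 1, "higher", "Root"),
            TaxonomyNode(100, 1, "family", "Bovidae"),
            TaxonomyNode(500, 100, "tribe", "Caprini"),
            TaxonomyNode(1000, 500, "genus", "Capra"),
            TaxonomyNode(1001, 500, "genus", "Ovis"),
            TaxonomyNode(1002, 100, "genus", "Bos"),
            TaxonomyNode(10000, 1000, "species", "Capra hircus"),
            TaxonomyNode(10001, 1000, "species", "Capra ibex"),
            TaxonomyNode(10002, 1001, "species", "Ovis aries"),
            TaxonomyNode(10003, 1002, "species", "Bos taurus"),
        ]
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
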