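import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mirortho.model_training import create_models
from mirortho.synthetic_data import SimulationConfig, evolve_clade

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_clade():
    """An 8-species clade, mild divergence, a few losses."""
    config = SimulationConfig(
        seed=5,
        n_species=8,
        n_genes=200,
        n_families=8,
        substitution_rate=0.01,
        loss_probability=0.05,
        n_core_species=3,
    )
    return evolve_clade(config)


@pytest.fixture(scope="session")
def small_models(small_clade):
    b = small_clade
    models, report, alignments = create_models(
        b.genomes[b.reference_species],
        b.annotations[b.reference_species],
        b.mirnas,
        [b.core_bundle(s) for s in b.core_species],
    )
    return models, report, alignments


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
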