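import numpy as np
import pytest

from coexmap.pipeline import tissue_preferential_profile
from coexmap.synthdata import (
    PlantedModuleSpec,
    TissueDesign,
    generate_tissue_experiment,
)


@pytest.fixture(scope="session")
def design():
    return TissueDesign()


@pytest.fixture(scope="session")
def two_module_experiment(design):
    """Two planted anticorrelated module pairs + invariants, moderate noise."""
    mods = [
        PlantedModuleSpec("P1", 50, 50, tissue_preferential_profile(0), 2.0),
        PlantedModuleSpec("P2", 50, 50, tissue_preferential_profile(1), 2.0),
    ]
    return generate_tissue_experiment(
        design, mods, n_invariant=100, n_violators=0, noise_sd=0.2, seed=2
    )


@pytest.fixture(scope="session")
def noiseless_experiment(design):
    mods = [PlantedModuleSpec("P1", 5, 5, tissue_preferential_profile(2), 2.0)]
    return generate_tissue_experiment(
        design,
        mods,
        n_invariant=5,
        n_violators=0,
        noise_sd=0.0,
        dye_effect_sd=0.0,
        tree_effect_sd=0.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
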