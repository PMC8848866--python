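import numpy as np
import pytest

from telandscape.simulate import SimulationConfig, generate_library, plant_insertions


@pytest.fixture(scope="session")
def small_bundle():
    """A small sequence-bearing synthetic genome shared across tests."""
    cfg = SimulationConfig(
        seed=101,
        chrom_lengths=(600_000, 600_000),
        hotspot_windows=(),
        n_genes=10,
        baseline_density_kb=25.0,
        density_sd_kb=5.0,
    )
    library = generate_library(cfg)
    genome, annots, truth = plant_insertions(cfg, library)
    return cfg, library, genome, annots, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
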