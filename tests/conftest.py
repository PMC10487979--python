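import pytest

from intronarch.datasets import seed_plant_example
from intronarch.simulate import SimConfig, simulate_family


@pytest.fixture(scope="session")
def seed_plant_case():
    """Seed-plant species tree and intron presence/absence matrix."""
    return seed_plant_example()


@pytest.fixture(scope="session")
def small_family():
    """A small simulated family with gains, losses and TEs (fixed seed)."""
    cfg = SimConfig(seed=11, n_leaves=8, te_rate=0.5)
    models, truth = simulate_family(cfg)
    return cfg, models, truth
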