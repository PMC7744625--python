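import numpy as np
import pytest

from wfadmix.model import SimulationConfig, SizeTrajectory, preset_hi
from wfadmix.engine import simulate


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_hi_population():
    """A small hybrid-isolation run shared by read-only tests.

    HI (0.25, 0.75), N=300, T=30, one 1-Morgan chromosome.
    """
    cfg = SimulationConfig(
        matrix=preset_hi([0.25, 0.75], 30),
        sizes=SizeTrajectory.constant(300, 30),
        chrom_lengths=(1.0,),
        sample_size=50,
        seed=7,
    )
    return cfg, simulate(cfg)
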