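import numpy as np
import pytest

from deconvcall import SimulationConfig, simulate_reads
from deconvcall.simulate import dye_crosstalk

#: Cross-talk and phasing used throughout as the "biased instrument".
TRUE_CROSSTALK = dye_crosstalk(0.3, 0.25)
TRUE_PHASING = np.array([0.05, 0.9, 0.05])


@pytest.fixture(scope="session")
def biased_noisefree():
    """500 reads x 50 cycles through the biased instrument, no noise."""
    cfg = SimulationConfig(
        n_reads=500,
        n_cycles=50,
        crosstalk_true=TRUE_CROSSTALK,
        phasing_true=TRUE_PHASING,
        seed=11,
    )
    return (cfg, *simulate_reads(cfg))


@pytest.fixture(scope="session")
def ideal_sim():
    """Ideal instrument: intensities are exactly the one-hot truth."""
    cfg = SimulationConfig(n_reads=200, n_cycles=30, seed=5)
    return (cfg, *simulate_reads(cfg))
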