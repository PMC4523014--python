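import numpy as np
import pytest

from methbench.simulate import SimulationConfig, synthetic_reference


@pytest.fixture(scope="session")
def reference():
    """Default synthetic amplicon reference: 205 nt, 19 CpG sites."""
    return synthetic_reference()


@pytest.fixture(scope="session")
def clean_config():
    """Idealised chemistry: no conversion failure, sequencing error,
    bias or chimeras; measurement-sampling noise only."""
    return SimulationConfig().unbiased()


@pytest.fixture()
def rng():
    return np.random.default_rng(20140)
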