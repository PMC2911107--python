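import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from texome.simulate import SimConfig, generate


@pytest.fixture(scope="session")
def sim_default():
    """A mid-sized synthetic genome exercising every planted feature."""
    config = SimConfig(
        seed=7,
        n_genes=30,
        p_exonization=0.2,
        est_depth=8,
        p_first_last_te=0.3,
        n_internal_cds_te=5,
        n_internal_cds_te_disqualified=5,
    )
    return generate(config)


@pytest.fixture(scope="session")
def sim_small():
    """A small genome for round-trip and file-format tests."""
    return generate(SimConfig(seed=3, n_genes=8, p_exonization=0.2, est_depth=4))
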