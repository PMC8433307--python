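import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from decatpipe.simulate import SimParams, simulate_pool


@pytest.fixture(scope="session")
def clean_pool():
    """Error-free pool: 9 samples x 5 reads, both orientations."""
    return simulate_pool(SimParams(
        n_samples=9, reads_per_sample=5,
        sub_rate=0.0, ins_rate=0.0, del_rate=0.0, seed=1,
    ))


@pytest.fixture(scope="session")
def noisy_pool():
    """Default ~1% error pool with truncation artefacts: 9 samples x 20 reads."""
    return simulate_pool(SimParams(
        n_samples=9, reads_per_sample=20, truncation_fraction=0.1, seed=7,
    ))
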