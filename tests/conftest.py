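import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from fermentome.synthetic import NetworkSpec, SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240501)


@pytest.fixture
def small_sim():
    """A light study: enough points to fit, enough replicates for forests."""
    return SimConfig(
        seed=7,
        n_timepoints=20,
        n_replicates=6,
        network_spec=NetworkSpec(n_organisms=8, planted_community_size=3),
    )
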