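import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from crisprhgt.simulate import SimulationConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_experiment():
    """A modest error-free recording: 1000 reads, 20% expanded, one donor."""
    cfg = SimulationConfig(seed=11, n_reads=1000, expansion_rate=0.2,
                           exogenous_fraction=0.5, pam_bias=0.5, error_rate=0.0,
                           donor_lengths={"donor_1": 5000})
    refs, events, reads, manifest = simulate_experiment(cfg)
    return cfg, refs, events, reads, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])
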