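import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from hairpincall.config import load_config
from hairpincall.fold import get_backend


@pytest.fixture(scope="session")
def maxpair():
    return get_backend("maxpair")


@pytest.fixture(scope="session")
def vienna():
    return get_backend("vienna")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def plants_config():
    return load_config(preset="plants")


@pytest.fixture
def algae_config():
    return load_config(preset="algae")


@pytest.fixture(scope="session")
def tiny_sim(tmp_path_factory):
    """Small ground-truthed dataset for pipeline-level tests."""
    from hairpincall.synthetic import simulate

    out = tmp_path_factory.mktemp("tiny_sim")
    truth = simulate(out, seed=7, genome_length=24_000, n_precursors=6,
                     arm_length=40, loop_length=6, n_defects=0,
                     mature_depth=30, star_depth=5, background_reads=100,
                     jitter=0)
    return out, truth


# fast, thermodynamics-free settings for orchestration-level tests
TINY_OVERRIDES = {
    "fold_backend": "maxpair",
    "cluster_flank_size": 80,
    "window_step": 10,
    "permutation_count": 20,
    "max_hairpin_count": 8,
}
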