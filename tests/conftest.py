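import numpy as np
import pandas as pd
import pytest

from chromcascade import synthetic as synth
from chromcascade.core import CountMatrix


@pytest.fixture(scope="session")
def small_config():
    """A fast, reduced-size study configuration shared across unit tests."""
    return synth.SimulationConfig(
        n_tss=400, n_remote_sites=200, n_invariant=80,
        n_coverage_regions=30, n_hic_links=20, seed=11,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    counts, truth = synth.simulate_counts(small_config)
    return counts, truth


@pytest.fixture()
def toy_count_matrix():
    counts = pd.DataFrame(
        {"s1": [10, 20, 30], "s2": [12, 18, 33]},
        index=["r1", "r2", "r3"],
    )
    samples = pd.DataFrame(
        {
            "mark": ["m", "m"],
            "background": ["WT", "WT"],
            "condition": ["FCS", "TPA"],
            "time": [0, 30],
            "replicate": [1, 1],
        },
        index=["s1", "s2"],
    )
    return CountMatrix(counts, samples)


def make_rng(seed=0):
    return np.random.default_rng(seed)
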