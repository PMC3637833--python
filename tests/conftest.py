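import numpy as np
import pytest

from posthocalign import SimConfig, generate_library, generate_replicates, merge_peaks
from posthocalign.datasets import pairwise_demo, pyridine_standards


@pytest.fixture
def pyridine():
    return pyridine_standards()


@pytest.fixture
def demo():
    return pairwise_demo()


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def make_merged_replicates(**overrides):
    """Generate replicates under the given config and area-merge each."""
    cfg = SimConfig(**overrides)
    library = generate_library(cfg)
    replicates, truth = generate_replicates(library, cfg)
    merged = [merge_peaks(r, "area") for r in replicates]
    return merged, truth, library
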