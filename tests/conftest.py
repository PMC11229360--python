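import numpy as np
import pytest

from crispr3census.pipeline import PipelineConfig, build_profile_library
from crispr3census.synthetic_data import SynthConfig, generate, make_seed_alignments


@pytest.fixture(scope="session")
def small_dataset():
    """Noiseless 30-genome synthetic input with ground truth."""
    return generate(SynthConfig(n_genomes=30, seed=7, noise=0.0))


@pytest.fixture(scope="session")
def small_profiles(small_dataset):
    """Calibrated profile library built from the small dataset's seeds."""
    seeds = make_seed_alignments(small_dataset.config)
    return build_profile_library(seeds, PipelineConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(20241)
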