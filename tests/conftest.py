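import numpy as np
import pytest

import tadbound as tb


@pytest.fixture(scope="session")
def small_fixture() -> tb.Fixture:
    """Default-condition synthetic dataset shared by read-only tests."""
    return tb.generate_fixture(tb.FixtureConfig(seed=11))


@pytest.fixture(scope="session")
def strong_matrix(small_fixture) -> tb.FeatureMatrix:
    """Signal+k-mer design matrix with a clearly separable effect."""
    fx = tb.generate_fixture(
        tb.FixtureConfig(
            n_boundaries=40, n_chromosomes=2, chrom_length=1_000_000, seed=7
        )
    )
    return tb.extract_features(
        fx.tracks, fx.boundaries, fx.contacts, fx.config.bin_config,
        genome=fx.genome, kmer=tb.KmerSpec(3),
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
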