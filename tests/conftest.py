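"""Shared fixtures: synthetic tiles and cohorts generated at test time."""

import numpy as np
import pytest

from vasculomorph import stains, synthetic


@pytest.fixture(scope="session")
def tile():
    """Default branched vascular tile with rendering noise."""
    return synthetic.generate_vessel_network(seed=11)


@pytest.fixture(scope="session")
def noise_free_tile():
    """Noise-free tile: exact Beer-Lambert rendering for round trips."""
    return synthetic.generate_vessel_network(seed=2, noise_sd=0.0)


@pytest.fixture(scope="session")
def tile_channels(tile):
    return stains.unmix_stains(tile.rgb_he)


@pytest.fixture(scope="session")
def hmm_model(tile):
    samples = synthetic.sample_state_pixels(tile, n_per_state=200, seed=5)
    return stains.train_color_hmm(samples)


@pytest.fixture(scope="session")
def cohort():
    """Default planted cohort: n=64, HR=2.4, 14 signal genes among 2000."""
    return synthetic.simulate_cohort(synthetic.SyntheticCohortSpec(seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
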