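import numpy as np
import pytest

from forestdrivers import synthetic


@pytest.fixture(scope="session")
def two_region_small():
    """100-cell two-region dataset: west driven by x1, east by x2."""
    spec = synthetic.two_region_spec(n_cells=100, seed=3)
    dataset, truth = synthetic.generate_spatial_dataset(spec)
    return dataset, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
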