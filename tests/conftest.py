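import numpy as np
import pytest

from pseudode import simulate_lineage


@pytest.fixture(scope="session")
def small_lineage():
    """200 cells x 100 genes, 20% DE, high dispersion, single lineage."""
    return simulate_lineage(200, 100, 0.2, "high", "single", seed=11)


@pytest.fixture(scope="session")
def null_lineage():
    """150 cells x 60 genes with no DE genes at all."""
    return simulate_lineage(150, 60, 0.0, "medium", "single", seed=12)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
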