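import numpy as np
import pytest

import exocollapse as xc


@pytest.fixture(scope="session")
def small_cohort():
    """A modest seeded cohort reused by read-only tests."""
    cfg = xc.SimulationConfig(n_cases=120, n_controls=600, n_genes=30,
                              variants_per_gene=25, seed=42)
    return xc.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def registry():
    return {m.name: m for m in xc.builtin_registry()}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
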