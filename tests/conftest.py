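import numpy as np
import pytest

from bayesmr import (
    InstrumentLayout,
    SimulationConfig,
    StructuralParams,
    simulate_combined,
)


@pytest.fixture(scope="session")
def small_layout() -> InstrumentLayout:
    return InstrumentLayout(L=3, K=3, M=2)


@pytest.fixture(scope="session")
def small_params(small_layout) -> StructuralParams:
    return StructuralParams.homogeneous(small_layout, alpha=0.3, beta=0.3, delta=1.0, sigma=0.1)


@pytest.fixture(scope="session")
def default_combined():
    """One combined replicate at the standard evaluation conditions."""
    cfg = SimulationConfig(
        n_total=400, missing_rate=0.5, alpha_level=0.3, beta_level=0.3, seed=42
    )
    combined, params = simulate_combined(cfg, 0, keep_hidden=True)
    return combined, params


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2718)
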