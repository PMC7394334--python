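import numpy as np
import pytest

from tdfe.io import ExpressionTensor
from tdfe.simulate import simulate_library, simulate_tensor


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noise_tensor(rng):
    """Pure-noise tensor (no baseline, no planted signal)."""
    x = rng.normal(size=(6, 40, 120))
    return ExpressionTensor(
        x,
        np.geomspace(0.1, 10, 6),
        [f"C{i:03d}" for i in range(40)],
        [f"G{i:03d}" for i in range(120)],
    )


@pytest.fixture(scope="session")
def planted():
    """Small planted screen reused across tests (strong, fast)."""
    tensor, truth = simulate_tensor(
        D=6, J=40, L=120, n_active_compounds=6, n_active_genes=20,
        beta=4.0, sigma=1.0, seed=42,
    )
    return tensor, truth


@pytest.fixture(scope="session")
def planted_library(planted):
    _, truth = planted
    return simulate_library(
        truth, n_sets=60, set_size=20, n_signal_sets=4, overlap_fraction=0.8, seed=43
    )
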