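import numpy as np
import pandas as pd
import pytest

from genegini import ExpressionMatrix, SampleKind, SimulationConfig, simulate_matrix


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    """4 genes x 3 samples with one transporter-like and one all-zero gene."""
    data = pd.DataFrame(
        {
            "kidney": [100.0, 5.0, 0.0, 0.0],
            "liver": [110.0, 0.0, 500.0, 0.0],
            "testis": [90.0, 4.0, 1.0, 0.0],
        },
        index=["PCBP1", "GENEA", "SLC22A4", "ZEROG"],
    )
    return ExpressionMatrix(data, sample_kind=SampleKind.TISSUE)


@pytest.fixture(scope="session")
def default_simulation():
    """Default-config simulation shared across tests (read-only)."""
    return simulate_matrix(SimulationConfig(seed=2026))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
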