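import numpy as np
import pytest

from synchrofluor import (
    Sample,
    default_fluorophores,
    default_matrix,
    simulate_eem,
    synchronous_scan,
)


@pytest.fixture(scope="session")
def models():
    return default_fluorophores()


@pytest.fixture(scope="session")
def noiseless_matrix():
    return default_matrix("solvent").noiseless


@pytest.fixture(scope="session")
def noiseless_eem(noiseless_matrix):
    """Factory: noiseless EEM on the default grids for given concentrations."""

    def make(**concentrations):
        return simulate_eem(
            Sample({k: float(v) for k, v in concentrations.items()}),
            matrix_model=noiseless_matrix,
        )

    return make


@pytest.fixture(scope="session")
def pure_sync(noiseless_eem):
    """Noiseless single-analyte synchronous traces at the working offset."""
    return {
        "FEX": synchronous_scan(noiseless_eem(FEX=1000.0), 25.0),
        "PSE": synchronous_scan(noiseless_eem(PSE=800.0), 25.0),
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
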