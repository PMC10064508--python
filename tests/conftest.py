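import pytest
from hypothesis import HealthCheck, settings

from qhtsplot import GeneratorSpec, generate_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """Two-readout, 20-compound synthetic campaign with fixed seed."""
    ds, ledger = generate_dataset(GeneratorSpec(n_compounds=20, seed=11))
    return ds, ledger


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Single-readout campaign with zero noise: responses sit on the curve."""
    ds, ledger = generate_dataset(
        GeneratorSpec(n_compounds=30, noise_sd=0.0, readouts=("FLuc",), seed=5)
    )
    return ds, ledger
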