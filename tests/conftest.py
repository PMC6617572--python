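import numpy as np
import pytest

from mcpinn.synthetic_data import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    """Reduced-size generation spec shared by the fast unit tests."""
    return SyntheticSpec(n_compounds=300, n_proteins=60, n_pairs=3000, seed=7)


@pytest.fixture(scope="session")
def small_bundle(small_spec):
    return generate_dataset(small_spec)


@pytest.fixture(scope="session")
def small_dataset(small_bundle):
    return small_bundle.dataset


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
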