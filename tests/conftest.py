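import numpy as np
import pytest

from cdbn_lesion import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def small_separable_dataset():
    """60 patches (20/class) at separable difficulty, fixed master seed."""
    return generate_dataset(GeneratorConfig.separable(), (20, 20, 20), master_seed=123)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
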