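import numpy as np
import pytest

from biaslens import DatasetSpec, generate_dataset, make_region_oracle


@pytest.fixture(scope="session")
def tiny_spec():
    """A miniature dataset spec for fast structural tests."""
    return DatasetSpec(split_sizes={"train": (6, 6), "val": (3, 3),
                                    "test": (2, 2)},
                       image_size=(64, 64), seed=11)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_spec):
    return generate_dataset(tiny_spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def corner_oracle():
    """Region oracle keyed on a square corner patch of a 64x64 image."""
    mask = np.zeros((64, 64), dtype=bool)
    mask[4:20, 4:20] = True
    return make_region_oracle(mask), mask
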