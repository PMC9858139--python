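import numpy as np
import pytest

import brainmr as bm


@pytest.fixture(scope="session")
def noiseless_phantom() -> bm.PhantomSample:
    return bm.make_phantom(bm.PhantomConfig(size=(128, 128), noise_sigma=0.0,
                                            seed=3))


@pytest.fixture(scope="session")
def noisy_phantom() -> bm.PhantomSample:
    return bm.make_phantom(bm.PhantomConfig(size=(128, 128), noise_sigma=3.0,
                                            seed=3))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


@pytest.fixture()
def small_dataset() -> bm.LabeledDataset:
    """A tiny two-class phantom cohort at desk scale."""
    return bm.make_dataset(4, 6, bm.PhantomConfig(size=(64, 64), seed=5))
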