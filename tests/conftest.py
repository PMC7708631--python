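import numpy as np
import pytest

from scenewalk.core import Grid, ModelParams
from scenewalk.synthdata import SyntheticSaliencySpec, make_saliency


@pytest.fixture(scope="session")
def grid128() -> Grid:
    return Grid()  # 128 x 128, 32 x 24 degrees


@pytest.fixture(scope="session")
def grid32() -> Grid:
    return Grid(n_x=32, n_y=32, extent_x=32.0, extent_y=24.0)


@pytest.fixture(scope="session")
def saliency128(grid128) -> np.ndarray:
    return make_saliency(SyntheticSaliencySpec(seed=11), grid128)


@pytest.fixture(scope="session")
def saliency32(grid32) -> np.ndarray:
    return make_saliency(SyntheticSaliencySpec(seed=11), grid32)


@pytest.fixture(scope="session")
def baseline_params() -> ModelParams:
    return ModelParams.baseline_defaults()


@pytest.fixture(scope="session")
def extended_params() -> ModelParams:
    return ModelParams.extended_defaults()
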