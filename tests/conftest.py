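import numpy as np
import pytest

from vesiph import (
    SceneParams,
    SegmentationParams,
    build_calibration_fixture,
)


@pytest.fixture(scope="session")
def fixture():
    """The reference O/R-versus-pH sigmoid pinned by the printed anchors."""
    return build_calibration_fixture()


@pytest.fixture(scope="session")
def curve(fixture):
    return fixture.as_curve()


@pytest.fixture
def seg_params():
    return SegmentationParams()


def noiseless_params(**overrides) -> SceneParams:
    """Scene parameters with every stochastic corruption disabled."""
    base = dict(
        n_vesicles=30,
        poisson_noise=False,
        read_noise_sd=0.0,
        psf_sigma_um=0.0,
        background_o=0.0,
        background_r=0.0,
        seed=0,
    )
    base.update(overrides)
    return SceneParams(**base)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
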