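import warnings

import numpy as np
import pytest

from neurophenotyper.synth import (
    FiberParams,
    PunctaParams,
    SceneParams,
    generate_image_scene,
)


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="no accepted nuclei")
        warnings.filterwarnings("ignore", message="empty or flat Hoechst")
        yield


@pytest.fixture
def nuclei_scene():
    """20 countable nuclei, 3 under the area gate, 2 pyknotic-bright."""
    params = SceneParams(n_nuclei=20, n_small_nuclei=3, n_pyknotic_nuclei=2)
    return generate_image_scene(params, seed=11)


@pytest.fixture
def fiber_scene():
    params = SceneParams(
        n_nuclei=0, fibers=[FiberParams(channel="btub", n_fibers=8)]
    )
    return generate_image_scene(params, seed=21)


@pytest.fixture
def synapse_scene():
    params = SceneParams(
        pixel_size_um=0.22,
        n_nuclei=0,
        fibers=[FiberParams(channel="btub", n_fibers=4, length_um=(60, 90), width_um=1.2)],
        puncta=PunctaParams(n_pre=50, n_post=50, coloc_fraction=0.4),
    )
    return generate_image_scene(params, seed=31)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
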