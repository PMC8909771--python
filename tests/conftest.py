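import numpy as np
import pytest

import ablateguide as ag


@pytest.fixture(scope="session")
def scene():
    """Default phantom scene, shared across tests (generation is pure)."""
    return ag.make_phantom(seed=7)


@pytest.fixture(scope="session")
def segmented(scene):
    return ag.segment_auto(scene.volume)


@pytest.fixture(scope="session")
def tracker_frame():
    """A representative world-to-tracker rigid motion."""
    return ag.RigidTransform.from_euler((5.0, -3.0, 12.0), (20.0, -30.0, 50.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
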