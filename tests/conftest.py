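import numpy as np
import pytest

from chromasal import synthetic


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def scene_bundle():
    """One deterministic paired color/gray bundle at the default study
    conditions (18 subjects, 50 fixations each, boost 5)."""
    return synthetic.generate_scene(seed=0)


@pytest.fixture(scope="session")
def sod_fixture():
    return synthetic.generate_sod_fixture(seed=1)
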