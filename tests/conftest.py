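import numpy as np
import pytest

from vstain import phantom


@pytest.fixture(scope="session")
def small_spec():
    """Default desk-scale phantom: 64 px patches, ~6 nuclei each."""
    return phantom.PhantomSpec(image_size=64, nuclei_rate=6.0,
                               nucleus_axes=(5.5, 4.0, 1.0),
                               stroma_texture=(5.0, 0.85), seed=7)


@pytest.fixture(scope="session")
def small_layout(small_spec):
    return phantom.sample_layout(small_spec)


@pytest.fixture(scope="session")
def phantom_dataset(small_spec, tmp_path_factory):
    """Unpaired 8+8 patch dataset on disk with its manifest."""
    out = tmp_path_factory.mktemp("phantom_data")
    manifest = phantom.make_dataset(small_spec, out, 8, 8, paired=False)
    return out, manifest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
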