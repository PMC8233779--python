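import numpy as np
import pytest

from limboct import phantom


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A (3, 3, 2)-eye synthetic cohort (32 quadrants) shared across tests."""
    out = tmp_path_factory.mktemp("cohort")
    manifest = phantom.generate_cohort(3, 3, 2, seed=11, out_dir=out)
    return manifest, out


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
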