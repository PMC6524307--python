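import warnings

import numpy as np
import pytest

from mvct_enhance import (DictionaryConfig, PhantomSpec, build_dictionary,
                          make_eval_scene, make_training_pairs)


@pytest.fixture(scope="session")
def small_spec():
    """A 96 px phantom with geometry scaled from the 256 px default."""
    return PhantomSpec(side=96, body_radius=37.5)


@pytest.fixture(scope="session")
def small_dictionary(small_spec):
    """Dictionary trained once on synthetic KVCT/MVCT pairs of the small
    phantom; shared by pipeline/sparse-coding tests."""
    pairs = make_training_pairs(small_spec, n_slices=5, seed=11)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return build_dictionary(pairs, DictionaryConfig(k_hq=128, k_na=128))


@pytest.fixture(scope="session")
def small_scene(small_spec):
    """(clean, noisy MVCT, target ROI, background ROI) on the small phantom."""
    return make_eval_scene(small_spec, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
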