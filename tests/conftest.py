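import numpy as np
import pytest

import conedetect as cd


@pytest.fixture(scope="session")
def small_suite():
    """Five training + two validation confocal mosaics (desk-scale)."""
    return cd.make_fixture_suite(seed=7, modality="confocal", n_train=5, n_val=2)


@pytest.fixture(scope="session")
def small_patchset(small_suite):
    return cd.build_training_set(small_suite.train_images, small_suite.train_marks,
                                 rng_seed=0)


@pytest.fixture(scope="session")
def trained_small_net(small_patchset):
    """A network trained briefly on the small fixture — enough to separate
    cone from non-cone patches, not a full-scale model."""
    net = cd.build_network(seed=0)
    cfg = cd.TrainingConfig(seed=0).scaled(10)
    cd.train_network(net, small_patchset.patches, small_patchset.labels, cfg)
    return net


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
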