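import numpy as np
import pytest

import lungood as lg


@pytest.fixture(scope="session")
def grid16():
    return lg.PatchGridSpec(patch_edge=16, overlap_fraction=0.2)


@pytest.fixture(scope="session")
def control_pair():
    return lg.generate_phantom(lg.PhantomSpec(seed=2), subject_id="ctrl")


@pytest.fixture(scope="session")
def diseased_pair():
    spec = lg.PhantomSpec(emphysema_burden=0.15, airtrap_burden=0.15, seed=1)
    return lg.generate_phantom(spec, subject_id="sick")


@pytest.fixture(scope="session")
def small_patch_set(control_pair, diseased_pair, grid16):
    """HU patches pooled from one control and one diseased phantom."""
    pc, _ = lg.extract_patch_grid(control_pair, grid16)
    pd_, _ = lg.extract_patch_grid(diseased_pair, grid16)
    return pc + pd_


@pytest.fixture(scope="session")
def trained_encoder(small_patch_set):
    cfg = lg.EncoderConfig(epochs=4, batch_size=32, seed=0)
    return lg.train_encoder(small_patch_set, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
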