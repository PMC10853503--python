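import numpy as np
import pytest

from clustervit import backbone as bb
from clustervit import ssl_train as ssl
from clustervit import tiles


@pytest.fixture(scope="session")
def tiny_cfg():
    return bb.BackboneConfig.tiny()


@pytest.fixture(scope="session")
def micro_cfg():
    """A minimal two-stage config for hand-checkable forwards (16 px tiles)."""
    return bb.BackboneConfig(
        image_size=16,
        patch_size=8,
        embed_dim=16,
        n_heads=2,
        stage_cls_counts=(4, 2),
        msa_blocks_per_stage=(1, 1),
        mlp_ratio=2.0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_params(tiny_cfg):
    return bb.init_params(tiny_cfg, np.random.default_rng(0), dtype=np.float64)


@pytest.fixture(scope="session")
def synthetic_batch():
    return tiles.generate_synthetic_dataset(40, seed=7)


@pytest.fixture(scope="session")
def trained_tiny():
    """A short self-distillation run shared by training/probe tests.

    Small (120 tiles, 2 epochs) so the suite stays fast; the full-scale run
    lives in the acceptance tests."""
    data = tiles.generate_synthetic_dataset(120, seed=11)
    cfg = bb.BackboneConfig.tiny()
    scfg = ssl.SSLConfig.tiny()
    scfg.epochs = 2
    result = ssl.train(data, cfg, scfg, seed=11)
    return cfg, scfg, result
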