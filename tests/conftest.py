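import numpy as np
import pytest

from voxalign.contrast import ContrastiveConfig, EncoderConfig, PatchSpec
from voxalign.simdata import simulate_cohort


@pytest.fixture(scope="session")
def desk_enc():
    return EncoderConfig(depth=2, heads=4, width=64, proj_dim=64)


@pytest.fixture(scope="session")
def desk_spec():
    return PatchSpec((8, 8, 8), (32, 32, 32))


@pytest.fixture(scope="session")
def tiny_enc():
    return EncoderConfig(depth=1, heads=2, width=16, proj_dim=8)


@pytest.fixture(scope="session")
def tiny_spec():
    return PatchSpec((4, 4, 4), (8, 8, 8))


@pytest.fixture(scope="session")
def small_cohort():
    """16 subjects, 8^3 volumes: fast enough for optimization smoke tests."""
    _, _, volumes, _ = simulate_cohort(
        n_subjects=16, n_snps=200, shape=(8, 8, 8), seed=11
    )
    return volumes


def tiny_con(**kw):
    base = dict(queue_size=64, epochs=2, batch_size=8, seed=3)
    base.update(kw)
    return ContrastiveConfig(**base)
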