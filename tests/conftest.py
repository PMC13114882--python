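import numpy as np
import pytest

from fmrifuse import SimConfig, make_dataset
from fmrifuse.data import prepare_dfc
from fmrifuse.dfc import DfcParams


@pytest.fixture(scope="session")
def tiny_config() -> SimConfig:
    """Small cohort exercising every pipeline stage in seconds."""
    return SimConfig(
        n_subjects=12,
        n_sites=2,
        vol_shape=(16, 16, 16),
        ts=120,
        atlas_specs=(("A", 6), ("B", 5)),
        coupling_pairs=((0, 1),),
        seed=42,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    ds = make_dataset(tiny_config)
    prepare_dfc(ds.records, DfcParams(window_volumes=30, step_volumes=2))
    return ds


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
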