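import numpy as np
import pytest

from dynconn.synth import SynthConfig
from dynconn.trace_io import DffTrace


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fs():
    return 22.7


def make_dff(values, fs=22.7, cell_id="cell", f0=100.0):
    return DffTrace(values=np.asarray(values, dtype=float), fs=fs, f0=f0, cell_id=cell_id)


@pytest.fixture
def short_cfg():
    """Small, fast synthetic recording for round-trip style tests."""
    return SynthConfig(
        n_cells=3, duration=120.0, base_rate=0.2, shared_fraction=0.5,
        noise_sd=0.02, seed=7,
    )
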