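import numpy as np
import pytest

from orca.chunking import Chunk
from orca.ln_model import LNParams, simulate
from orca.preprocessing import Trace
from orca.synthetic import emg_peak_value, emg_profile

CALCIUM_DT = 1.0 / 1.66


@pytest.fixture(scope="session")
def chunk_grid():
    """Standard chunk time grid with a unit-peak elution profile at 0."""
    t_rel = np.arange(-10.0, 40.0, CALCIUM_DT)
    stim = emg_profile(t_rel, 0.0, 1.5, 3.0) / emg_peak_value(1.5, 3.0)
    return t_rel, stim


@pytest.fixture(scope="session")
def one_comp_truth():
    return LNParams(k_a=0.5, k_af=0.4, k_f=0.12, n_components=1)


@pytest.fixture
def make_chunk(chunk_grid):
    """Factory: a chunk carrying a forward-simulated response plus noise."""
    t_rel, stim = chunk_grid

    def _make(params, noise_sd=0.0, seed=0, code="SYNT"):
        clean = simulate(params, Trace(t_rel, stim, "fid")).v
        rng = np.random.default_rng(seed)
        v = clean + rng.normal(0.0, noise_sd, clean.size)
        return Chunk(code, t_rel, v, stim, -2, 0, 100.0)

    return _make
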