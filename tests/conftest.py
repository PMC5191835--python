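import numpy as np
import pandas as pd
import pytest

from entrosurge import synthetic_data as sd
from entrosurge.containers import MoleculeMatrix


@pytest.fixture(scope="session")
def constant_schedule():
    return sd.make_schedule("constant", n_genes=8, seed=0)


@pytest.fixture(scope="session")
def constant_matrix(constant_schedule):
    """Small stationary snapshot matrix from a time-invariant schedule."""
    return sd.sample_snapshots(constant_schedule, 30, seed=1)


@pytest.fixture(scope="session")
def surge_matrix():
    sch = sd.make_schedule("entropy_surge", n_genes=20, seed=1)
    return sd.sample_snapshots(sch, 50, seed=2)


@pytest.fixture
def noise_free_models():
    spikes = sd.SpikeModel(cell_effect_sd=0.0, residual_sd=0.0, fail_prob=0.0)
    dropout = sd.DropoutModel(ud_prob=0.0, bad_cell_prob=0.0)
    return spikes, dropout


def make_matrix(values: np.ndarray, times, genes=None) -> MoleculeMatrix:
    """Build a MoleculeMatrix from a raw array and per-cell time labels."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[1])]
    ids = [f"c{i}" for i in range(values.shape[0])]
    return MoleculeMatrix(
        pd.DataFrame(values, index=ids, columns=genes),
        pd.Series(list(times), index=ids),
    )
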