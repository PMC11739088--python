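import numpy as np
import pytest

from sctkit.grid import ImageGrid, Modality
from sctkit.phantom import PhantomSpec, generate_pair


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom_spec():
    return PhantomSpec(grid_size=64, discrepancy_level=0.5, n_gas_pockets=8, seed=7)


@pytest.fixture(scope="session")
def phantom_pair(phantom_spec):
    """One aligned-geometry MR/CT phantom slice pair with labels."""
    return generate_pair(phantom_spec, slice_index=0)


def make_ct(values, spacing=1.0):
    return ImageGrid(np.asarray(values, dtype=float), spacing, Modality.CT)


def make_mr(values, spacing=1.0):
    return ImageGrid(np.asarray(values, dtype=float), spacing, Modality.MR)
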