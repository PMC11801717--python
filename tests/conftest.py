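import numpy as np
import pytest

from vegeff.types import AnnualRasterStack


def make_stack(values, years=None, variable="VQQI", cell_area=1.0, mask=None):
    """Stack from a (n_years, rows, cols) array-like (lists accepted)."""
    data = np.asarray(values, dtype=float)
    if data.ndim == 1:  # single-pixel series
        data = data[:, None, None]
    if years is None:
        years = np.arange(2000, 2000 + data.shape[0])
    if mask is None:
        mask = np.ones(data.shape[1:], dtype=bool)
    return AnnualRasterStack(variable, years, data, mask, cell_area)


@pytest.fixture
def stack_factory():
    return make_stack


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
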