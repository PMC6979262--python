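import numpy as np
import pytest

from rdrbench.data import CountMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def make_matrix(values, labels=None, library_sizes=None, iso_ids=None, cell_ids=None):
    """Build a CountMatrix from a raw array with auto-generated ids."""
    values = np.asarray(values, dtype=float)
    n_iso, n_cells = values.shape
    return CountMatrix(
        values=values,
        isoform_ids=iso_ids or [f"g{i:04d}" for i in range(n_iso)],
        cell_ids=cell_ids or [f"c{j:04d}" for j in range(n_cells)],
        group_labels=labels,
        library_sizes=library_sizes,
    )


def matrix_from_logvalues(y, labels, library_sizes_const=1e6):
    """CountMatrix whose log2(CPM+1) equals exactly the given array.

    With library sizes fixed to 1e6, CPM equals the raw values, so storing
    2**y - 1 makes log2(CPM+1) reproduce y.
    """
    y = np.asarray(y, dtype=float)
    vals = np.exp2(y) - 1.0
    n_cells = y.shape[1]
    return make_matrix(
        vals, labels=labels, library_sizes=np.full(n_cells, library_sizes_const)
    )


@pytest.fixture
def two_group_matrix(rng):
    """A small 60-isoform, 12-cell labelled matrix of overdispersed counts."""
    vals = rng.poisson(rng.gamma(1.0, 8.0, size=(60, 12)))
    vals[0] = 0  # an all-zero isoform
    return make_matrix(vals.astype(float), labels=["a"] * 6 + ["b"] * 6)
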