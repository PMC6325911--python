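import numpy as np
import pytest

from diskfact import DiskMatrix, create_matrix


def as_diskmatrix(arr, path, precision="double") -> DiskMatrix:
    """Write an in-memory array to disk and return its handle."""
    arr = np.atleast_2d(np.asarray(arr))
    mat = create_matrix(path, arr.shape[0], arr.shape[1], precision)
    mm = mat.memmap(mode="r+")
    mm[:] = arr
    mm.flush()
    del mm
    return mat


@pytest.fixture
def make_matrix(tmp_path):
    """Factory fixture: ndarray -> DiskMatrix in the test's tmp dir."""
    counter = iter(range(10**6))

    def _make(arr, precision="double"):
        return as_diskmatrix(
            arr, tmp_path / f"m{next(counter)}.bin", precision
        )

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
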