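"""File-backed dense matrices.

A :class:`DiskMatrix` is a headerless raw binary file of IEEE-754 numbers,
row-major, little-endian, with dimensions carried externally (the CLI passes
them on the command line).  Access goes through :func:`numpy.memmap`, so a
matrix far larger than main memory can be read and written while the operating
system pages tiles in and out on demand.  The module also provides the
text<->binary converters and the row-tile iterator every streaming kernel in
the package is built on.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Literal, Tuple

import numpy as np

from .errors import DimensionError, FormatError, ParameterError

Precision = Literal["single", "double"]

#: Little-endian dtypes for the two supported precisions.
DTYPES: dict[str, np.dtype] = {
    "single": np.dtype("<f4"),
    "double": np.dtype("<f8"),
}

#: Default tile budget: 64 Mi elements (256 MiB single / 512 MiB double),
#: sized to amortize I/O while staying small next to a desktop's memory.
DEFAULT_TILE_ELEMENTS = 64 * 2**20

#: Decimal digits guaranteeing binary->text->binary round trips.
ROUNDTRIP_DIGITS = {"single": 9, "double": 17}


def _check_precision(precision: str) -> np.dtype:
    if precision not in DTYPES:
        raise ParameterError(
            f"precision must be 'single' or 'double', got {precision!r}"
        )
    return DTYPES[precision]


@dataclass(frozen=True)
class TileSpec:
    """Half-open row/column bounds of one tile of a larger matrix."""

    row_start: int
    row_stop: int
    col_start: int
    col_stop: int

    @property
    def n_rows(self) -> int:
        return self.row_stop - self.row_start

    @property
    def n_cols(self) -> int:
        return self.col_stop - self.col_start


@dataclass(frozen=True)
class DiskMatrix:
    """Handle to a dense matrix stored in a raw binary file.

    Parameters
    ----------
    path
        Location of the backing file.
    n_rows, n_cols
        Matrix dimensions; for genotype matrices rows are individuals (N) and
        columns are markers (M), for GRMs both equal N.
    precision
        ``"single"`` (float32) or ``"double"`` (float64).
    """

    path: Path
    n_rows: int
    n_cols: int
    precision: Precision

    @property
    def dtype(self) -> np.dtype:
        return DTYPES[self.precision]

    @property
    def shape(self) -> Tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def itemsize(self) -> int:
        return self.dtype.itemsize

    @property
    def nbytes(self) -> int:
        return self.n_rows * self.n_cols * self.itemsize

    def memmap(self, mode: str = "r") -> np.memmap:
        """Memory-map the backing file as an ``n_rows x n_cols`` array."""
        return np.memmap(
            self.path, dtype=self.dtype, mode=mode, shape=(self.n_rows, self.n_cols)
        )

    def read(self, validate: bool = False) -> np.ndarray:
        """Load the whole matrix into memory (small matrices only)."""
        arr = np.array(self.memmap(mode="r"))
        if validate and not np.isfinite(arr).all():
            bad = int(np.count_nonzero(~np.isfinite(arr)))
            raise FormatError(
                f"{self.path}: {bad} non-finite value(s) in validated read"
            )
        return arr


def create_matrix(
    path: os.PathLike | str, n_rows: int, n_cols: int, precision: Precision
) -> DiskMatrix:
    """Allocate a zero-filled backing file and return its handle."""
    dtype = _check_precision(precision)
    if n_rows < 1 or n_cols < 1:
        raise ParameterError(f"dimensions must be positive, got {n_rows}x{n_cols}")
    path = Path(path)
    mm = np.memmap(path, dtype=dtype, mode="w+", shape=(n_rows, n_cols))
    mm.flush()
    del mm
    return DiskMatrix(path=path, n_rows=n_rows, n_cols=n_cols, precision=precision)


def open_matrix(
    path: os.PathLike | str, n_rows: int, n_cols: int, precision: Precision
) -> DiskMatrix:
    """Open an existing raw binary matrix, checking the byte count.

    The file must hold exactly ``n_rows * n_cols`` elements of the requested
    precision; a mismatch raises :class:`DimensionError` naming both counts so
    the caller can tell a wrong-``n`` invocation from a truncated file.
    """
    dtype = _check_precision(precision)
    path = Path(path)
    if n_rows < 1 or n_cols < 1:
        raise ParameterError(f"dimensions must be positive, got {n_rows}x{n_cols}")
    if not path.is_file():
        raise OSError(f"matrix file not found: {path}")
    expected = n_rows * n_cols * dtype.itemsize
    actual = path.stat().st_size
    if actual != expected:
        raise DimensionError(
            f"{path}: file holds {actual} bytes but {n_rows}x{n_cols} "
            f"{precision}-precision elements require {expected}"
        )
    return DiskMatrix(path=path, n_rows=n_rows, n_cols=n_cols, precision=precision)


def text_to_binary(
    text_path: os.PathLike | str,
    precision: Precision,
    out_path: os.PathLike | str,
) -> DiskMatrix:
    """Convert a whitespace-separated text matrix to raw binary.

    One matrix row per line; scientific notation is accepted.  Rows are
    streamed, so the text file may exceed memory.  Ragged rows and
    non-numeric tokens are reported with their 1-based line number.
    """
    dtype = _check_precision(precision)
    text_path = Path(text_path)
    out_path = Path(out_path)
    n_cols = 0
    n_rows = 0
    with open(text_path) as src, open(out_path, "wb") as dst:
        for lineno, line in enumerate(src, start=1):
            tokens = line.split()
            if not tokens:
                continue  # blank/trailing lines are ignored
            if n_cols == 0:
                n_cols = len(tokens)
            elif len(tokens) != n_cols:
                raise FormatError(
                    f"{text_path}: line {lineno} has {len(tokens)} values, "
                    f"expected {n_cols}"
                )
            try:
                row = np.array(tokens, dtype=np.float64)
            except ValueError as exc:
                raise FormatError(
                    f"{text_path}: line {lineno}: non-numeric token ({exc})"
                ) from exc
            dst.write(np.ascontiguousarray(row, dtype=dtype).tobytes())
            n_rows += 1
    if n_rows == 0:
        raise FormatError(f"{text_path}: no matrix rows found")
    return DiskMatrix(
        path=out_path, n_rows=n_rows, n_cols=n_cols, precision=precision
    )


def binary_to_text(
    matrix: DiskMatrix,
    out_path: os.PathLike | str,
    digits: int | None = None,
    tile_elements: int = DEFAULT_TILE_ELEMENTS,
) -> Path:
    """Render a binary matrix as text, one row per line.

    ``digits`` is the number of significant digits; the default is the
    precision's decimal round-trip guarantee (9 for single, 17 for double) so
    text->binary->text is lossless.
    """
    out_path = Path(out_path)
    if digits is None:
        digits = ROUNDTRIP_DIGITS[matrix.precision]
    if digits < 1:
        raise ParameterError(f"digits must be positive, got {digits}")
    fmt = f"%.{digits}g"
    with open(out_path, "w") as dst:
        for _, block in iter_row_tiles(matrix, tile_elements):
            np.savetxt(dst, block, fmt=fmt, delimiter=" ")
    return out_path


def iter_row_tiles(
    matrix: DiskMatrix, max_tile_elements: int = DEFAULT_TILE_ELEMENTS
) -> Iterator[Tuple[TileSpec, np.ndarray]]:
    """Yield contiguous row blocks covering the matrix exactly once, in order.

    Each yielded block is an in-memory copy of at most ``max_tile_elements``
    elements; the budget must admit at least one full row.
    """
    if max_tile_elements < matrix.n_cols:
        raise ParameterError(
            f"tile budget of {max_tile_elements} elements is below one "
            f"{matrix.n_cols}-element row"
        )
    rows_per_tile = max(1, max_tile_elements // matrix.n_cols)
    mm = matrix.memmap(mode="r")
    try:
        for start in range(0, matrix.n_rows, rows_per_tile):
            stop = min(start + rows_per_tile, matrix.n_rows)
            spec = TileSpec(start, stop, 0, matrix.n_cols)
            yield spec, np.array(mm[start:stop])
    finally:
        del mm


def n_row_tiles(matrix: DiskMatrix, max_tile_elements: int) -> int:
    """Number of tiles :func:`iter_row_tiles` will produce."""
    rows_per_tile = max(1, max_tile_elements // matrix.n_cols)
    return math.ceil(matrix.n_rows / rows_per_tile)


def write_vector(
    values: np.ndarray, out_path: os.PathLike | str, precision: Precision
) -> DiskMatrix:
    """Store a 1-D vector as an n x 1 binary matrix (eigen/singular values)."""
    dtype = _check_precision(precision)
    values = np.asarray(values).reshape(-1, 1)
    out_path = Path(out_path)
    np.ascontiguousarray(values, dtype=dtype).tofile(out_path)
    return DiskMatrix(
        path=out_path, n_rows=values.shape[0], n_cols=1, precision=precision
    )
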