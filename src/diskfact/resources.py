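"""Analytic memory and disk footprint models.

The eigendecomposition model is the closed-form peak-memory account of an
in-memory divide-and-conquer run: the N x N matrix itself plus the solver's
documented minimum workspace of ``1 + 6N + 2N²`` floats and ``3 + 5N``
4-byte integers.  Totals are reported in GiB (2³⁰ bytes) rounded half-up to
one decimal, the convention used when quoting such footprints for desktop
feasibility planning.

The SVD and disk models are the package's own accounting of its Gram-route
implementation; their formulas are spelled out in the README.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal

from .diskmatrix import DEFAULT_TILE_ELEMENTS, DTYPES, Precision, _check_precision
from .errors import ParameterError

GIB = 2**30


def _gib_1dp(total_bytes: int) -> float:
    return float(
        (Decimal(total_bytes) / Decimal(GIB)).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    )


@dataclass(frozen=True)
class ResourceEstimate:
    """Predicted peak footprint of one factorization route."""

    matrix_bytes: int
    workspace_bytes: int
    integer_workspace_bytes: int

    @property
    def total_bytes(self) -> int:
        return self.matrix_bytes + self.workspace_bytes + self.integer_workspace_bytes

    @property
    def total_gib_1dp(self) -> float:
        """Total in GiB rounded half-up to one decimal place."""
        return _gib_1dp(self.total_bytes)


def estimate_eigen_memory(n: int, precision: Precision) -> ResourceEstimate:
    """Peak memory of an in-memory full eigendecomposition of an N x N GRM.

    ``matrix + (1 + 6n + 2n²) floats + (3 + 5n) int32`` — the divide-and-
    conquer driver's minimum when eigenvectors are requested.
    """
    s = _check_precision(precision).itemsize
    if n < 1:
        raise ParameterError(f"n must be positive, got {n}")
    return ResourceEstimate(
        matrix_bytes=n * n * s,
        workspace_bytes=(1 + 6 * n + 2 * n * n) * s,
        integer_workspace_bytes=(3 + 5 * n) * 4,
    )


def estimate_svd_memory(
    n: int,
    m: int,
    k: int,
    precision: Precision,
    route: Literal["gram", "dense"] = "gram",
    accumulation_precision: Precision = "double",
    tile_elements: int = DEFAULT_TILE_ELEMENTS,
) -> ResourceEstimate:
    """Peak resident memory of a thin/top-k SVD of an N x M matrix.

    gram route (the package's streaming implementation): the M x M Gram
    matrix in accumulation precision, the M x k right-vector block, and one
    row tile; the N x M input and N x k output never reside in memory.

    dense route: a conventional in-memory divide-and-conquer thin SVD —
    input (N·M) + U (N·M) + V (M²) floats, ``4M² + 7M`` float workspace and
    ``8M`` integers.
    """
    s = _check_precision(precision).itemsize
    if n < 1 or m < 1:
        raise ParameterError(f"dimensions must be positive, got {n}x{m}")
    if not 1 <= k <= min(n, m):
        raise ParameterError(f"k={k} outside [1, min(n, m)={min(n, m)}]")
    if route == "gram":
        s_acc = DTYPES[accumulation_precision].itemsize
        return ResourceEstimate(
            matrix_bytes=tile_elements * s,
            workspace_bytes=m * m * s_acc + m * k * s,
            integer_workspace_bytes=0,
        )
    if route == "dense":
        return ResourceEstimate(
            matrix_bytes=2 * n * m * s + m * m * s,
            workspace_bytes=(4 * m * m + 7 * m) * s,
            integer_workspace_bytes=8 * m * 4,
        )
    raise ParameterError(f"unknown route {route!r}")


def estimate_disk(
    n: int,
    m: int,
    precision: Precision,
    route: Literal["eigen", "svd-gram"],
    k: int | None = None,
) -> int:
    """Total disk footprint (input + outputs + file-backed workspace), bytes.

    eigen: input N² + eigenvector matrix N² + the 2N²-class solver workspace
    + the eigenvalue vector.  svd-gram: input N·M + U (N·k) + V (M·k) + σ (k);
    the Gram pass needs no file-backed scratch.
    """
    s = _check_precision(precision).itemsize
    if n < 1 or m < 1:
        raise ParameterError(f"dimensions must be positive, got {n}x{m}")
    if route == "eigen":
        workspace = (1 + 6 * n + 2 * n * n) * s
        return n * n * s + n * n * s + workspace + n * s
    if route == "svd-gram":
        if k is None:
            k = min(n, m)
        if not 1 <= k <= min(n, m):
            raise ParameterError(f"k={k} outside [1, min(n, m)={min(n, m)}]")
        return n * m * s + n * k * s + m * k * s + k * s
    raise ParameterError(f"unknown route {route!r}")


def format_bytes(nbytes: int) -> str:
    """Human-readable size with binary prefixes."""
    if nbytes < 1024:
        return f"{nbytes} B"
    exp = min(int(math.log(nbytes, 1024)), 4)
    unit = ["B", "KiB", "MiB", "GiB", "TiB"][exp]
    return f"{nbytes / 1024 ** exp:.1f} {unit}"
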