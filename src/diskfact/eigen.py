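"""Full eigendecomposition of symmetric matrices (GRMs).

Two modes share one code path into the divide-and-conquer LAPACK driver:

* ``memory`` — matrix copy, eigenvector output and solver workspace are
  ordinary in-memory arrays; peak footprint follows
  :func:`diskfact.resources.estimate_eigen_memory`.
* ``disk`` — the matrix copy (which becomes the eigenvector matrix), the
  ~2N²-element float workspace and the integer workspace are all
  ``np.memmap`` files, so resident memory stays bounded regardless of N.
  The arithmetic is identical to memory mode; only the storage moves.

Eigenvalues come back ascending (solver convention); eigenvector j is paired
with eigenvalue j.
"""

from __future__ import annotations

import shutil
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

from . import _lapack
from .diskmatrix import (
    DEFAULT_TILE_ELEMENTS,
    DTYPES,
    DiskMatrix,
    Precision,
    iter_row_tiles,
)
from .errors import DimensionError, ResourceError, SymmetryError
from .resources import estimate_eigen_memory, format_bytes

Mode = Literal["memory", "disk"]

#: Off-diagonal pairs sampled for the disk-mode symmetry check.
_SYMMETRY_SAMPLES = 4096
#: Matrices up to this edge are symmetry-checked exhaustively even on disk.
_FULL_CHECK_MAX_N = 2048


@dataclass
class EigenResult:
    """Eigenvalues and eigenvectors of a symmetric matrix.

    ``vectors_rowwise`` stores eigenvector j in *row* j (the natural layout of
    the solver's output buffer, which in disk mode is a file-backed map);
    :attr:`eigenvectors` exposes the conventional column-per-eigenvector view.
    """

    eigenvalues: np.ndarray
    vectors_rowwise: np.ndarray | None
    precision: Precision
    mode: Mode
    workspace_paths: tuple[Path, ...] = field(default_factory=tuple)

    @property
    def n(self) -> int:
        return self.eigenvalues.shape[0]

    @property
    def eigenvectors(self) -> np.ndarray:
        """N x N matrix whose column j is the eigenvector of eigenvalue j."""
        if self.vectors_rowwise is None:
            raise ValueError("decomposition was run with vectors=False")
        return self.vectors_rowwise.T

    def cleanup(self, keep_vectors: bool = True) -> None:
        """Remove disk-mode scratch files.

        With ``keep_vectors`` the (possibly file-backed) eigenvector buffer
        is first copied into memory — only sensible at small N; pass
        ``keep_vectors=False`` once outputs have been written elsewhere.
        """
        if self.vectors_rowwise is not None and self.workspace_paths:
            if keep_vectors:
                self.vectors_rowwise = np.asarray(self.vectors_rowwise).copy()
            else:
                self.vectors_rowwise = None
        for p in self.workspace_paths:
            Path(p).unlink(missing_ok=True)
        self.workspace_paths = ()


def _check_symmetry(
    matrix: DiskMatrix, symmetrize: bool, tile_elements: int
) -> None:
    """Reject asymmetric inputs; sampled check for large disk matrices."""
    if symmetrize:
        return
    eps = float(np.finfo(matrix.dtype).eps)
    mm = matrix.memmap(mode="r")
    n = matrix.n_rows
    if n * n <= min(tile_elements, _FULL_CHECK_MAX_N**2):
        a = np.asarray(mm)
        scale = float(np.abs(a).max()) if a.size else 0.0
        diff = np.abs(a - a.T)
        worst = float(diff.max(initial=0.0))
        if worst > 100.0 * eps * max(scale, 1.0):
            i, j = np.unravel_index(int(diff.argmax()), diff.shape)
            raise SymmetryError(
                f"matrix is not symmetric: |A[{i},{j}] - A[{j},{i}]| = {worst:.3g} "
                f"exceeds tolerance {100.0 * eps * max(scale, 1.0):.3g}"
            )
        return
    rng = np.random.default_rng(0)  # fixed: the check must be reproducible
    ii = rng.integers(0, n, _SYMMETRY_SAMPLES)
    jj = rng.integers(0, n, _SYMMETRY_SAMPLES)
    keep = ii != jj
    ii, jj = ii[keep], jj[keep]
    aij = np.array([mm[i, j] for i, j in zip(ii, jj)], dtype=np.float64)
    aji = np.array([mm[j, i] for i, j in zip(ii, jj)], dtype=np.float64)
    scale = max(float(np.abs(aij).max(initial=0.0)), 1.0)
    diff = np.abs(aij - aji)
    worst = int(diff.argmax()) if diff.size else 0
    if diff.size and diff[worst] > 100.0 * eps * scale:
        raise SymmetryError(
            f"matrix is not symmetric at sampled pair "
            f"({ii[worst]},{jj[worst]}): |difference| = {diff[worst]:.3g}"
        )


def _fill_buffer(
    matrix: DiskMatrix, buf: np.ndarray, symmetrize: bool, tile_elements: int
) -> None:
    """Copy (and optionally symmetrize) the input into the solver buffer."""
    src = matrix.memmap(mode="r")
    rows = max(1, tile_elements // matrix.n_cols)
    for start in range(0, matrix.n_rows, rows):
        stop = min(start + rows, matrix.n_rows)
        block = np.array(src[start:stop])
        if symmetrize:
            # transposed counterpart: columns start:stop of all rows
            block = 0.5 * (block + np.array(src[:, start:stop]).T)
        buf[start:stop] = block
    del src


def eigendecompose(
    matrix: DiskMatrix,
    mode: Mode = "memory",
    precision: Precision | None = None,
    symmetrize: bool = False,
    workspace_dir: Path | str | None = None,
    tile_elements: int = DEFAULT_TILE_ELEMENTS,
    check_free_space: bool = True,
    vectors: bool = True,
) -> EigenResult:
    """Compute all eigenpairs of a symmetric :class:`DiskMatrix`.

    Parameters
    ----------
    matrix
        Square symmetric input.  Asymmetry beyond ``100·ε·max|A|`` raises
        :class:`SymmetryError` unless ``symmetrize`` averages ``(A + Aᵀ)/2``.
    mode
        ``"memory"`` or ``"disk"`` (file-backed buffers, bounded residency).
    precision
        Working precision; defaults to the input's storage precision.
    workspace_dir
        Where disk mode puts its scratch files (default: next to the input,
        i.e. on the same volume).
    vectors
        With ``vectors=False`` only eigenvalues are computed; the solver
        then needs just ``2N + 1`` floats of workspace and runs markedly
        faster.  ``result.eigenvectors`` is unavailable in that case.
    """
    if matrix.n_rows != matrix.n_cols:
        raise DimensionError(
            f"eigendecomposition needs a square matrix, got {matrix.shape}"
        )
    if precision is None:
        precision = matrix.precision
    dtype = DTYPES[precision]
    n = matrix.n_rows
    _check_symmetry(matrix, symmetrize, tile_elements)

    lwork, liwork = _lapack.syevd_workspace_sizes(n, compute_vectors=vectors)
    workspace_paths: tuple[Path, ...] = ()

    if mode == "memory":
        buf = np.empty((n, n), dtype=dtype)
        work = np.empty(lwork, dtype=dtype)
        iwork = np.empty(liwork, dtype=np.int32)
    elif mode == "disk":
        wdir = Path(workspace_dir) if workspace_dir else matrix.path.parent
        wdir.mkdir(parents=True, exist_ok=True)
        need = (n * n + lwork) * dtype.itemsize + liwork * 4
        if check_free_space:
            free = shutil.disk_usage(wdir).free
            if need > free:
                est = estimate_eigen_memory(n, precision)
                raise ResourceError(
                    f"disk-mode eigendecomposition at N={n} needs "
                    f"{format_bytes(need)} of workspace in {wdir} but only "
                    f"{format_bytes(free)} is free "
                    f"(analytic estimate: {est.total_gib_1dp} GiB)"
                )
        prefix = tempfile.mktemp(prefix="eigws_", dir=wdir)
        vec_path = Path(prefix + ".vectors.bin")
        work_path = Path(prefix + ".work.bin")
        iwork_path = Path(prefix + ".iwork.bin")
        buf = np.memmap(vec_path, dtype=dtype, mode="w+", shape=(n, n))
        work = np.memmap(work_path, dtype=dtype, mode="w+", shape=(lwork,))
        iwork = np.memmap(iwork_path, dtype=np.int32, mode="w+", shape=(liwork,))
        workspace_paths = (vec_path, work_path, iwork_path)
    else:
        raise ValueError(f"mode must be 'memory' or 'disk', got {mode!r}")

    _fill_buffer(matrix, buf, symmetrize, tile_elements)
    eigenvalues = np.empty(n, dtype=dtype)
    try:
        _lapack.syevd_inplace(buf, eigenvalues, work, iwork, compute_vectors=vectors)
    finally:
        if mode == "disk":
            work.flush()
            del work, iwork
            # solver scratch is no longer needed; the vector buffer is the output
            Path(workspace_paths[1]).unlink(missing_ok=True)
            Path(workspace_paths[2]).unlink(missing_ok=True)
            workspace_paths = (workspace_paths[0],)

    if not vectors:
        if mode == "disk":
            del buf
            Path(workspace_paths[0]).unlink(missing_ok=True)
            workspace_paths = ()
        buf = None
    return EigenResult(
        eigenvalues=eigenvalues,
        vectors_rowwise=buf,
        precision=precision,
        mode=mode,
        workspace_paths=workspace_paths,
    )


def check_reconstruction(
    matrix: DiskMatrix,
    result: EigenResult,
    tile_elements: int = DEFAULT_TILE_ELEMENTS,
) -> float:
    """Relative residual ``‖A·Q − Q·diag(λ)‖_F / ‖A‖_F``, computed tile-wise.

    Streams row tiles of A and row blocks of Q so it works out-of-core; all
    accumulation is in double precision.
    """
    n = result.n
    if matrix.shape != (n, n):
        raise DimensionError(
            f"matrix shape {matrix.shape} does not match result dimension {n}"
        )
    lam = result.eigenvalues.astype(np.float64)
    rows_q = max(1, tile_elements // n)
    num = 0.0
    den = 0.0
    for spec, block in iter_row_tiles(matrix, tile_elements):
        b = block.astype(np.float64)
        den += float(np.sum(b * b))
        aq = np.zeros((spec.n_rows, n))
        for c0 in range(0, n, rows_q):
            c1 = min(c0 + rows_q, n)
            # rows c0:c1 of Q == columns c0:c1 of the row-wise buffer
            q_rows = np.asarray(result.vectors_rowwise[:, c0:c1]).T.astype(np.float64)
            aq += b[:, c0:c1] @ q_rows
        q_tile = np.asarray(
            result.vectors_rowwise[:, spec.row_start : spec.row_stop]
        ).T.astype(np.float64)
        r = aq - q_tile * lam
        num += float(np.sum(r * r))
    if den == 0.0:
        return 0.0
    return float(np.sqrt(num) / np.sqrt(den))
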