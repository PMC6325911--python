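"""Thin and top-k SVD of tall matrices via out-of-core Gram accumulation.

For a tall N x M genotype matrix (N individuals ≫ M markers) the dominant
cost — and the only quadratic-in-M memory — is the Gram matrix G = AᵀA.
G is accumulated one row tile at a time, so A itself never has to be
resident; its eigendecomposition (M x M, in memory) yields the right
singular vectors V and σ = √λ, and a second streaming pass reconstructs
U = A·V·diag(1/σ).

Accuracy trade-off: squaring the matrix squares its condition number, so a
singular value σᵢ ≪ σ₁ carries a relative error of order ε·(σ₁/σᵢ)²
compared with ~ε for direct bidiagonalization.  For genotype matrices,
whose spectra are flat by construction, this is immaterial; eigenvalues of G below the numerical-rank
tolerance ``max(N,M)·ε·λ₁`` (equivalently σ below ~``√(max(N,M)·ε)·σ₁``,
the resolution limit of the squared problem) are reported as zero singular
values and their U columns zero-filled.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import scipy.linalg

from .diskmatrix import (
    DEFAULT_TILE_ELEMENTS,
    DTYPES,
    DiskMatrix,
    Precision,
    create_matrix,
    iter_row_tiles,
)
from .errors import DimensionError, ParameterError, ResourceError

Mode = Literal["memory", "disk"]

#: Largest Gram matrix (in elements) accumulated in memory by default:
#: 8192² doubles = 512 MiB.  Beyond this, eigendecomposition of the GRM
#: (module ``eigen``) is the appropriate route.
DEFAULT_MAX_GRAM_ELEMENTS = 8192**2


@dataclass(frozen=True)
class GramMatrix:
    """M x M Gram matrix AᵀA, exactly symmetric by construction."""

    values: np.ndarray
    accumulation_precision: Precision


@dataclass
class SVDResult:
    """Singular values and vectors, descending.

    ``left_vectors`` (U) is N x k, ``right_vectors`` (V) is M x k; column j
    of each pairs with ``singular_values[j]``.  ``zero_columns`` lists
    columns whose σ fell below the numerical-rank tolerance: their σ is 0
    and their U column zero-filled.  If the input was wide (N < M) it was
    transposed internally and U/V swapped back; ``transposed`` records this.
    """

    singular_values: np.ndarray
    left_vectors: np.ndarray
    right_vectors: np.ndarray
    precision: Precision
    k: int
    zero_columns: tuple[int, ...] = ()
    transposed: bool = False
    workspace_paths: tuple[Path, ...] = field(default_factory=tuple)

    def cleanup(self, keep_vectors: bool = True) -> None:
        """Remove disk-mode scratch files.

        With ``keep_vectors`` a file-backed U is first copied into memory;
        pass ``keep_vectors=False`` once outputs are written elsewhere.
        """
        if keep_vectors:
            self.left_vectors = np.asarray(self.left_vectors).copy()
            self.right_vectors = np.asarray(self.right_vectors).copy()
        for p in self.workspace_paths:
            Path(p).unlink(missing_ok=True)
        self.workspace_paths = ()


def gram_accumulate(
    matrix: DiskMatrix,
    accumulation_precision: Precision = "double",
    tile_elements: int = DEFAULT_TILE_ELEMENTS,
    max_gram_elements: int = DEFAULT_MAX_GRAM_ELEMENTS,
) -> GramMatrix:
    """Accumulate G = AᵀA by streaming row tiles (G += BᵀB per tile).

    Only the lower triangle is accumulated (rank-k update); it is mirrored
    once at the end, so G is exactly symmetric.  Accumulation defaults to
    double precision even for single inputs: with millions of rows,
    single-precision accumulation can lose small singular values entirely.
    """
    m = matrix.n_cols
    if m * m > max_gram_elements:
        raise ResourceError(
            f"Gram matrix would need {m}x{m} = {m * m} elements, over the "
            f"{max_gram_elements}-element budget; for matrices this wide, "
            "eigendecompose the N x N relationship matrix instead"
        )
    acc_dtype = DTYPES[accumulation_precision]
    syrk = (
        scipy.linalg.blas.dsyrk
        if acc_dtype == np.float64
        else scipy.linalg.blas.ssyrk
    )
    g = np.zeros((m, m), dtype=acc_dtype, order="F")
    for _, block in iter_row_tiles(matrix, tile_elements):
        b = np.asfortranarray(block, dtype=acc_dtype)
        g = syrk(1.0, b, beta=1.0, c=g, trans=1, lower=1, overwrite_c=1)
    full = np.tril(g) + np.tril(g, -1).T
    return GramMatrix(values=full, accumulation_precision=accumulation_precision)


def _transpose_to_tempfile(
    matrix: DiskMatrix, tile_elements: int
) -> tuple[DiskMatrix, Path]:
    """Materialize Aᵀ on disk (wide inputs are handled via the tall path)."""
    tmp = Path(
        tempfile.mktemp(prefix="svdT_", dir=matrix.path.parent)
    ).with_suffix(".bin")
    out = create_matrix(tmp, matrix.n_cols, matrix.n_rows, matrix.precision)
    dst = out.memmap(mode="r+")
    for spec, block in iter_row_tiles(matrix, tile_elements):
        dst[:, spec.row_start : spec.row_stop] = block.T
    dst.flush()
    del dst
    return out, tmp


def _normalize_signs(v: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive."""
    idx = np.abs(v).argmax(axis=0)
    signs = np.sign(v[idx, np.arange(v.shape[1])])
    signs[signs == 0] = 1.0
    return v * signs


def _svd_impl(
    matrix: DiskMatrix,
    k: int | None,
    mode: Mode,
    precision: Precision | None,
    accumulation_precision: Precision,
    tile_elements: int,
    max_gram_elements: int,
) -> SVDResult:
    if matrix.n_rows < 1 or matrix.n_cols < 1:
        raise DimensionError(f"empty matrix {matrix.shape}")
    if precision is None:
        precision = matrix.precision
    dtype = DTYPES[precision]

    transposed = matrix.n_rows < matrix.n_cols
    work_paths: list[Path] = []
    if transposed:
        matrix, tpath = _transpose_to_tempfile(matrix, tile_elements)
        work_paths.append(tpath)
    n, m = matrix.shape
    k_full = m  # == min(N, M) on the tall path
    k_eff = k_full if k is None else k

    gram = gram_accumulate(
        matrix, accumulation_precision, tile_elements, max_gram_elements
    )
    # m x m symmetric eigenproblem, in memory, descending
    lam, vecs = scipy.linalg.eigh(gram.values, driver="evd", check_finite=False)
    order = np.argsort(lam)[::-1][:k_eff]
    lam = lam[order]
    v = _normalize_signs(vecs[:, order])
    sigma = np.sqrt(np.clip(lam, 0.0, None))

    # Rank decision in λ-space: the Gram route computes λ = σ², so a true
    # zero singular value surfaces as λ ~ ε·λ₁, i.e. σ ~ √ε·σ₁.
    eps = float(np.finfo(dtype).eps)
    lam_tol = max(n, m) * eps * (float(lam[0]) if lam.size else 0.0)
    zero_cols = tuple(int(i) for i in np.nonzero(lam <= lam_tol)[0])
    sigma = sigma.copy()
    sigma[list(zero_cols)] = 0.0

    inv_sigma = np.zeros_like(sigma)
    keep = sigma > 0
    inv_sigma[keep] = 1.0 / sigma[keep]

    if mode == "disk":
        upath = Path(
            tempfile.mktemp(prefix="svdU_", dir=matrix.path.parent)
        ).with_suffix(".bin")
        u_store = create_matrix(upath, n, k_eff, precision)
        u = u_store.memmap(mode="r+")
        work_paths.append(upath)
    elif mode == "memory":
        u = np.empty((n, k_eff), dtype=dtype)
    else:
        raise ParameterError(f"mode must be 'memory' or 'disk', got {mode!r}")

    proj = v * inv_sigma  # m x k, accumulation precision
    for spec, block in iter_row_tiles(matrix, tile_elements):
        u[spec.row_start : spec.row_stop] = (
            block.astype(proj.dtype) @ proj
        ).astype(dtype)

    sigma_out = sigma.astype(dtype)
    v_out = v.astype(dtype)
    if transposed:
        # singular vectors of Aᵀ: its V is A's U and vice versa
        u, v_out = v_out, np.asarray(u)
    return SVDResult(
        singular_values=sigma_out,
        left_vectors=u,
        right_vectors=v_out,
        precision=precision,
        k=k_eff,
        zero_columns=zero_cols,
        transposed=transposed,
        workspace_paths=tuple(work_paths),
    )


def svd_thin(
    matrix: DiskMatrix,
    mode: Mode = "memory",
    precision: Precision | None = None,
    accumulation_precision: Precision = "double",
    tile_elements: int = DEFAULT_TILE_ELEMENTS,
    max_gram_elements: int = DEFAULT_MAX_GRAM_ELEMENTS,
) -> SVDResult:
    """Thin SVD (k = min(N, M)) via the streaming Gram route."""
    return _svd_impl(
        matrix, None, mode, precision, accumulation_precision,
        tile_elements, max_gram_elements,
    )


def svd_topk(
    matrix: DiskMatrix,
    k: int,
    mode: Mode = "memory",
    precision: Precision | None = None,
    accumulation_precision: Precision = "double",
    tile_elements: int = DEFAULT_TILE_ELEMENTS,
    max_gram_elements: int = DEFAULT_MAX_GRAM_ELEMENTS,
) -> SVDResult:
    """The k largest singular triplets, with k strictly below min(N, M).

    The full Gram pass is still required — restricting k saves only the U
    reconstruction, which is why computing a subset of singular values is
    barely cheaper than the thin SVD.  The result equals the first k columns
    of :func:`svd_thin` exactly (same code path, truncated selection).
    """
    kmin = min(matrix.n_rows, matrix.n_cols)
    if not isinstance(k, (int, np.integer)) or not 1 <= k < kmin:
        raise ParameterError(
            f"k must satisfy 1 <= k < min(N, M) = {kmin}, got {k}"
        )
    return _svd_impl(
        matrix, int(k), mode, precision, accumulation_precision,
        tile_elements, max_gram_elements,
    )


def check_svd_reconstruction(
    matrix: DiskMatrix,
    result: SVDResult,
    tile_elements: int = DEFAULT_TILE_ELEMENTS,
) -> float:
    """Relative residual ``‖A − U·diag(σ)·Vᵀ‖_F / ‖A‖_F``, streamed row-wise."""
    u, v = result.left_vectors, result.right_vectors
    sv = (np.asarray(v).astype(np.float64) * result.singular_values.astype(np.float64)).T
    num = 0.0
    den = 0.0
    for spec, block in iter_row_tiles(matrix, tile_elements):
        b = block.astype(np.float64)
        den += float(np.sum(b * b))
        r = b - np.asarray(u[spec.row_start : spec.row_stop]).astype(np.float64) @ sv
        num += float(np.sum(r * r))
    return float(np.sqrt(num) / np.sqrt(den)) if den else 0.0
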