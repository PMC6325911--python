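"""Seeded generation of genotype matrices and GRM-like symmetric fixtures.

Genotype matrices follow the standard biallelic-dosage model: entry (i, j)
is Binomial(2, p_j) with marker allele frequencies p_j drawn uniformly from
a MAF window, emulating unrelated individuals in Hardy-Weinberg
equilibrium.  GRMs are the VanRaden standardized kind, Z·Zᵀ/m with each
marker centered by 2p̂ and scaled by √(2p̂(1−p̂)), which makes them
symmetric PSD with diagonal near 1 — the structure the factorization
kernels are exercised against.

Every generator is a pure function of its seed: regenerating with the same
seed is byte-identical, regardless of the tile budget (randomness is drawn
in fixed-size row chunks).
"""

from __future__ import annotations

import logging
import os
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .diskmatrix import (
    DEFAULT_TILE_ELEMENTS,
    DiskMatrix,
    Precision,
    create_matrix,
    iter_row_tiles,
)
from .errors import ParameterError

logger = logging.getLogger(__name__)

#: Rows generated per RNG draw; fixed so outputs do not depend on tiling.
_CHUNK_ROWS = 1024


@dataclass(frozen=True)
class GenotypeSpec:
    """Parameters of a synthetic biallelic genotype matrix.

    MAF defaults span the commonly analyzed range: markers rarer than 5%
    are usually filtered out of GRM construction, and 0.5 is the maximum
    possible minor-allele frequency.
    """

    n_individuals: int
    n_markers: int
    maf_low: float = 0.05
    maf_high: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1 or self.n_markers < 1:
            raise ParameterError(
                f"dimensions must be positive, got "
                f"{self.n_individuals}x{self.n_markers}"
            )
        if not 0.0 < self.maf_low <= self.maf_high <= 0.5:
            raise ParameterError(
                f"need 0 < maf_low <= maf_high <= 0.5, got "
                f"[{self.maf_low}, {self.maf_high}]"
            )

    def allele_frequencies(self) -> np.ndarray:
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 0]))
        return rng.uniform(self.maf_low, self.maf_high, self.n_markers)


def generate_genotypes(
    spec: GenotypeSpec,
    out_path: os.PathLike | str,
    precision: Precision = "single",
) -> DiskMatrix:
    """Write a seeded N x M dosage matrix (entries in {0, 1, 2}) to disk."""
    out = create_matrix(out_path, spec.n_individuals, spec.n_markers, precision)
    p = spec.allele_frequencies()
    mm = out.memmap(mode="r+")
    for chunk, start in enumerate(range(0, spec.n_individuals, _CHUNK_ROWS)):
        stop = min(start + _CHUNK_ROWS, spec.n_individuals)
        rng = np.random.default_rng(
            np.random.SeedSequence([spec.seed, 1, chunk])
        )
        mm[start:stop] = rng.binomial(2, p, (stop - start, spec.n_markers))
    mm.flush()
    del mm
    return out


def _streamed_self_outer(
    source: DiskMatrix,
    out: DiskMatrix,
    scale: float,
    center: np.ndarray | None,
    spread: np.ndarray | None,
    keep: np.ndarray | None,
    tile_elements: int,
) -> None:
    """out = scale * Z·Zᵀ with Z = (source[:, keep] − center) / spread.

    Blocked over row-tile pairs so neither Z nor the N x N output needs to
    be resident; accumulation in double precision.
    """
    dst = out.memmap(mode="r+")

    def standardized(block: np.ndarray) -> np.ndarray:
        z = block.astype(np.float64)
        if keep is not None:
            z = z[:, keep]
        if center is not None:
            z = (z - center) / spread
        return z

    tiles = list(iter_row_tiles(source, tile_elements))
    for ti, (spec_i, block_i) in enumerate(tiles):
        zi = standardized(block_i)
        for spec_j, block_j in tiles[: ti + 1]:
            zj = standardized(block_j)
            prod = (zi @ zj.T) * scale
            dst[spec_i.row_start : spec_i.row_stop,
                spec_j.row_start : spec_j.row_stop] = prod
            if spec_i.row_start != spec_j.row_start:
                dst[spec_j.row_start : spec_j.row_stop,
                    spec_i.row_start : spec_i.row_stop] = prod.T
    dst.flush()
    del dst


def build_grm(
    genotypes: DiskMatrix,
    out_path: os.PathLike | str,
    precision: Precision = "double",
    tile_elements: int = DEFAULT_TILE_ELEMENTS,
) -> DiskMatrix:
    """VanRaden GRM = Z·Zᵀ/m from a dosage matrix, streamed in row tiles.

    Marker means are estimated in a first pass; monomorphic markers (zero
    variance after centering) are dropped with a logged count.  The output
    is symmetric PSD by construction.
    """
    n, m = genotypes.shape
    sums = np.zeros(m)
    for _, block in iter_row_tiles(genotypes, tile_elements):
        sums += block.sum(axis=0, dtype=np.float64)
    p_hat = sums / (2.0 * n)
    variance = 2.0 * p_hat * (1.0 - p_hat)
    keep = variance > 0.0
    m_kept = int(keep.sum())
    if m_kept == 0:
        raise ParameterError("all markers are monomorphic; GRM is undefined")
    if m_kept < m:
        logger.info("build_grm: dropped %d monomorphic marker(s)", m - m_kept)
    out = create_matrix(out_path, n, n, precision)
    _streamed_self_outer(
        genotypes,
        out,
        scale=1.0 / m_kept,
        center=2.0 * p_hat[keep],
        spread=np.sqrt(variance[keep]),
        keep=keep,
        tile_elements=tile_elements,
    )
    return out


def generate_symmetric(
    n: int,
    seed: int,
    kind: str,
    out_path: os.PathLike | str,
    precision: Precision = "double",
    noise: float = 0.05,
    tile_elements: int = DEFAULT_TILE_ELEMENTS,
) -> DiskMatrix:
    """Seeded symmetric N x N test matrix of a requested family.

    kinds
    -----
    ``grm_like``
        VanRaden GRM of a fresh genotype fixture with 2N markers.
    ``wishart``
        X·Xᵀ/(2N) for standard-normal X of shape N x 2N; eigenvalue bulk
        follows the Marchenko–Pastur law with ratio 1/2.
    ``diag_plus_noise``
        diag(d) + noise·(S + Sᵀ)/2 with d ~ U(0, 1) and S standard normal;
        at noise = 0 the eigenvalues are exactly the sorted diagonal.
    """
    if n < 1:
        raise ParameterError(f"n must be positive, got {n}")
    out_path = Path(out_path)
    if kind == "grm_like":
        spec = GenotypeSpec(n_individuals=n, n_markers=2 * n, seed=seed)
        with tempfile.TemporaryDirectory(dir=out_path.parent) as td:
            geno = generate_genotypes(spec, Path(td) / "geno.bin")
            return build_grm(geno, out_path, precision, tile_elements)
    if kind == "wishart":
        m = 2 * n
        with tempfile.TemporaryDirectory(dir=out_path.parent) as td:
            x = create_matrix(Path(td) / "x.bin", n, m, "double")
            mm = x.memmap(mode="r+")
            for chunk, start in enumerate(range(0, n, _CHUNK_ROWS)):
                stop = min(start + _CHUNK_ROWS, n)
                rng = np.random.default_rng(
                    np.random.SeedSequence([seed, 2, chunk])
                )
                mm[start:stop] = rng.standard_normal((stop - start, m))
            mm.flush()
            del mm
            out = create_matrix(out_path, n, n, precision)
            _streamed_self_outer(
                x, out, scale=1.0 / m, center=None, spread=None, keep=None,
                tile_elements=tile_elements,
            )
            return out
    if kind == "diag_plus_noise":
        rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
        d = rng.uniform(0.0, 1.0, n)
        s = rng.standard_normal((n, n))
        a = np.diag(d) + noise * 0.5 * (s + s.T)
        if noise == 0.0:
            a = np.diag(d)  # exactly diagonal, no -0.0 off-diagonals
        out = create_matrix(out_path, n, n, precision)
        mm = out.memmap(mode="r+")
        mm[:] = a
        mm.flush()
        del mm
        return out
    raise ParameterError(
        f"unknown kind {kind!r}; expected grm_like, wishart or diag_plus_noise"
    )
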