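"""Numerical-agreement metrics between two factorizations.

Agreement is quantified by three relative norms of the difference vector,
each normalized by the *reference* (second) argument:

    ‖test − reference‖_p / ‖reference‖_p    for p ∈ {∞, 1, 2}

i.e. the infinity (max-component), taxicab (sum of absolute components)
and Euclidean norms.  Eigen- and singular-vector signs are mathematically
arbitrary, so vector matrices are sign-aligned column-by-column against the
reference before comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ComparisonError, DimensionError, ParameterError

#: Columns whose paired values differ by less than this relative tolerance
#: span an ill-identified subspace; per-column reports mark them ambiguous.
DEGENERACY_RTOL = 1e-6


@dataclass(frozen=True)
class NormReport:
    """The three relative difference norms (reference-normalized)."""

    inf_norm: float
    taxicab_norm: float
    euclidean_norm: float

    def as_dict(self) -> dict[str, float]:
        return {
            "inf": self.inf_norm,
            "taxicab": self.taxicab_norm,
            "euclidean": self.euclidean_norm,
        }


def compare_vectors(test: np.ndarray, reference: np.ndarray) -> NormReport:
    """Relative ∞/1/2-norm differences of two equal-length vectors.

    The second argument is the normalizer; comparing a candidate against a
    trusted reference is therefore ``compare_vectors(candidate, trusted)``.
    """
    test = np.asarray(test, dtype=np.float64).ravel()
    reference = np.asarray(reference, dtype=np.float64).ravel()
    if test.shape != reference.shape:
        raise DimensionError(
            f"length mismatch: {test.shape[0]} vs {reference.shape[0]}"
        )
    if not np.any(reference):
        raise ParameterError("reference vector is zero; ratios are undefined")
    delta = test - reference
    return NormReport(
        inf_norm=float(np.abs(delta).max() / np.abs(reference).max()),
        taxicab_norm=float(np.abs(delta).sum() / np.abs(reference).sum()),
        euclidean_norm=float(
            np.linalg.norm(delta) / np.linalg.norm(reference)
        ),
    )


def align_signs(
    test_vectors: np.ndarray, reference_vectors: np.ndarray
) -> np.ndarray:
    """Flip test columns whose inner product with the reference is negative.

    This is the 2-norm-optimal per-column sign choice: flipping column v
    against reference r changes ‖v − r‖² by ±4⟨v, r⟩.
    """
    test_vectors = np.asarray(test_vectors)
    reference_vectors = np.asarray(reference_vectors)
    if test_vectors.shape != reference_vectors.shape:
        raise DimensionError(
            f"shape mismatch: {test_vectors.shape} vs {reference_vectors.shape}"
        )
    dots = np.einsum("ij,ij->j", test_vectors, reference_vectors)
    signs = np.where(dots < 0, -1.0, 1.0)
    return test_vectors * signs


def _extract(result) -> tuple[np.ndarray, np.ndarray, str]:
    """(values, vector matrix, kind) from an Eigen- or SVDResult."""
    if hasattr(result, "eigenvalues"):
        return (
            np.asarray(result.eigenvalues),
            np.asarray(result.eigenvectors),
            "eigen",
        )
    if hasattr(result, "singular_values"):
        vecs = np.vstack(
            [np.asarray(result.left_vectors), np.asarray(result.right_vectors)]
        )
        return np.asarray(result.singular_values), vecs, "svd"
    raise ComparisonError(f"not a factorization result: {type(result).__name__}")


def compare_factorizations(
    a, b, per_column: bool = False
) -> dict[str, object]:
    """Norm reports for two factorizations of the same kind and size.

    Returns ``{"values": NormReport, "vectors": NormReport}`` where the
    vector report covers the flattened, sign-aligned vector matrix (for SVD
    results, U stacked on V).  ``b`` is the reference/normalizer.  With
    ``per_column=True`` a ``"columns"`` list is added holding one NormReport
    per vector column, or the string ``"subspace-ambiguous"`` for columns
    whose reference values are degenerate (equal within a relative
    tolerance of neighbouring values): individual vectors in a repeated
    eigenvalue's subspace are not identifiable, so comparing them
    one-by-one is meaningless.
    """
    va, ma, kind_a = _extract(a)
    vb, mb, kind_b = _extract(b)
    if kind_a != kind_b:
        raise ComparisonError(f"cannot compare {kind_a} with {kind_b}")
    if va.shape != vb.shape or ma.shape != mb.shape:
        raise ComparisonError(
            f"size mismatch: values {va.shape} vs {vb.shape}, "
            f"vectors {ma.shape} vs {mb.shape}"
        )
    aligned = align_signs(ma, mb)
    out: dict[str, object] = {
        "values": compare_vectors(va, vb),
        "vectors": compare_vectors(aligned.ravel(), mb.ravel()),
    }
    if per_column:
        scale = float(np.abs(vb).max()) or 1.0
        degenerate = np.zeros(vb.size, dtype=bool)
        close = np.abs(np.diff(vb)) <= DEGENERACY_RTOL * scale
        degenerate[:-1] |= close
        degenerate[1:] |= close
        cols: list[object] = []
        for j in range(ma.shape[1]):
            if degenerate[j]:
                cols.append("subspace-ambiguous")
            else:
                cols.append(compare_vectors(aligned[:, j], mb[:, j]))
        out["columns"] = cols
    return out
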