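"""Direct access to LAPACK's divide-and-conquer symmetric eigensolver.

The high-level SciPy wrappers allocate the solver's float workspace — about
2N² elements when eigenvectors are requested — as ordinary heap memory.  That
is exactly the allocation an out-of-core run must keep on disk, so this module
calls ``ssyevd``/``dsyevd`` through the function pointers SciPy exports in
``scipy.linalg.cython_lapack.__pyx_capi__``: the caller supplies the matrix
*and* the workspace as arrays, either of which may be an ``np.memmap``.

LAPACK is column-major.  A symmetric matrix is layout-invariant, so a C-order
buffer can be handed over directly; on exit the buffer's *rows* are the
eigenvectors (the Fortran view's columns).
"""

from __future__ import annotations

import ctypes

import numpy as np
import scipy.linalg.cython_lapack as _cl

from .errors import ComputationError

_c_int_p = ctypes.POINTER(ctypes.c_int)
_c_float_p = ctypes.POINTER(ctypes.c_float)
_c_double_p = ctypes.POINTER(ctypes.c_double)
_c_char_p = ctypes.c_char_p


def _capsule_function(name: str, argtypes) -> ctypes._CFuncPtr:
    capsule = _cl.__pyx_capi__[name]
    get_name = ctypes.pythonapi.PyCapsule_GetName
    get_name.restype = ctypes.c_char_p
    get_name.argtypes = [ctypes.py_object]
    get_ptr = ctypes.pythonapi.PyCapsule_GetPointer
    get_ptr.restype = ctypes.c_void_p
    get_ptr.argtypes = [ctypes.py_object, ctypes.c_char_p]
    ptr = get_ptr(capsule, get_name(capsule))
    return ctypes.CFUNCTYPE(None, *argtypes)(ptr)


_SYEVD = {
    np.dtype(np.float64): _capsule_function(
        "dsyevd",
        [_c_char_p, _c_char_p, _c_int_p, _c_double_p, _c_int_p, _c_double_p,
         _c_double_p, _c_int_p, _c_int_p, _c_int_p, _c_int_p],
    ),
    np.dtype(np.float32): _capsule_function(
        "ssyevd",
        [_c_char_p, _c_char_p, _c_int_p, _c_float_p, _c_int_p, _c_float_p,
         _c_float_p, _c_int_p, _c_int_p, _c_int_p, _c_int_p],
    ),
}


def syevd_workspace_sizes(n: int, compute_vectors: bool = True) -> tuple[int, int]:
    """Documented minimum workspace of ``?syevd`` for an n x n problem.

    With eigenvectors: ``1 + 6n + 2n²`` floats and ``3 + 5n`` integers
    (n > 1); values-only needs ``2n + 1`` floats and one integer.
    """
    if n <= 1:
        return (1, 1)
    if compute_vectors:
        return (1 + 6 * n + 2 * n * n, 3 + 5 * n)
    return (2 * n + 1, 1)


def syevd_inplace(
    a: np.ndarray,
    eigenvalues: np.ndarray,
    work: np.ndarray,
    iwork: np.ndarray,
    compute_vectors: bool = True,
) -> None:
    """Run ``?syevd`` in place on a symmetric matrix buffer.

    ``a`` is an n x n C-contiguous float32/float64 array (ndarray or memmap)
    holding the full symmetric matrix; on return its rows are the
    eigenvectors and ``eigenvalues`` holds λ in ascending order.  ``work``
    and ``iwork`` are caller-allocated scratch arrays at least as large as
    :func:`syevd_workspace_sizes` demands; ``work`` may be disk-backed.
    """
    n = a.shape[0]
    if a.shape != (n, n):
        raise ValueError(f"expected a square buffer, got {a.shape}")
    if not a.flags["C_CONTIGUOUS"]:
        raise ValueError("matrix buffer must be C-contiguous")
    dtype = a.dtype
    if dtype not in _SYEVD:
        raise ValueError(f"unsupported dtype {dtype}")
    if eigenvalues.dtype != dtype or eigenvalues.shape != (n,):
        raise ValueError("eigenvalue buffer must be length-n of matching dtype")
    min_work, min_iwork = syevd_workspace_sizes(n, compute_vectors)
    if work.size < min_work or work.dtype != dtype:
        raise ValueError(f"float workspace needs >= {min_work} {dtype} elements")
    if iwork.size < min_iwork or iwork.dtype != np.int32:
        raise ValueError(f"integer workspace needs >= {min_iwork} int32 elements")

    func = _SYEVD[dtype]
    fp = _c_double_p if dtype == np.float64 else _c_float_p
    n_c = ctypes.c_int(n)
    lwork = ctypes.c_int(int(work.size))
    liwork = ctypes.c_int(int(iwork.size))
    info = ctypes.c_int(0)
    jobz = b"V" if compute_vectors else b"N"
    func(
        jobz,
        b"L",
        ctypes.byref(n_c),
        a.ctypes.data_as(fp),
        ctypes.byref(n_c),
        eigenvalues.ctypes.data_as(fp),
        work.ctypes.data_as(fp),
        ctypes.byref(lwork),
        iwork.ctypes.data_as(_c_int_p),
        ctypes.byref(liwork),
        ctypes.byref(info),
    )
    if info.value != 0:
        raise ComputationError(f"syevd failed with info={info.value}")
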