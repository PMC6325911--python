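# Methods

## Scope and model

`diskfact` factorizes two kinds of dense matrices from statistical genomics:

* **GRM eigendecomposition.** A genomic relationship matrix K (N×N,
  symmetric, PSD up to sampling noise) is decomposed as K = Q·diag(λ)·Qᵀ by
  LAPACK's divide-and-conquer symmetric driver (`ssyevd`/`dsyevd`).
  Eigenvalues are returned ascending, eigenvector j paired with eigenvalue j.
* **Tall-matrix SVD.** An N×M genotype matrix A with N ≫ M is decomposed as
  A = U·diag(σ)·Vᵀ through the Gram matrix G = AᵀA: σ = √λ(G) (descending),
  V = eigenvectors of G, U = A·V·Σ⁻¹ rebuilt by streaming. Top-k selection
  truncates after the full Gram eigendecomposition; the Gram pass itself is
  always full-M, so requesting few singular values saves only the U pass.

The out-of-core contract is the package's central claim: in `disk` mode the
input copy, the eigenvector output and the solver's float workspace (the
~2N²-element scratch of the divide-and-conquer driver) are `np.memmap`
arrays backed by files, and the solver is invoked through LAPACK's
explicit-workspace interface (via `scipy.linalg.cython_lapack` function
pointers), so no hidden heap allocation of quadratic size occurs. Memory
and disk mode execute the identical LAPACK code on the identical bytes;
only the storage class of the buffers differs. The mode-equivalence test
asserts this (eigenvalues agree to ≤ 10·ε in the relative Euclidean norm;
in practice they are bit-identical).

## Storage format and tiling

Matrices are headerless raw IEEE-754 files, row-major, little-endian, with
dimensions supplied externally (as the CLI's positional `n`/`m`). A text
dialect (whitespace-separated values, one matrix row per line, scientific
notation accepted) is interconvertible with the binary form; text output
uses each precision's decimal round-trip digit count (9 single, 17 double),
so text→binary→text is lossless.

All streaming kernels iterate contiguous row tiles under an element budget.
Default budget: 64 Mi elements (256 MiB single / 512 MiB double) — small
against a desktop's memory while large enough to amortize I/O. Every
result is tile-budget-independent up to floating-point reassociation
(asserted ≤ 10·ε·‖A‖² for Gram accumulation).

## Numerical choices

* **Symmetry gate.** Eigendecomposition rejects inputs whose asymmetry
  exceeds 100·ε·max|A| (full check for matrices up to 2048², a fixed
  4096-pair sample above that) rather than silently symmetrizing; an
  explicit `--symmetrize` averages (A + Aᵀ)/2 tile-wise. Silent repair
  hides upstream bugs in GRM construction.
* **Gram accumulation precision.** G is accumulated in double even for
  single inputs (configurable). Squaring halves effective precision; with
  very many rows, single accumulation can lose small σ entirely.
  Accumulation is a rank-k update of the lower triangle (`syrk`), mirrored
  once, so G is exactly symmetric by construction.
* **Numerical rank.** The Gram route computes λ = σ², so an exactly zero
  singular value surfaces as λ ≈ ε·λ₁, i.e. σ ≈ √ε·σ₁ — a σ-space
  threshold of order ε·σ₁ could never trigger. The rank decision is
  therefore made in λ-space: λᵢ ≤ max(N,M)·ε·λ₁ is treated as zero, its σ
  reported as 0 and its U column zero-filled (flagged in
  `SVDResult.zero_columns`).
* **Accuracy trade-off of the Gram route.** Relative error in σᵢ behaves
  like ε·(σ₁/σᵢ)², versus ~ε for direct bidiagonalization. Genotype
  spectra are flat, so this is immaterial in the intended regime; it is
  the documented cost of making N ≫ M feasible out-of-core.
* **Sign convention.** Each V column is flipped so its largest-magnitude
  entry is positive; U inherits. Eigen/singular vector signs are
  mathematically arbitrary; fixing them makes outputs diffable. For
  comparisons between two factorizations, `align_signs` flips test columns
  whose inner product with the reference is negative — the 2-norm-optimal
  per-column choice.
* **Degenerate subspaces.** Per-column vector comparison marks columns
  whose paired values are equal within 1e-6 (relative) as
  "subspace-ambiguous": individual vectors in a repeated eigenvalue's
  eigenspace are not identifiable. The default scalar report compares the
  flattened sign-aligned matrix instead.
* **Boundary cases.** N = 1 returns the scalar as its eigenvalue with
  Q = [1]. Wide SVD inputs (N < M) are transposed to a scratch file and
  U/V swapped back, flagged `transposed`. Validated reads reject NaN/Inf;
  raw reads pass them through.

## Resource model

Peak memory of an in-memory eigendecomposition with vectors:

    n²·s + (1 + 6n + 2n²)·s + (3 + 5n)·4 bytes,   s = 4 (single) / 8 (double)

— the matrix plus the divide-and-conquer driver's documented minimum float
and integer workspace (the driver's own workspace query returns exactly
these sizes). Totals are quoted in GiB (2³⁰) rounded half-up to one
decimal; representative single-precision values: 1.1 GiB at N = 10,000,
10.1 at 30,000, 27.9 at 50,000, 111.8 at 100,000. Double precision doubles
the float components, leaving the integer workspace unchanged.

The SVD gram-route resident estimate is m²·s_acc + m·k·s + tile budget;
the dense-route model (2NM + M²)·s matrix/output + (4M² + 7M)·s + 8M·4
workspace is provided for comparison. Disk estimates sum input + outputs +
file-backed workspace per route; disk-mode runs are refused up-front when
the estimate exceeds free space on the workspace volume.

## Synthetic fixtures

The generator emulates the data the tool targets, at desk scale:

* **Genotypes:** entry (i,j) ~ Binomial(2, p_j), p_j ~ Uniform(0.05, 0.5)
  per marker — unrelated individuals in Hardy–Weinberg equilibrium across
  the commonly analyzed MAF range. Generation is chunked in fixed 1024-row
  blocks with per-block child seeds, so output is byte-identical for a
  given seed regardless of tile budget.
* **GRM:** VanRaden standardized, K = Z·Zᵀ/m with markers centered at 2p̂
  and scaled by √(2p̂(1−p̂)); monomorphic markers are dropped (logged).
  Symmetric PSD by construction, diagonal mean ≈ 1.
* **Symmetric families for comparisons:** `grm_like` (above, m = 2N),
  `wishart` (XXᵀ/2N, Marchenko–Pastur bulk with ratio 1/2), and
  `diag_plus_noise` (exact eigenvalues at zero noise).

What the fixtures do **not** model: linkage disequilibrium, population
structure, relatedness, missingness and genotyping error. Passing tests
demonstrate numerical correctness of the factorizations and the storage
contract on matrices with realistic spectra — not robustness to the
quality-control issues of real cohort data, which occur upstream of these
kernels.

## Precision agreement and its variability

Single-precision results are validated against double references with the
three relative norms (∞, taxicab, Euclidean; second argument normalizes).
On GRM fixtures (N = 1000, m = 2N, fixed seed) the single-vs-double
eigenvalue ∞-norm ratio is ≈ 4×10⁻⁷, and ≈ 2.5×10⁻⁶ at N = 10,000; across
seeds the constant fluctuates within roughly a factor of three, as
expected for a backward-stable solver where the bound's constant is
matrix-dependent. Published single-vs-reference agreement figures for
comparable problem sizes should therefore be read as order-of-magnitude
anchors, not sharp thresholds, when the test matrix is not identical. Two path-level facts matter when reproducing such
numbers: LAPACK's values-only path (`jobz='N'`) is roughly an order of
magnitude less accurate in single precision than the with-vectors
divide-and-conquer path, and NumPy's `eigvalsh` silently upcasts float32
input to double — so only an explicit single-precision LAPACK call
measures genuine single-precision accuracy.

## Problem sizes in the test suite

Unit and property tests run on matrices up to 500×500; oracle-equivalence
tests up to 200; the precision-agreement checks run the full pipeline at
N = 1000 and N = 10,000 (the latter dominates suite runtime at a few
minutes single-threaded). These sizes exercise every code path — tiling,
disk mode, both precisions — while keeping the suite fast; the kernels
themselves are size-oblivious.

## Known limitations

* No direct out-of-core bidiagonalization: wide matrices with both N and M
  beyond memory are out of scope (the Gram route requires M² resident).
* Selected-eigenpair drivers are deliberately not offered: their
  workspace-access pattern performs poorly against memory-mapped storage.
* The binary format is this package's own (headerless little-endian
  row-major); no PLINK/HDF5 dialects.
* Thread control (`--threads`, `DISKFACT_NUM_THREADS`, with
  `MKL_NUM_THREADS` honored as an alias) records and reports the effective
  count; the BLAS backend's own mechanism governs actual parallelism.
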