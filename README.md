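# diskfact

Out-of-core factorization of large genomic matrices: full eigendecomposition
of genomic relationship matrices (GRMs) and thin/top-k singular value
decomposition of tall genotype matrices, with the matrices — and the
eigensolver's workspace — living in memory-mapped files so the resident
memory footprint stays bounded regardless of matrix size.

## The problem

Biobank-scale cohorts produce N×N GRMs (pairwise genetic relatedness among N
individuals, typically K = Z·Zᵀ/m from column-standardized genotypes Z) and
N×M genotype dosage matrices with N in the hundreds of thousands. The
eigendecomposition K = Q·diag(λ)·Qᵀ underpins PCA, heritability estimation
and mixed-model association analysis, but a dense symmetric eigensolver with
eigenvectors needs the matrix *plus* about 2N² elements of scratch — an
N = 100,000 single-precision problem needs ≈ 112 GiB, far beyond a desktop.

`diskfact` keeps the matrix, the eigenvector output and the solver workspace
in disk-backed memory maps and lets the operating system page tiles in and
out, so the same LAPACK divide-and-conquer arithmetic runs with a bounded
resident footprint. For tall genotype matrices (N ≫ M) it computes the SVD
A = U·diag(σ)·Vᵀ through the Gram matrix G = AᵀA, accumulated in streaming
row tiles: only the M×M Gram matrix is ever resident, so N is limited by
disk, not memory. σ = √λ(G), V are the eigenvectors of G, and U = A·V·Σ⁻¹
is rebuilt in a second streaming pass.

## Worked example

```sh
# a seeded 500x500 synthetic GRM (VanRaden, from binomial dosages)
diskfact simulate grm 500 grm.bin --m 1000 --seed 7

# full eigendecomposition, double precision, disk-backed workspace
diskfact eigen double disk 500 grm.bin E.bin Q.bin

# how much memory would the in-memory route need at biobank scale?
diskfact estimate eigen 100000 --precision single
```

The last command prints:

```
route=eigen N=100000 M=- precision=single
memory: 111.8 GiB (120004400016 bytes)
disk:   149.0 GiB
```

i.e. an in-memory single-precision run at N = 100,000 would need 111.8 GiB
(matrix n²·s + workspace (1 + 6n + 2n²)·s + (3 + 5n) 4-byte integers,
s = 4), which is why the disk-backed mode exists: the same arrays land in
files (the 149 GiB disk figure: input + eigenvector output + file-backed
workspace + eigenvalue vector) while resident memory stays at the tile
budget.

From Python:

```python
import diskfact as df

grm = df.generate_symmetric(500, seed=7, kind="grm_like", out_path="grm.bin")
res = df.eigendecompose(grm, mode="disk")
print(res.eigenvalues[-5:])            # top of the spectrum, ascending order
print(df.check_reconstruction(grm, res))   # ‖A·Q − Q·Λ‖_F / ‖A‖_F, ~1e-15
```

Two runs of the same matrix (e.g. single vs double precision, or two tools)
are compared with the three relative agreement norms
‖x_test − x_ref‖_p / ‖x_ref‖_p for p ∈ {∞, 1, 2}:

```python
report = df.compare_vectors(single_eigenvalues, double_eigenvalues)
print(report.inf_norm, report.taxicab_norm, report.euclidean_norm)
```

See `docs/methods.md` for the numerical model, parameter defaults and known
trade-offs (notably the Gram route's loss of accuracy for σᵢ ≪ σ₁).

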