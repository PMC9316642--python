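"""Genotype QC, genetic relationship matrix, and GRM principal components.

The GRM is the standard allele-frequency-standardised estimator of realized
relatedness: off-diagonals average ``(x_ij - 2p_i)(x_ik - 2p_i) / 2p_i(1-p_i)``
over SNPs, the diagonal uses the variance-corrected form
``1 + (x^2 - (1+2p)x + 2p^2) / 2p(1-p)``, and missing genotypes are excluded
pairwise with per-pair SNP counts recorded.  Allele frequencies are estimated
in-sample from non-missing dosages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .simdata import GenotypeMatrix

__all__ = [
    "GRMResult",
    "QCReport",
    "qc_filter",
    "compute_grm",
    "grm_pca",
    "write_grm_gcta",
    "read_grm_gcta",
    "write_grm_tsv",
]


@dataclass
class GRMResult:
    matrix: np.ndarray  # n x n symmetric
    n_snps_used: np.ndarray  # n x n per-pair SNP counts
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.matrix, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("GRM must be square")
        if not np.allclose(a, a.T, atol=1e-12):
            raise ValueError("GRM must be symmetric")
        self.matrix = a

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def take(self, idx: np.ndarray) -> "GRMResult":
        """Subset samples, preserving order of ``idx``."""
        return GRMResult(
            matrix=self.matrix[np.ix_(idx, idx)],
            n_snps_used=self.n_snps_used[np.ix_(idx, idx)],
            sample_ids=self.sample_ids[idx],
        )


@dataclass
class QCReport:
    n_snps_in: int
    n_removed_maf: int
    n_removed_missing: int
    n_snps_out: int
    maf_min: float
    missing_max: float

    def __post_init__(self) -> None:
        if self.n_snps_out != self.n_snps_in - self.n_removed_maf - self.n_removed_missing:
            raise ValueError("QC counts do not add up")


def qc_filter(
    geno: GenotypeMatrix, maf_min: float = 0.01, missing_max: float = 0.05
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop SNPs by minor-allele frequency and missing rate.

    A SNP failing both rules is counted under the MAF rule only (rules applied
    in order, no double counting).
    """
    freq = geno.allele_freq
    maf = np.minimum(freq, 1.0 - freq)
    maf = np.where(np.isnan(maf), 0.0, maf)  # all-missing SNP: treat as MAF 0
    fail_maf = maf < maf_min
    fail_miss = (geno.missing_rate > missing_max) & ~fail_maf
    keep = ~(fail_maf | fail_miss)
    if not keep.any():
        raise ValueError("QC removed every SNP")
    report = QCReport(
        n_snps_in=geno.n_snps,
        n_removed_maf=int(fail_maf.sum()),
        n_removed_missing=int(fail_miss.sum()),
        n_snps_out=int(keep.sum()),
        maf_min=maf_min,
        missing_max=missing_max,
    )
    return geno.take_snps(np.flatnonzero(keep)), report


def compute_grm(geno: GenotypeMatrix, mean_impute: bool = False) -> GRMResult:
    """Allele-frequency-standardised GRM with pairwise missing exclusion.

    With ``mean_impute=True`` missing dosages are replaced by ``2p`` (their
    zero contribution) but per-pair counts still use the full SNP number —
    faster, slightly biased toward zero for pairs with missingness.
    """
    X = geno.dosages
    n, m = X.shape
    p = geno.allele_freq
    if np.any(np.isnan(p)) or np.any((p <= 0) | (p >= 1)):
        raise ValueError("every SNP must be polymorphic (0 < p < 1) after QC")
    denom = 2.0 * p * (1.0 - p)

    obs = ~np.isnan(X)
    Z = (np.where(obs, X, 2.0 * p) - 2.0 * p) / np.sqrt(denom)  # missing -> 0

    num = Z @ Z.T
    if mean_impute or obs.all():
        counts = np.full((n, n), m, dtype=float)
    else:
        counts = obs.astype(float) @ obs.astype(float).T
    if np.any(counts == 0):
        raise ValueError("some sample pair shares no non-missing SNP")
    A = num / counts

    # diagonal: 1 + mean over non-missing SNPs of (x^2 - (1+2p)x + 2p^2) / 2p(1-p)
    Xi = np.where(obs, X, 0.0)
    diag_terms = (Xi**2 - (1.0 + 2.0 * p) * Xi + 2.0 * p**2) / denom
    diag_terms = np.where(obs, diag_terms, 0.0)
    mj = obs.sum(axis=1).astype(float)
    np.fill_diagonal(A, 1.0 + diag_terms.sum(axis=1) / mj)
    np.fill_diagonal(counts, mj)

    return GRMResult(matrix=(A + A.T) / 2.0, n_snps_used=counts, sample_ids=geno.sample_ids)


def grm_pca(grm: GRMResult, k: int = 10) -> tuple[np.ndarray, np.ndarray, bool]:
    """Top-k principal components of the GRM.

    Returns ``(scores, eigenvalues, degenerate)`` where scores are the top-k
    eigenvectors scaled by sqrt(eigenvalue) with the deterministic sign
    convention that each component's largest-magnitude loading is positive.
    ``degenerate`` flags a spectrum with no structure (all eigenvalues equal).
    """
    if k >= grm.n:
        raise ValueError("k must be < number of samples")
    A = grm.matrix
    if not np.all(np.isfinite(A)):
        raise ValueError("non-finite GRM entries")
    vals, vecs = scipy.linalg.eigh(A)
    order = np.argsort(vals)[::-1][:k]
    lam = vals[order]
    V = vecs[:, order]
    for j in range(k):
        i = np.argmax(np.abs(V[:, j]))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
    scores = V * np.sqrt(np.clip(lam, 0.0, None))
    degenerate = bool(np.isclose(vals.max(), vals.min(), rtol=1e-10, atol=1e-12))
    return scores, lam, degenerate


# ---------------------------------------------------------------------------
# GCTA-compatible triple I/O
# ---------------------------------------------------------------------------


def _tri_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.tril_indices(n)


def write_grm_gcta(grm: GRMResult, prefix: str) -> None:
    """Write grm.bin / grm.N.bin (float32 lower triangle) and grm.id."""
    r, c = _tri_indices(grm.n)
    grm.matrix[r, c].astype("<f4").tofile(f"{prefix}.grm.bin")
    grm.n_snps_used[r, c].astype("<f4").tofile(f"{prefix}.grm.N.bin")
    with open(f"{prefix}.grm.id", "w") as f:
        for sid in grm.sample_ids:
            f.write(f"{sid}\t{sid}\n")


def read_grm_gcta(prefix: str) -> GRMResult:
    ids = pd.read_csv(f"{prefix}.grm.id", sep="\t", header=None)[1].to_numpy(dtype=str)
    n = len(ids)
    tri = np.fromfile(f"{prefix}.grm.bin", dtype="<f4").astype(float)
    tn = np.fromfile(f"{prefix}.grm.N.bin", dtype="<f4").astype(float)
    if tri.size != n * (n + 1) // 2:
        raise ValueError("grm.bin size inconsistent with grm.id")
    A = np.zeros((n, n))
    N = np.zeros((n, n))
    r, c = _tri_indices(n)
    A[r, c] = tri
    N[r, c] = tn
    A = A + np.tril(A, -1).T
    N = N + np.tril(N, -1).T
    return GRMResult(matrix=A, n_snps_used=N, sample_ids=ids)


def write_grm_tsv(grm: GRMResult, path: str) -> None:
    """Plain-text full matrix with sample ids as header and index."""
    pd.DataFrame(grm.matrix, index=grm.sample_ids, columns=grm.sample_ids).to_csv(
        path, sep="\t"
    )
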