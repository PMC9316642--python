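"""GWAS on trajectory parameters.

Per-SNP ordinary least squares of the (inverse-normal transformed) trajectory
parameter on allele dosage with covariate adjustment (sex, mean age, mean
height, PC1-PC10 by convention).  Covariates are projected out once and each
SNP tested by the Frisch-Waugh residual regression, which is algebraically
identical to the full per-SNP OLS fit and its t test on the dosage
coefficient.  Also provides the genomic inflation factor, Benjamini-Hochberg
FDR adjustment, and greedy distance/r^2 clumping of significant variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

from .simdata import GenotypeMatrix

__all__ = [
    "GwasSummary",
    "run_gwas",
    "genomic_lambda",
    "fdr_adjust",
    "clump",
    "qq_manhattan_export",
]

GENOME_WIDE_ALPHA = 5e-8
_CHI2_1_MEDIAN = float(chi2.median(1))


@dataclass
class GwasSummary:
    """Per-SNP association rows plus genome-wide diagnostics."""

    rows: pd.DataFrame  # snp_id chrom pos allele_freq beta se t_stat p_value q_value n
    lambda_gc: float
    n_signif_gw: int
    alpha: float = GENOME_WIDE_ALPHA
    clumps: list[tuple[str, list[str]]] = field(default_factory=list)


def run_gwas(
    pheno: np.ndarray,
    geno: GenotypeMatrix,
    covars: np.ndarray,
    missing: str = "mean_impute",
) -> GwasSummary:
    """Per-SNP linear association with covariate adjustment.

    ``covars`` must not include an intercept column of ones twice; one is
    added here.  Missing dosages are mean-imputed per SNP by default
    (``missing='complete_case'`` refits each affected SNP on its observed
    rows).  Monomorphic SNPs are emitted with NaN statistics; a SNP collinear
    with the covariates raises.
    """
    y = np.asarray(pheno, dtype=float)
    C = np.atleast_2d(np.asarray(covars, dtype=float))
    n = y.size
    if C.shape[0] != n or geno.n_samples != n:
        raise ValueError("pheno, genotypes and covariates must align on samples")
    ok = np.isfinite(y) & np.all(np.isfinite(C), axis=1)
    y, C = y[ok], C[ok]
    G = geno.dosages[ok]
    n = y.size
    X = np.column_stack([np.ones(n), C])
    p_cov = X.shape[1]
    if np.linalg.matrix_rank(X) < p_cov:
        raise ValueError("collinear covariates")
    q, _ = np.linalg.qr(X)

    snp_var = np.nanvar(G, axis=0)
    mono = ~(snp_var > 0)

    col_mean = np.nanmean(np.where(mono[None, :], 0.0, G), axis=0)
    Gf = np.where(np.isnan(G), col_mean[None, :], G)

    yr = y - q @ (q.T @ y)
    Gr = Gf - q @ (q.T @ Gf)
    sxx = np.einsum("ij,ij->j", Gr, Gr)
    syy = float(yr @ yr)
    sxy = Gr.T @ yr

    bad_collinear = (~mono) & (sxx < 1e-10 * n * np.maximum(snp_var, 1e-300))
    if bad_collinear.any():
        which = geno.snp_ids[bad_collinear][:5]
        raise ValueError(f"SNP(s) collinear with covariates: {list(which)}")

    df = n - p_cov - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        rss = syy - beta * sxy
        se = np.sqrt(np.maximum(rss, 0.0) / df / sxx)
        tstat = beta / se
    pvals = 2.0 * t_dist.sf(np.abs(tstat), df)
    n_per_snp = np.full(geno.n_snps, n)

    if missing == "complete_case":
        for j in np.flatnonzero(np.isnan(G).any(axis=0) & ~mono):
            obs = ~np.isnan(G[:, j])
            nj = int(obs.sum())
            Xj = np.column_stack([X[obs], G[obs, j]])
            coef, *_ = np.linalg.lstsq(Xj, y[obs], rcond=None)
            r = y[obs] - Xj @ coef
            dfj = nj - Xj.shape[1]
            xtx_inv = np.linalg.inv(Xj.T @ Xj)
            sej = np.sqrt(float(r @ r) / dfj * xtx_inv[-1, -1])
            beta[j], se[j] = coef[-1], sej
            tstat[j] = coef[-1] / sej
            pvals[j] = 2.0 * float(t_dist.sf(abs(tstat[j]), dfj))
            n_per_snp[j] = nj
    elif missing != "mean_impute":
        raise ValueError("missing must be 'mean_impute' or 'complete_case'")

    for arr in (beta, se, tstat, pvals):
        arr[mono] = np.nan

    rows = pd.DataFrame(
        {
            "snp_id": geno.snp_ids,
            "chrom": geno.chrom,
            "pos": geno.pos,
            "a1": geno.ref_alt[:, 1],  # effect (alt) allele, counted by dosage
            "a2": geno.ref_alt[:, 0],
            "allele_freq": geno.allele_freq,
            "beta": beta,
            "se": se,
            "t_stat": tstat,
            "p_value": pvals,
            "n": n_per_snp,
        }
    )
    finite_p = rows["p_value"].dropna().to_numpy()
    lam = genomic_lambda(finite_p) if finite_p.size >= 100 else float("nan")
    q_values = np.full(len(rows), np.nan)
    if finite_p.size:
        q_values[rows["p_value"].notna().to_numpy()] = fdr_adjust(finite_p)
    rows["q_value"] = q_values
    n_sig = int((rows["p_value"] < GENOME_WIDE_ALPHA).sum())
    return GwasSummary(rows=rows, lambda_gc=lam, n_signif_gw=n_sig)


def genomic_lambda(p_values: np.ndarray) -> float:
    """Genomic inflation: median association chi-square over its null median."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size < 100:
        raise ValueError("need at least 100 p-values for a stable median")
    stats = chi2.isf(p, 1)
    return float(np.median(stats) / _CHI2_1_MEDIAN)


def fdr_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, q >= p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def clump(
    summary: GwasSummary,
    geno: GenotypeMatrix,
    p_index_max: float = GENOME_WIDE_ALPHA,
    window_kb: float = 250.0,
    r2_min: float = 0.1,
) -> list[tuple[str, list[str]]]:
    """Greedy clumping of significant SNPs by distance and dosage r^2.

    Repeatedly takes the smallest-p unassigned SNP below ``p_index_max`` as an
    index variant and absorbs unassigned SNPs on the same chromosome within
    ``window_kb`` whose squared dosage correlation with the index is at least
    ``r2_min``.  Returns (index SNP, members including the index) pairs and
    stores them on ``summary.clumps``.
    """
    rows = summary.rows
    id_to_col = {s: i for i, s in enumerate(geno.snp_ids)}
    order = rows[rows["p_value"] < p_index_max].sort_values("p_value")
    assigned: set[str] = set()
    clumps: list[tuple[str, list[str]]] = []
    window = window_kb * 1000.0

    G = geno.dosages
    col_mean = np.nanmean(G, axis=0)
    Gc = np.where(np.isnan(G), col_mean[None, :], G) - col_mean[None, :]
    norms = np.sqrt(np.einsum("ij,ij->j", Gc, Gc))

    for _, idx_row in order.iterrows():
        sid = idx_row["snp_id"]
        if sid in assigned:
            continue
        assigned.add(sid)
        members = [sid]
        jc = id_to_col[sid]
        near = rows[
            (rows["chrom"] == idx_row["chrom"])
            & ((rows["pos"] - idx_row["pos"]).abs() <= window)
            & (~rows["snp_id"].isin(assigned))
        ]
        if len(near):
            cols = near["snp_id"].map(id_to_col).to_numpy()
            with np.errstate(invalid="ignore"):
                r = (Gc[:, cols].T @ Gc[:, jc]) / (norms[cols] * norms[jc])
            hit = near["snp_id"].to_numpy()[np.nan_to_num(r**2) >= r2_min]
            for h in hit:
                assigned.add(h)
                members.append(h)
        clumps.append((sid, members))
    summary.clumps = clumps
    return clumps


def qq_manhattan_export(summary: GwasSummary) -> pd.DataFrame:
    """Sorted -log10 p with uniform expected quantiles and cumulative positions.

    One row per tested SNP, suitable for external QQ / Manhattan plotting.
    """
    rows = summary.rows.dropna(subset=["p_value"]).copy()
    rows = rows.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    offset = 0.0
    cum = np.empty(len(rows))
    for _, grp in rows.groupby("chrom", sort=False):
        cum[grp.index] = grp["pos"].to_numpy() + offset
        offset = cum[grp.index].max()
    rows["cum_pos"] = cum
    rows["neglog10_p"] = -np.log10(rows["p_value"])
    ranks = rows["p_value"].rank(method="first")
    m = len(rows)
    rows["expected_neglog10_p"] = -np.log10(ranks / (m + 1.0))
    return rows
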