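import numpy as np
import pytest

from longherit import SimTruth, compute_grm, simulate_cohort, simulate_genotypes


@pytest.fixture(scope="session")
def small_truth():
    return SimTruth(n_subjects=300, n_snps=400, seed=42)


@pytest.fixture(scope="session")
def small_sim(small_truth):
    """(geno, cohort, truth_df) for a 300-subject, 400-SNP cohort."""
    geno = simulate_genotypes(small_truth)
    cohort, truth_df = simulate_cohort(small_truth, geno)
    return geno, cohort, truth_df


@pytest.fixture(scope="session")
def small_grm(small_sim):
    geno, _, _ = small_sim
    return compute_grm(geno)


@pytest.fixture(scope="session")
def medium_sim():
    """n=1000, M=1000 cohort with nonzero heritabilities, no dropout."""
    truth = SimTruth(
        n_subjects=1000, n_snps=1000, h0_sq=0.30, h1_sq=0.15, rho_g=0.6,
        dropout_prob=0.0, seed=2024,
    )
    geno = simulate_genotypes(truth)
    cohort, truth_df = simulate_cohort(truth, geno)
    return truth, geno, cohort, truth_df


def wls_oracle(x, y, w):
    """Independent weighted-least-squares solve of y on (1, x) by normal equations."""
    X = np.column_stack([np.ones_like(x), x])
    A = X.T @ (w[:, None] * X)
    b = X.T @ (w * y)
    return np.linalg.solve(A, b)


def reml_loglik_oracle(y, X, A, sg2, se2):
    """Restricted Gaussian log-likelihood at (sg2, se2), by direct dense algebra.

    Uses an explicit eigendecomposition of V (the realized-relatedness matrix
    can have small negative eigenvalues, so V must be checked for positive
    definiteness eigenvalue by eigenvalue) -- shares no code with the AI-REML
    fitting path.
    """
    n = y.size
    V = sg2 * A + se2 * np.eye(n)
    vals, vecs = np.linalg.eigh(V)
    if vals.min() <= 0:
        return -np.inf
    logdetV = float(np.sum(np.log(vals)))
    Vinv = (vecs / vals) @ vecs.T
    XtVX = X.T @ Vinv @ X
    sign2, logdetX = np.linalg.slogdet(XtVX)
    if sign2 <= 0:
        return -np.inf
    beta = np.linalg.solve(XtVX, X.T @ Vinv @ y)
    r = y - X @ beta
    return -0.5 * (logdetV + logdetX + float(r @ Vinv @ r))
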