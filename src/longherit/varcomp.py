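"""GRM-based REML variance components.

Implements restricted maximum likelihood for Gaussian mixed models whose
covariance is a linear combination of known matrices:

* univariate:  V = sigma_g^2 A + sigma_e^2 I  (SNP heritability),
* bivariate:   2n-dimensional model with genetic covariance structure
  [[sg0, sg01], [sg01, sg1]] (x) A and residual [[se0, se01], [se01, se1]]
  (x) I, giving the genetic correlation between two traits,
* G x E:       V = sigma_g^2 A + sigma_gxe^2 K + sigma_e^2 I with
  K_jk = A_jk when samples j, k share the exposure group and 0 otherwise
  (diagonal kept), the SNP-by-exposure interaction variance.

Maximisation uses average-information (AI) Newton steps with step-halving and
an expectation-maximisation fallback, so the restricted log-likelihood never
decreases across accepted iterations.  Variance components are constrained
non-negative by projection to a small positive floor; covariance components
are kept inside the positive-semidefinite cone of their 2x2 block.  Standard
errors of ratio quantities (h^2, rho_g) come from the inverse AI matrix by the
first-order delta method.  Null hypotheses on a variance component sit on the
boundary of the parameter space, so their likelihood-ratio test uses the
50:50 mixture of a point mass at zero and chi-square(1); the genetic
covariance is an interior parameter and uses a plain chi-square(1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.stats import chi2

from .grm import GRMResult

__all__ = [
    "UnivariateComponents",
    "BivariateComponents",
    "GxEComponents",
    "fit_univariate_greml",
    "fit_bivariate_greml",
    "fit_gxe_greml",
    "derived_quantities",
    "lrt_pvalue",
]


# ---------------------------------------------------------------------------
# generic dense REML engine
# ---------------------------------------------------------------------------


@dataclass
class _REMLFit:
    params: np.ndarray
    logL: float
    ai: np.ndarray
    ai_inv: np.ndarray | None
    singular_ai: bool
    converged: bool
    n_iter: int


class _REMLState:
    """Quantities at one parameter point: logL, P y, scores, AI matrix."""

    __slots__ = ("logL", "Py", "score", "ai", "tr_PA")

    def __init__(self, y, X, mats, theta):
        n = y.size
        V = np.zeros((n, n))
        for t, A in zip(theta, mats):
            V += t * A
        c, low = scipy.linalg.cho_factor(V, lower=True, check_finite=False)
        logdetV = 2.0 * np.sum(np.log(np.diag(c)))
        Vinv = scipy.linalg.cho_solve((c, low), np.eye(n), check_finite=False)
        W = Vinv @ X
        XtVX = X.T @ W
        cx, lowx = scipy.linalg.cho_factor(XtVX, lower=True)
        logdetX = 2.0 * np.sum(np.log(np.diag(cx)))
        P = Vinv - W @ scipy.linalg.cho_solve((cx, lowx), W.T)
        Py = P @ y
        self.logL = -0.5 * (logdetV + logdetX + float(y @ Py))
        self.Py = Py
        k = len(mats)
        U = np.empty((n, k))
        self.tr_PA = np.empty(k)
        for i, A in enumerate(mats):
            U[:, i] = A @ Py
            self.tr_PA[i] = float(np.sum(P * A))  # tr(P A), both symmetric
        yPAPy = U.T @ Py
        self.score = 0.5 * (yPAPy - self.tr_PA)
        T = P @ U
        self.ai = 0.5 * (U.T @ T)


def _feasible(theta: np.ndarray, var_idx, cov_blocks, floor: float) -> np.ndarray:
    """Project variances to >= floor, covariances into their PSD block."""
    th = theta.copy()
    for i in var_idx:
        th[i] = max(th[i], floor)
    for (i0, ic, i1) in cov_blocks:
        bound = 0.999 * np.sqrt(th[i0] * th[i1])
        th[ic] = np.clip(th[ic], -bound, bound)
    return th


def _reml_maximize(
    y: np.ndarray,
    X: np.ndarray,
    mats: list[np.ndarray],
    init: np.ndarray,
    var_idx: list[int],
    cov_blocks: list[tuple[int, int, int]] = (),
    tol: float = 1e-6,
    max_iter: int = 100,
) -> _REMLFit:
    """AI-REML with step-halving and EM fallback for V = sum(theta_k mats_k)."""
    vary = float(np.var(y))
    floor = 1e-8 * max(vary, 1e-12)
    n = y.size
    theta = _feasible(np.asarray(init, dtype=float), var_idx, cov_blocks, floor)
    state = _REMLState(y, X, mats, theta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # Newton direction from the average-information matrix (ridge if needed)
        ai = state.ai
        try:
            delta = np.linalg.solve(ai + 1e-12 * np.eye(len(mats)), state.score)
        except np.linalg.LinAlgError:
            delta = state.score / max(np.max(np.diag(ai)), 1.0)

        new_state = None
        new_theta = theta
        step = 1.0
        for _ in range(30):
            cand = _feasible(theta + step * delta, var_idx, cov_blocks, floor)
            try:
                cs = _REMLState(y, X, mats, cand)
            except (np.linalg.LinAlgError, scipy.linalg.LinAlgError):
                step *= 0.5
                continue
            if cs.logL >= state.logL - 1e-12:
                new_state, new_theta = cs, cand
                break
            step *= 0.5
        if new_state is None:
            # EM-flavoured fallback: guaranteed-ascent direction for variances
            em = theta.copy()
            for i in var_idx:
                em[i] = theta[i] + (theta[i] ** 2 / n) * 2.0 * state.score[i]
            for (_, ic, _) in cov_blocks:
                em[ic] = theta[ic] + (abs(theta[ic]) + floor) ** 2 / n * 2.0 * state.score[ic]
            em = _feasible(em, var_idx, cov_blocks, floor)
            try:
                cs = _REMLState(y, X, mats, em)
                if cs.logL >= state.logL - 1e-12:
                    new_state, new_theta = cs, em
            except (np.linalg.LinAlgError, scipy.linalg.LinAlgError):
                pass
        if new_state is None:
            # no ascent possible from here: treat as converged at theta
            converged = True
            break
        dlog = new_state.logL - state.logL
        rel = np.max(
            np.abs(new_theta - theta) / np.maximum(np.abs(theta), floor * 1e4 + 1e-12)
        )
        theta, state = new_theta, new_state
        if dlog < tol and rel < 10.0 * tol:
            converged = True
            break

    ai = state.ai
    sing = False
    ai_inv: np.ndarray | None
    try:
        cond = np.linalg.cond(ai)
        if not np.isfinite(cond) or cond > 1e10:
            sing = True
        ai_inv = np.linalg.inv(ai)
    except np.linalg.LinAlgError:
        sing, ai_inv = True, None
    if not converged:
        warnings.warn(
            f"REML did not converge in {max_iter} iterations", stacklevel=2
        )
    return _REMLFit(
        params=theta,
        logL=state.logL,
        ai=ai,
        ai_inv=ai_inv,
        singular_ai=sing,
        converged=converged,
        n_iter=it,
    )


def _null_logL(y: np.ndarray, X: np.ndarray) -> float:
    """Closed-form restricted logL of the residual-only model V = s2 I."""
    n, p = X.shape
    q, r = np.linalg.qr(X)
    resid = y - q @ (q.T @ y)
    rss = float(resid @ resid)
    s2 = rss / (n - p)
    logdet_xtx = 2.0 * np.sum(np.log(np.abs(np.diag(r))))
    return -0.5 * ((n - p) * np.log(s2) + logdet_xtx + (n - p))


def _complete_cases(y_list: list[np.ndarray], X: np.ndarray) -> np.ndarray:
    ok = np.all(np.isfinite(X), axis=1)
    for y in y_list:
        ok &= np.isfinite(y)
    return ok


def lrt_pvalue(logL_full: float, logL_reduced: float, null_kind: str) -> float:
    """Likelihood-ratio p-value; boundary nulls use the 50:50 chi2(0):chi2(1) mix."""
    lam = 2.0 * (logL_full - logL_reduced)
    if lam < -1e-6:
        raise ValueError(f"full-model logL below reduced-model logL (LRT = {lam:.3g})")
    lam = max(lam, 0.0)
    if null_kind == "boundary_mixture":
        return 1.0 if lam == 0.0 else 0.5 * float(chi2.sf(lam, 1))
    if null_kind == "chi2_1":
        return float(chi2.sf(lam, 1))
    raise ValueError(f"unknown null_kind {null_kind!r}")


# ---------------------------------------------------------------------------
# univariate heritability
# ---------------------------------------------------------------------------


@dataclass
class UnivariateComponents:
    sigma_g2: float
    sigma_e2: float
    h2: float
    se_h2: float
    logL: float
    logL_null: float
    lrt: float
    p_value: float
    n_used: int
    converged: bool
    n_iter: int
    ai_singular: bool = False

    def __post_init__(self) -> None:
        if self.sigma_g2 < 0 or self.sigma_e2 < 0:
            raise ValueError("variance components must be non-negative")


def fit_univariate_greml(
    y: np.ndarray,
    X: np.ndarray,
    grm: GRMResult,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> UnivariateComponents:
    """SNP heritability by AI-REML under V = A sigma_g^2 + I sigma_e^2.

    Rows with missing phenotype or covariates are dropped (counted in
    ``n_used``).  The p-value tests sigma_g^2 = 0 by LRT against the
    boundary-mixture null.  A near-singular AI matrix (e.g. A with no
    off-diagonal structure, leaving the two components unidentifiable) is
    flagged via ``ai_singular``.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size or grm.n != y.size:
        raise ValueError("y, X and GRM must align on samples")
    ok = _complete_cases([y], X)
    y, X = y[ok], X[ok]
    A = grm.matrix[np.ix_(np.flatnonzero(ok), np.flatnonzero(ok))]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design X is rank deficient")
    n = y.size
    vary = float(np.var(y, ddof=1))
    init = np.array([0.5 * vary, 0.5 * vary])
    fit = _reml_maximize(
        y, X, [A, np.eye(n)], init, var_idx=[0, 1], tol=tol, max_iter=max_iter
    )
    sg, se = fit.params
    h2 = sg / (sg + se)
    if fit.ai_inv is not None and not fit.singular_ai:
        g = np.array([se, -sg]) / (sg + se) ** 2
        se_h2 = float(np.sqrt(max(g @ fit.ai_inv @ g, 0.0)))
    else:
        se_h2 = float("nan")
    logL0 = _null_logL(y, X)
    lam = max(2.0 * (fit.logL - logL0), 0.0)
    p = lrt_pvalue(fit.logL, min(logL0, fit.logL), "boundary_mixture")
    return UnivariateComponents(
        sigma_g2=float(sg),
        sigma_e2=float(se),
        h2=float(h2),
        se_h2=se_h2,
        logL=fit.logL,
        logL_null=logL0,
        lrt=lam,
        p_value=p,
        n_used=n,
        converged=fit.converged,
        n_iter=fit.n_iter,
        ai_singular=fit.singular_ai,
    )


# ---------------------------------------------------------------------------
# bivariate genetic correlation
# ---------------------------------------------------------------------------


@dataclass
class BivariateComponents:
    sigma_g0_2: float
    sigma_g1_2: float
    sigma_g01: float
    rho_g: float
    se_rho_g: float
    p_rho_g: float
    sigma_e0_2: float
    sigma_e1_2: float
    sigma_e01: float
    rho_e: float
    se_rho_e: float
    logL: float
    logL_rg0: float
    n_used: int
    converged: bool
    ai_singular: bool = False


def _bivar_mats(A: np.ndarray) -> list[np.ndarray]:
    n = A.shape[0]
    I = np.eye(n)
    Z = np.zeros((n, n))

    def blk(tl, tr, br):
        return np.block([[tl, tr], [tr, br]])

    return [
        blk(A, Z, Z),  # sigma_g0^2
        blk(Z, A, Z),  # sigma_g01
        blk(Z, Z, A),  # sigma_g1^2
        blk(I, Z, Z),  # sigma_e0^2
        blk(Z, I, Z),  # sigma_e01
        blk(Z, Z, I),  # sigma_e1^2
    ]


def fit_bivariate_greml(
    y0: np.ndarray,
    y1: np.ndarray,
    X: np.ndarray,
    grm: GRMResult,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> BivariateComponents:
    """Bivariate GREML: genetic and residual correlation between two traits.

    The stacked 2n model has covariance
    ``[[sg0 A + se0 I, sg01 A + se01 I], [sg01 A + se01 I, sg1 A + se1 I]]``
    with the same fixed-effect design applied to each trait.  Parameterised in
    covariances (not correlations) so the likelihood stays smooth at
    rho -> +/-1; ``rho_g`` is derived, its SE by the delta method and its
    p-value by LRT against the fit with the genetic covariance fixed at 0
    (interior parameter: plain chi-square(1)).
    """
    y0 = np.asarray(y0, dtype=float)
    y1 = np.asarray(y1, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not (y0.size == y1.size == X.shape[0] == grm.n):
        raise ValueError("y0, y1, X and GRM must align on samples")
    ok = _complete_cases([y0, y1], X)
    idx = np.flatnonzero(ok)
    y0, y1, X = y0[idx], y1[idx], X[idx]
    A = grm.matrix[np.ix_(idx, idx)]
    n = y0.size
    yy = np.concatenate([y0, y1])
    XX = scipy.linalg.block_diag(X, X)
    mats = _bivar_mats(A)

    # warm start from the univariate fits plus a damped phenotypic covariance
    v0, v1 = float(np.var(y0, ddof=1)), float(np.var(y1, ddof=1))
    c01 = float(np.cov(y0, y1)[0, 1])
    init = np.array([0.5 * v0, 0.25 * c01, 0.5 * v1, 0.5 * v0, 0.25 * c01, 0.5 * v1])
    cov_blocks = [(0, 1, 2), (3, 4, 5)]
    fit = _reml_maximize(
        yy, XX, mats, init, var_idx=[0, 2, 3, 5], cov_blocks=cov_blocks,
        tol=tol, max_iter=max_iter,
    )
    sg0, sg01, sg1, se0, se01, se1 = fit.params
    rho_g = sg01 / np.sqrt(sg0 * sg1)
    rho_e = se01 / np.sqrt(se0 * se1)

    def _rho_se(i0, ic, i1, v0_, c_, v1_):
        if fit.ai_inv is None:
            return float("nan")
        r = c_ / np.sqrt(v0_ * v1_)
        g = np.zeros(6)
        g[i0] = -0.5 * r / v0_
        g[ic] = 1.0 / np.sqrt(v0_ * v1_)
        g[i1] = -0.5 * r / v1_
        return float(np.sqrt(max(g @ fit.ai_inv @ g, 0.0)))

    se_rho_g = _rho_se(0, 1, 2, sg0, sg01, sg1)
    se_rho_e = _rho_se(3, 4, 5, se0, se01, se1)

    # constrained fit: genetic covariance fixed at zero
    mats0 = [mats[0], mats[2], mats[3], mats[4], mats[5]]
    init0 = np.array([sg0, sg1, se0, se01, se1])
    fit0 = _reml_maximize(
        yy, XX, mats0, init0, var_idx=[0, 1, 2, 4], cov_blocks=[(2, 3, 4)],
        tol=tol, max_iter=max_iter,
    )
    if not fit0.converged:
        warnings.warn("constrained (rho_g = 0) refit did not converge", stacklevel=2)
    p_rho = lrt_pvalue(max(fit.logL, fit0.logL), fit0.logL, "chi2_1")
    return BivariateComponents(
        sigma_g0_2=float(sg0),
        sigma_g1_2=float(sg1),
        sigma_g01=float(sg01),
        rho_g=float(rho_g),
        se_rho_g=se_rho_g,
        p_rho_g=p_rho,
        sigma_e0_2=float(se0),
        sigma_e1_2=float(se1),
        sigma_e01=float(se01),
        rho_e=float(rho_e),
        se_rho_e=se_rho_e,
        logL=fit.logL,
        logL_rg0=fit0.logL,
        n_used=n,
        converged=fit.converged,
        ai_singular=fit.singular_ai,
    )


# ---------------------------------------------------------------------------
# SNP-by-exposure interaction
# ---------------------------------------------------------------------------


@dataclass
class GxEComponents:
    sigma_g2: float
    sigma_gxe2: float
    sigma_e2: float
    h_gxe2: float
    se_h_gxe2: float
    logL: float
    logL_null: float
    lrt: float
    p_value: float
    n_used: int
    converged: bool
    ai_singular: bool = False


def fit_gxe_greml(
    y: np.ndarray,
    X: np.ndarray,
    grm: GRMResult,
    env: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> GxEComponents:
    """SNP-by-environment interaction variance under V = A sg + K sgxe + I se.

    ``K`` equals the GRM within exposure groups and zero across them (diagonal
    kept), so sigma_gxe^2 captures genetic variance whose effect differs by
    exposure.  The exposure main effect must be included in ``X`` by the
    caller; samples with missing exposure are dropped.  The p-value tests
    sigma_gxe^2 = 0 with the boundary-mixture LRT.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    env = np.asarray(env, dtype=float)
    if not (y.size == X.shape[0] == env.size == grm.n):
        raise ValueError("y, X, env and GRM must align on samples")
    ok = _complete_cases([y, env], X)
    idx = np.flatnonzero(ok)
    y, X, env = y[idx], X[idx], env[idx]
    if np.unique(env).size < 2:
        raise ValueError("exposure is constant: K = A and sigma_gxe^2 is unidentifiable")
    A = grm.matrix[np.ix_(idx, idx)]
    same = env[:, None] == env[None, :]
    K = np.where(same, A, 0.0)
    np.fill_diagonal(K, np.diag(A))
    n = y.size
    vary = float(np.var(y, ddof=1))
    init = np.array([vary / 3.0, vary / 3.0, vary / 3.0])
    fit = _reml_maximize(
        y, X, [A, K, np.eye(n)], init, var_idx=[0, 1, 2], tol=tol, max_iter=max_iter
    )
    sg, sgxe, se = fit.params
    tot = sg + sgxe + se
    h_gxe2 = sgxe / tot
    if fit.ai_inv is not None and not fit.singular_ai:
        g = np.array([-sgxe, tot - sgxe, -sgxe]) / tot**2
        se_h = float(np.sqrt(max(g @ fit.ai_inv @ g, 0.0)))
    else:
        se_h = float("nan")
    # null: no interaction component
    fit0 = _reml_maximize(
        y, X, [A, np.eye(n)], np.array([0.5 * vary, 0.5 * vary]),
        var_idx=[0, 1], tol=tol, max_iter=max_iter,
    )
    lam = max(2.0 * (fit.logL - fit0.logL), 0.0)
    p = lrt_pvalue(max(fit.logL, fit0.logL), fit0.logL, "boundary_mixture")
    return GxEComponents(
        sigma_g2=float(sg),
        sigma_gxe2=float(sgxe),
        sigma_e2=float(se),
        h_gxe2=float(h_gxe2),
        se_h_gxe2=se_h,
        logL=fit.logL,
        logL_null=fit0.logL,
        lrt=lam,
        p_value=p,
        n_used=n,
        converged=fit.converged,
        ai_singular=fit.singular_ai,
    )


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------


def derived_quantities(b: BivariateComponents) -> tuple[float, float]:
    """Genetic covariance and the slope's genetic variance conditional on the level.

    Returns ``(sqrt(sg0^2 * sg1^2) * rho_g, sg1^2 * (1 - rho_g^2))``: the
    first is the genetic covariance between the two trajectory parameters, the
    second the genetic variance of the annual change rate that remains once
    the genetic effect on the subject-specific mean is held fixed.
    """
    if b.sigma_g0_2 <= 0 or b.sigma_g1_2 <= 0:
        raise ValueError("genetic variances must be positive")
    cov = float(np.sqrt(b.sigma_g0_2 * b.sigma_g1_2) * b.rho_g)
    cond = float(b.sigma_g1_2 * (1.0 - b.rho_g**2))
    return cov, cond
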