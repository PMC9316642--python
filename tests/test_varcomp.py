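import numpy as np
import pytest

from longherit import (
    SimTruth,
    compute_grm,
    derived_quantities,
    fit_bivariate_greml,
    fit_gxe_greml,
    fit_univariate_greml,
    lrt_pvalue,
    simulate_cohort,
    simulate_genotypes,
)
from longherit.grm import GRMResult
from longherit.varcomp import BivariateComponents, _reml_maximize

from conftest import reml_loglik_oracle


def _sim_grm_pheno(n, m, h2, seed):
    """Genotypes, GRM and a phenotype with heritability h2 (no cohort layer)."""
    t = SimTruth(n_subjects=n, n_snps=m, h0_sq=h2, seed=seed)
    geno = simulate_genotypes(t)
    _, truth = simulate_cohort(t, geno)
    return geno, compute_grm(geno), truth["beta0"].to_numpy()


class TestUnivariate:
    def test_optimum_dominates_grid_oracle(self):
        # brute-force 50x50 grid over (sigma_g^2, sigma_e^2) using an
        # independently coded restricted likelihood
        geno, grm, y = _sim_grm_pheno(150, 200, 0.5, seed=41)
        X = np.ones((150, 1))
        fit = fit_univariate_greml(y, X, grm)
        vy = np.var(y, ddof=1)
        grid = np.linspace(0.02, 2.0, 50) * vy
        best, arg = -np.inf, None
        for sg in grid:
            for se in grid:
                ll = reml_loglik_oracle(y, X, grm.matrix, sg, se)
                if ll > best:
                    best, arg = ll, (sg, se)
        assert fit.logL >= best - 1e-6
        cell = grid[1] - grid[0]
        assert abs(fit.sigma_g2 - arg[0]) <= cell
        assert abs(fit.sigma_e2 - arg[1]) <= cell

    def test_identity_kinship_flagged_unidentifiable(self):
        rng = np.random.default_rng(1)
        n = 120
        grm = GRMResult(
            matrix=np.eye(n), n_snps_used=np.full((n, n), 10.0),
            sample_ids=np.array([f"i{i}" for i in range(n)]),
        )
        fit = fit_univariate_greml(rng.normal(size=n), np.ones((n, 1)), grm)
        assert fit.ai_singular

    def test_reordering_invariance(self):
        geno, grm, y = _sim_grm_pheno(200, 300, 0.4, seed=42)
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(200), rng.normal(size=200)])
        fit = fit_univariate_greml(y, X, grm)
        perm = rng.permutation(200)
        grm_p = GRMResult(
            matrix=grm.matrix[np.ix_(perm, perm)],
            n_snps_used=grm.n_snps_used[np.ix_(perm, perm)],
            sample_ids=grm.sample_ids[perm],
        )
        fit_p = fit_univariate_greml(y[perm], X[perm], grm_p)
        assert fit_p.h2 == pytest.approx(fit.h2, abs=1e-6)
        assert fit_p.logL == pytest.approx(fit.logL, abs=1e-5)

    def test_scale_invariance_of_h2(self):
        geno, grm, y = _sim_grm_pheno(200, 300, 0.4, seed=43)
        X = np.ones((200, 1))
        fit1 = fit_univariate_greml(y, X, grm)
        fit3 = fit_univariate_greml(3.0 * y, X, grm)
        assert fit3.h2 == pytest.approx(fit1.h2, abs=1e-6)
        assert fit3.sigma_g2 == pytest.approx(9.0 * fit1.sigma_g2, rel=1e-4)

    def test_missing_rows_dropped(self):
        geno, grm, y = _sim_grm_pheno(200, 300, 0.4, seed=44)
        y2 = y.copy()
        y2[:10] = np.nan
        fit = fit_univariate_greml(y2, np.ones((200, 1)), grm)
        assert fit.n_used == 190

    def test_rank_deficient_design_rejected(self):
        geno, grm, y = _sim_grm_pheno(100, 100, 0.4, seed=45)
        X = np.column_stack([np.ones(100), np.ones(100)])
        with pytest.raises(ValueError, match="rank"):
            fit_univariate_greml(y, X, grm)

    def test_coverage_of_h2_interval(self):
        # nominal 95% interval from the delta-method SE should cover the
        # generating value in roughly 95% of replicates (accept 90-99%)
        truth_h2 = 0.4
        hits, total = 0, 100
        for rep in range(total):
            geno, grm, y = _sim_grm_pheno(500, 500, truth_h2, seed=9000 + rep)
            fit = fit_univariate_greml(y, np.ones((500, 1)), grm)
            lo = fit.h2 - 1.96 * fit.se_h2
            hi = fit.h2 + 1.96 * fit.se_h2
            hits += lo <= truth_h2 <= hi
        assert 90 <= hits <= 99


class TestBivariate:
    def test_model_factorizes_without_covariances(self):
        # dropping both covariance components must reproduce the two marginal
        # univariate fits exactly
        geno, grm, y0 = _sim_grm_pheno(150, 200, 0.5, seed=46)
        rng = np.random.default_rng(5)
        y1 = rng.normal(size=150)
        X = np.ones((150, 1))
        u0 = fit_univariate_greml(y0, X, grm)
        u1 = fit_univariate_greml(y1, X, grm)
        n = 150
        import scipy.linalg

        from longherit.varcomp import _bivar_mats

        mats = _bivar_mats(grm.matrix)
        mats_nocov = [mats[0], mats[2], mats[3], mats[5]]
        yy = np.concatenate([y0, y1])
        XX = scipy.linalg.block_diag(X, X)
        v0, v1 = np.var(y0, ddof=1), np.var(y1, ddof=1)
        fit = _reml_maximize(
            yy, XX, mats_nocov,
            np.array([0.5 * v0, 0.5 * v1, 0.5 * v0, 0.5 * v1]),
            var_idx=[0, 1, 2, 3],
        )
        np.testing.assert_allclose(
            fit.params, [u0.sigma_g2, u1.sigma_g2, u0.sigma_e2, u1.sigma_e2],
            rtol=1e-4, atol=1e-6,
        )
        assert fit.logL == pytest.approx(u0.logL + u1.logL, abs=1e-4)

    def test_null_genetic_correlation_within_two_se(self):
        t = SimTruth(n_subjects=500, n_snps=500, h0_sq=0.5, h1_sq=0.5,
                     rho_g=0.0, rho_e=0.0, seed=47)
        geno = simulate_genotypes(t)
        _, truth = simulate_cohort(t, geno)
        grm = compute_grm(geno)
        X = np.ones((500, 1))
        b = fit_bivariate_greml(
            truth["beta0"].to_numpy(), truth["beta1_std"].to_numpy(), X, grm
        )
        assert abs(b.rho_g) <= 2.0 * b.se_rho_g + 1e-9

    def test_rho_g_consistency_relation(self):
        t = SimTruth(n_subjects=400, n_snps=400, h0_sq=0.5, h1_sq=0.4,
                     rho_g=0.7, seed=48)
        geno = simulate_genotypes(t)
        _, truth = simulate_cohort(t, geno)
        grm = compute_grm(geno)
        b = fit_bivariate_greml(
            truth["beta0"].to_numpy(), truth["beta1_std"].to_numpy(),
            np.ones((400, 1)), grm,
        )
        assert b.rho_g == pytest.approx(
            b.sigma_g01 / np.sqrt(b.sigma_g0_2 * b.sigma_g1_2), abs=1e-10
        )
        assert -1.0 <= b.rho_g <= 1.0 and -1.0 <= b.rho_e <= 1.0
        assert b.logL >= b.logL_rg0 - 1e-6


class TestGxE:
    def test_constant_exposure_rejected(self, small_grm):
        n = small_grm.n
        y = np.random.default_rng(2).normal(size=n)
        with pytest.raises(ValueError, match="constant"):
            fit_gxe_greml(y, np.ones((n, 1)), small_grm, np.ones(n))

    def test_null_interaction_near_zero(self):
        t = SimTruth(n_subjects=500, n_snps=500, h0_sq=0.3, h1_sq=0.3,
                     gxe_var_frac=0.0, smoker_frac=0.5, seed=49)
        geno = simulate_genotypes(t)
        _, truth = simulate_cohort(t, geno)
        grm = compute_grm(geno)
        env = (truth["smoking"] == "ever").to_numpy(dtype=float)
        X = np.column_stack([np.ones(500), env])
        fit = fit_gxe_greml(truth["beta1_std"].to_numpy(), X, grm, env)
        assert fit.h_gxe2 <= 2.0 * fit.se_h_gxe2 + 1e-9
        assert fit.p_value > 0.01

    def test_missing_exposure_dropped(self):
        t = SimTruth(n_subjects=300, n_snps=300, h0_sq=0.3, smoker_frac=0.5, seed=50)
        geno = simulate_genotypes(t)
        _, truth = simulate_cohort(t, geno)
        grm = compute_grm(geno)
        env = (truth["smoking"] == "ever").to_numpy(dtype=float)
        env[:20] = np.nan
        X = np.column_stack([np.ones(300), np.nan_to_num(env)])
        fit = fit_gxe_greml(truth["beta0"].to_numpy(), X, grm, env)
        assert fit.n_used == 280


class TestDerivedQuantities:
    @staticmethod
    def _components(sg0, sg1, rho_g):
        return BivariateComponents(
            sigma_g0_2=sg0, sigma_g1_2=sg1,
            sigma_g01=rho_g * np.sqrt(sg0 * sg1), rho_g=rho_g,
            se_rho_g=np.nan, p_rho_g=np.nan, sigma_e0_2=1 - sg0,
            sigma_e1_2=1 - sg1, sigma_e01=0.0, rho_e=0.0, se_rho_e=np.nan,
            logL=0.0, logL_rg0=0.0, n_used=0, converged=True,
        )

    def test_published_ratio_trait_covariance(self):
        # genetic (co)variances reported for the FEV1/FVC trajectory pair
        cov, cond = derived_quantities(self._components(0.1807, 0.1538, 0.6279))
        assert round(cov, 4) == 0.1047
        assert round(cond, 4) == 0.0932

    def test_published_postbronchodilator_covariance(self):
        cov, cond = derived_quantities(self._components(0.2593, 0.1742, 0.466))
        assert round(cov, 3) == 0.099
        assert round(cond, 4) == 0.1364

    def test_independence_case(self):
        cov, cond = derived_quantities(self._components(0.2, 0.1, 0.0))
        assert cov == 0.0
        assert cond == pytest.approx(0.1)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            derived_quantities(self._components(0.0, 0.1, 0.5))


class TestLRT:
    def test_zero_statistic(self):
        assert lrt_pvalue(10.0, 10.0, "chi2_1") == pytest.approx(1.0)
        assert lrt_pvalue(10.0, 10.0, "boundary_mixture") >= 0.5

    def test_chi2_quantile(self):
        assert lrt_pvalue(0.0, -3.841459 / 2, "chi2_1") == pytest.approx(0.05, abs=1e-6)

    def test_mixture_quantile_against_normal_tail(self):
        # 0.5 * P(chi2_1 > L) = P(Z > sqrt(L)) via the normal tail
        from math import erfc, sqrt

        lam = 2.705543
        expected = 0.5 * erfc(sqrt(lam / 2))
        assert lrt_pvalue(lam / 2, 0.0, "boundary_mixture") == pytest.approx(
            expected, abs=1e-9
        )
        assert expected == pytest.approx(0.05, abs=1e-6)

    def test_negative_statistic_rejected(self):
        with pytest.raises(ValueError):
            lrt_pvalue(0.0, 1.0, "chi2_1")
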