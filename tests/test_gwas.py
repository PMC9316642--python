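import numpy as np
import pytest
from scipy.stats import chi2
from scipy.stats import t as t_dist

from longherit import SimTruth, clump, fdr_adjust, genomic_lambda, run_gwas, simulate_genotypes
from longherit.gwas import GwasSummary, qq_manhattan_export
from longherit.simdata import GenotypeMatrix
import pandas as pd


def _make_geno(dosages, pos=None, chrom=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    return GenotypeMatrix(
        dosages=dosages,
        snp_ids=np.array([f"v{j}" for j in range(m)]),
        chrom=np.array(chrom if chrom is not None else ["1"] * m),
        pos=np.asarray(pos if pos is not None else np.arange(1, m + 1) * 1000),
        ref_alt=np.array([("A", "G")] * m),
        sample_ids=np.array([f"i{i}" for i in range(n)]),
    )


def ols_oracle(y, X):
    """Closed-form OLS with t test on the last column -- normal equations only."""
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    r = y - X @ beta
    df = len(y) - X.shape[1]
    s2 = float(r @ r) / df
    se = np.sqrt(s2 * np.linalg.inv(XtX)[-1, -1])
    t = beta[-1] / se
    p = 2 * t_dist.sf(abs(t), df)
    return beta[-1], se, t, p


class TestRunGwas:
    def test_single_snp_matches_ols_oracle(self):
        rng = np.random.default_rng(61)
        n = 200
        dos = rng.binomial(2, 0.3, n).astype(float)
        covars = rng.normal(size=(n, 3))
        y = 0.3 * dos + covars @ [0.5, -0.2, 0.1] + rng.normal(size=n)
        geno = _make_geno(dos[:, None])
        summ = run_gwas(y, geno, covars)
        X = np.column_stack([np.ones(n), covars, dos])
        beta, se, t, p = ols_oracle(y, X)
        row = summ.rows.iloc[0]
        assert (row["a1"], row["a2"]) == ("G", "A")  # effect allele is alt
        assert row["beta"] == pytest.approx(beta, abs=1e-10)
        assert row["se"] == pytest.approx(se, abs=1e-10)
        assert row["t_stat"] == pytest.approx(t, abs=1e-8)
        assert row["p_value"] == pytest.approx(p, rel=1e-8)

    def test_permutation_null_calibrated(self):
        rng = np.random.default_rng(62)
        t = SimTruth(n_subjects=400, n_snps=5000, seed=62)
        geno = simulate_genotypes(t)
        y = rng.permutation(rng.normal(size=400))
        covars = rng.normal(size=(400, 2))
        summ = run_gwas(y, geno, covars)
        frac = (summ.rows["p_value"] < 0.05).mean()
        assert abs(frac - 0.05) < 0.01

    def test_snp_identical_to_covariate_rejected(self):
        rng = np.random.default_rng(63)
        n = 100
        dos = rng.binomial(2, 0.4, n).astype(float)
        covars = dos[:, None].copy()
        with pytest.raises(ValueError, match="collinear"):
            run_gwas(rng.normal(size=n), _make_geno(dos[:, None]), covars)

    def test_monomorphic_snp_flagged_not_fatal(self):
        rng = np.random.default_rng(64)
        n = 100
        dos = np.column_stack([np.zeros(n), rng.binomial(2, 0.4, n)]).astype(float)
        summ = run_gwas(rng.normal(size=n), _make_geno(dos), rng.normal(size=(n, 1)))
        assert np.isnan(summ.rows.loc[0, "p_value"])
        assert np.isfinite(summ.rows.loc[1, "p_value"])

    def test_beta_independent_of_other_snps(self):
        rng = np.random.default_rng(65)
        t = SimTruth(n_subjects=150, n_snps=20, seed=65)
        geno = simulate_genotypes(t)
        y = rng.normal(size=150)
        covars = rng.normal(size=(150, 2))
        full = run_gwas(y, geno, covars)
        solo = run_gwas(y, geno.take_snps(np.array([7])), covars)
        assert full.rows.loc[7, "beta"] == pytest.approx(
            solo.rows.loc[0, "beta"], abs=1e-12
        )

    def test_planted_large_effect_snp_attains_min_p(self):
        hits = 0
        for seed in range(10):
            t = SimTruth(n_subjects=500, n_snps=5000, seed=700 + seed)
            geno = simulate_genotypes(t)
            rng = np.random.default_rng(800 + seed)
            target = 1234
            y = 0.5 * geno.dosages[:, target] + rng.normal(size=500)
            covars = rng.normal(size=(500, 2))
            summ = run_gwas(y, geno, covars)
            hits += int(summ.rows["p_value"].idxmin() == target)
        assert hits >= 9

    def test_complete_case_mode_matches_oracle_with_missing(self):
        rng = np.random.default_rng(66)
        n = 300
        dos = rng.binomial(2, 0.3, n).astype(float)
        dos[:30] = np.nan
        covars = rng.normal(size=(n, 2))
        y = rng.normal(size=n)
        summ = run_gwas(y, _make_geno(dos[:, None]), covars, missing="complete_case")
        obs = ~np.isnan(dos)
        X = np.column_stack([np.ones(obs.sum()), covars[obs], dos[obs]])
        beta, se, _, _ = ols_oracle(y[obs], X)
        assert summ.rows.loc[0, "beta"] == pytest.approx(beta, abs=1e-10)
        assert summ.rows.loc[0, "se"] == pytest.approx(se, abs=1e-10)
        assert summ.rows.loc[0, "n"] == obs.sum()


class TestGenomicLambda:
    def test_all_half_pvalues_give_unity(self):
        lam = genomic_lambda(np.full(500, 0.5))
        assert lam == pytest.approx(1.0, abs=1e-12)

    def test_uniform_null(self):
        rng = np.random.default_rng(67)
        lam = genomic_lambda(rng.random(100_000))
        assert abs(lam - 1.0) < 0.02

    def test_inflated_chisq_by_construction(self):
        rng = np.random.default_rng(68)
        stats = 1.2 * chi2.rvs(1, size=200_000, random_state=rng)
        lam = genomic_lambda(chi2.sf(stats, 1))
        assert lam == pytest.approx(1.2, abs=0.02)

    def test_too_few_pvalues_rejected(self):
        with pytest.raises(ValueError):
            genomic_lambda(np.full(50, 0.5))


class TestFdrAdjust:
    def test_single_p_unchanged(self):
        assert fdr_adjust(np.array([0.037]))[0] == pytest.approx(0.037)

    def test_hand_bh_computation(self):
        # q_i = min over j>=i of p_j * m / j; here every step gives 0.04
        q = fdr_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        np.testing.assert_allclose(fdr_adjust(np.ones(5)), 1.0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(69)
        p = rng.random(200)
        perm = rng.permutation(200)
        q = fdr_adjust(p)
        q_perm = fdr_adjust(p[perm])
        np.testing.assert_allclose(q_perm, q[perm])

    def test_q_at_least_p_and_monotone(self):
        rng = np.random.default_rng(70)
        p = rng.random(500)
        q = fdr_adjust(p)
        assert np.all(q >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestClump:
    def _summary(self, geno, pvals):
        rows = pd.DataFrame(
            {
                "snp_id": geno.snp_ids,
                "chrom": geno.chrom,
                "pos": geno.pos,
                "allele_freq": geno.allele_freq,
                "p_value": pvals,
            }
        )
        return GwasSummary(rows=rows, lambda_gc=1.0, n_signif_gw=0)

    def test_uncorrelated_snps_form_singleton_clumps(self):
        rng = np.random.default_rng(71)
        dos = rng.binomial(2, 0.5, size=(500, 4)).astype(float)
        geno = _make_geno(dos)
        summ = self._summary(geno, np.array([1e-10, 1e-9, 1e-12, 0.5]))
        clumps = clump(summ, geno)
        assert sorted(c[0] for c in clumps) == ["v0", "v1", "v2"]
        assert all(len(c[1]) == 1 for c in clumps)

    def test_duplicate_column_absorbed(self):
        rng = np.random.default_rng(72)
        base = rng.binomial(2, 0.5, 400).astype(float)
        dos = np.column_stack([base, base])
        geno = _make_geno(dos, pos=[1000, 2000])
        summ = self._summary(geno, np.array([1e-10, 1e-9]))
        clumps = clump(summ, geno)
        assert clumps == [("v0", ["v0", "v1"])]

    def test_hand_traced_greedy_assignment(self):
        # six SNPs; v1 has the smallest p and is correlated with v0 and v2
        # (within window); v3 is significant, far away; v4 is correlated with
        # v1 but outside the window; v5 is not significant and uncorrelated
        rng = np.random.default_rng(73)
        n = 600
        a = rng.binomial(2, 0.5, n).astype(float)
        b = rng.binomial(2, 0.5, n).astype(float)
        flip = rng.random(n) < 0.05
        a_like1 = np.where(flip, rng.binomial(2, 0.5, n), a).astype(float)
        a_like2 = np.where(flip, rng.binomial(2, 0.5, n), a).astype(float)
        indep = rng.binomial(2, 0.5, n).astype(float)
        dos = np.column_stack([a_like1, a, a_like2, b, a.copy(), indep])
        pos = [1_000, 50_000, 100_000, 600_000, 1_000_000, 120_000]
        geno = _make_geno(dos, pos=pos)
        pvals = np.array([1e-9, 1e-15, 1e-8, 1e-10, 1e-9, 0.9])
        summ = self._summary(geno, pvals)
        clumps = clump(summ, geno, window_kb=250, r2_min=0.1)
        as_dict = dict(clumps)
        assert set(as_dict["v1"]) == {"v1", "v0", "v2"}
        assert as_dict["v3"] == ["v3"]
        assert as_dict["v4"] == ["v4"]  # r2 high but outside the 250 kb window
        assert "v5" not in as_dict


class TestQQExport:
    def test_export_shapes_and_ordering(self):
        rng = np.random.default_rng(74)
        t = SimTruth(n_subjects=200, n_snps=300, seed=74)
        geno = simulate_genotypes(t)
        summ = run_gwas(rng.normal(size=200), geno, rng.normal(size=(200, 2)))
        qq = qq_manhattan_export(summ)
        assert len(qq) == 300
        assert (np.diff(qq["cum_pos"]) > 0).all()
        sp = qq.sort_values("p_value")
        assert (np.diff(sp["expected_neglog10_p"]) <= 0).all()
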