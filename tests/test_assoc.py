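import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bloodeqtl.assoc import GRM, GRMKernel, MixedModel, compute_grm, fit_null, scan_snps
from bloodeqtl.containers import GenotypeMatrix
from bloodeqtl.simulate import SimConfig, simulate_genotypes

from oracles import grm_oracle


def make_geno(dosages, positions=None, chrom="1"):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    positions = positions if positions is not None else np.arange(1, m + 1) * 1000
    variants = pd.DataFrame(
        {"chrom": chrom, "pos": positions, "id": [f"v{k}" for k in range(m)],
         "ref": "A", "alt": "G"}
    )
    return GenotypeMatrix(dosages, variants, [f"s{i}" for i in range(n)])


class TestGrm:
    def test_single_variant_off_diagonal(self):
        # dosages 2 and 0 at p=0.5: (2-1)(0-1)/(2*0.5*0.5) = -2
        g = make_geno([[2.0], [0.0]])
        G = compute_grm(g).matrix
        assert G[0, 1] == pytest.approx(-2.0, abs=1e-12)

    def test_identical_rows_offdiag_equals_diag(self, rng):
        row = rng.integers(0, 3, size=20).astype(float)
        other = rng.integers(0, 3, size=(4, 20)).astype(float)
        g = make_geno(np.vstack([row, row, other]))
        G = compute_grm(g).matrix
        assert G[0, 1] == pytest.approx(G[0, 0], abs=1e-10)
        assert G[0, 1] == pytest.approx(G[1, 1], abs=1e-10)

    def test_matches_brute_force(self, rng):
        X = rng.integers(0, 3, size=(6, 20)).astype(float)
        g = make_geno(X)
        np.testing.assert_allclose(compute_grm(g).matrix, grm_oracle(X), atol=1e-10)

    def test_monomorphic_excluded_from_m(self, rng):
        X = rng.integers(0, 3, size=(8, 10)).astype(float)
        X[:, 0] = 2.0  # monomorphic
        assert compute_grm(make_geno(X)).n_variants_used == 9

    def test_all_monomorphic_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            compute_grm(make_geno(np.ones((5, 3)) * 2))

    def test_asymmetric_matrix_rejected(self):
        M = np.eye(3)
        M[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            GRM(M, 1)


class TestNullFit:
    def test_identity_grm_matches_ols(self, rng):
        n = 120
        y = rng.standard_normal(n)
        X = rng.standard_normal((n, 2))
        cov = pd.DataFrame(X, columns=["c1", "c2"])
        fit = fit_null(y, cov, np.eye(n))
        ols = np.linalg.lstsq(np.column_stack([np.ones(n), X]), y, rcond=None)[0]
        np.testing.assert_allclose(fit.params.to_numpy(), ols, atol=1e-8)

    def test_lambda_recovery(self, rng):
        cfg = SimConfig(n_samples=500, n_variants=800, chrom_length=60_000_000,
                        seed=29, missing_rate=0.0)
        g = simulate_genotypes(cfg)
        G = compute_grm(g)
        vals, vecs = np.linalg.eigh(G.matrix)
        vals = np.clip(vals, 0, None)
        K = GRMKernel(G)
        errs = []
        for rep in range(4):
            u = vecs @ (np.sqrt(vals) * rng.standard_normal(500))
            u = u / u.std(ddof=1)
            y = np.sqrt(0.5) * u + np.sqrt(0.5) * rng.standard_normal(500)
            errs.append(abs(fit_null(y, None, K).lam - 0.5))
        assert np.median(errs) < 0.15

    def test_zero_variance_phenotype_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            fit_null(np.ones(50), None, np.eye(50))

    def test_collinear_covariates_named(self, rng):
        n = 60
        x = rng.standard_normal(n)
        cov = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="b"):
            fit_null(rng.standard_normal(n), cov, np.eye(n))

    def test_summary_renders(self, rng):
        fit = fit_null(rng.standard_normal(40), None, np.eye(40))
        s = fit.summary()
        assert "sigma_g^2" in s and "REML" in s


@pytest.fixture(scope="module")
def sim():
    cfg = SimConfig(n_samples=150, n_variants=120, chrom_length=6_000_000,
                    seed=31, missing_rate=0.0)
    return simulate_genotypes(cfg)


class TestScan:
    def test_identity_grm_matches_simple_regression(self, sim, rng):
        y = rng.standard_normal(sim.n_samples)
        fit = fit_null(y, None, np.eye(sim.n_samples))
        scan = fit.scan(sim)
        X = sim.dosages
        for j in range(0, sim.n_variants, 7):
            lr = stats.linregress(X[:, j], y)
            assert abs(np.log10(lr.pvalue) - np.log10(scan["p"][j])) <= 0.01

    def test_sign_flip_equivariance(self, sim, rng):
        y = rng.standard_normal(sim.n_samples)
        K = GRMKernel(compute_grm(sim))
        fit = fit_null(y, None, K)
        scan = fit.scan(sim)
        flipped = GenotypeMatrix(2.0 - sim.dosages, sim.variants.copy(), list(sim.samples))
        scan_f = fit.scan(flipped)
        np.testing.assert_allclose(scan_f["beta"], -scan["beta"], atol=1e-10)
        np.testing.assert_allclose(scan_f["p"], scan["p"], rtol=1e-10)

    def test_sample_permutation_invariance(self, sim, rng):
        y = rng.standard_normal(sim.n_samples)
        perm = rng.permutation(sim.n_samples)
        G = compute_grm(sim)
        fit1 = fit_null(y, None, GRMKernel(G))
        gp = sim.take_samples(perm)
        fit2 = fit_null(y[perm], None, GRMKernel(compute_grm(gp)))
        s1 = fit1.scan(sim)
        s2 = fit2.scan(gp)
        np.testing.assert_allclose(s1["beta"], s2["beta"], atol=1e-8)
        np.testing.assert_allclose(
            np.log10(s1["p"]), np.log10(s2["p"]), atol=1e-6
        )

    def test_degenerate_variant_flagged(self, sim, rng):
        y = rng.standard_normal(sim.n_samples)
        X = sim.dosages.copy()
        X[:, 5] = 1.0  # constant
        g2 = GenotypeMatrix(X, sim.variants.copy(), list(sim.samples))
        fit = fit_null(y, None, np.eye(sim.n_samples))
        scan = fit.scan(g2)
        assert bool(scan["degenerate"][5])
        assert scan["p"][5] == 1.0

    def test_one_eigendecomposition_for_many_phenotypes(self, sim, rng):
        K = GRMKernel(compute_grm(sim))
        for _ in range(20):
            y = rng.standard_normal(sim.n_samples)
            fit_null(y, None, K).scan(sim)
        assert K.n_decompositions == 1

    def test_scan_vs_joint_reml_refit(self, sim, rng):
        """Null-fixed variance-component Wald p tracks the exact per-SNP
        joint REML refit for every small p."""
        G = compute_grm(sim)
        vals, vecs = np.linalg.eigh(G.matrix)
        vals = np.clip(vals, 0, None)
        u = vecs @ (np.sqrt(vals) * rng.standard_normal(sim.n_samples))
        u = u / u.std(ddof=1)
        X = sim.dosages
        y = 0.5 * X[:, 60] + np.sqrt(0.4) * u + np.sqrt(0.6) * rng.standard_normal(sim.n_samples)
        K = GRMKernel(G)
        scan = fit_null(y, None, K).scan(sim)
        n = sim.n_samples
        for j in range(sim.n_variants):
            if scan["p"][j] >= 0.01 or scan["degenerate"][j]:
                continue
            refit = MixedModel(y, pd.DataFrame({"snp": X[:, j]}), GRMKernel(G)).fit()
            b, se = refit.params["snp"], refit.bse["snp"]
            df = n - refit.model.X.shape[1]
            p_ref = 2 * stats.t.sf(abs(b / se), df)
            assert abs(np.log10(p_ref) - np.log10(scan["p"][j])) <= 0.05


def test_scan_snps_wrapper(rng):
    cfg = SimConfig(n_samples=80, n_variants=40, chrom_length=2_000_000, seed=37, missing_rate=0.0)
    g = simulate_genotypes(cfg)
    y = rng.standard_normal(80)
    fit = fit_null(y, None, compute_grm(g))
    out = scan_snps(fit, g, threshold=1e-4)
    assert {"phenotype", "id", "beta", "se", "p", "significant"} <= set(out.columns)
    assert len(out) == g.n_variants
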