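import subprocess

import numpy as np
import pandas as pd
import pytest

import cnr
from cnr import DataError, DesignMatrix, FitError, Phylogeny, SpeciesRecord


def intercept_only(n):
    return DesignMatrix(names=["intercept"], X=np.ones((n, 1)))


class TestPhyloCovariance:
    def test_three_tip_hand_example(self):
        phy = Phylogeny.from_newick_string("((A:1,B:1):1,C:2);")
        C = cnr.phylo_covariance(phy, ["A", "B", "C"])
        assert np.array_equal(C.matrix, [[2, 1, 0], [1, 2, 0], [0, 0, 2]])

    def test_star_tree_is_identity(self):
        phy = Phylogeny.from_newick_string("(A:1,B:1,C:1,D:1);")
        C = cnr.phylo_covariance(phy, ["A", "B", "C", "D"])
        assert np.array_equal(C.matrix, np.eye(4))

    def test_single_cherry(self):
        phy = Phylogeny.from_newick_string("(A:1,B:1);")
        C = cnr.phylo_covariance(phy, ["A", "B"])
        assert np.array_equal(C.matrix, np.eye(2))

    def test_respects_species_order(self):
        phy = Phylogeny.from_newick_string("((A:1,B:1):1,C:2);")
        C = cnr.phylo_covariance(phy, ["C", "A", "B"])
        assert np.array_equal(C.matrix, [[2, 0, 0], [0, 2, 1], [0, 1, 2]])

    def test_missing_species_named(self):
        phy = Phylogeny.from_newick_string("(A:1,B:1);")
        with pytest.raises(DataError, match="Z"):
            cnr.phylo_covariance(phy, ["A", "Z"])


class TestLambdaTransform:
    def setup_method(self):
        phy = Phylogeny.from_newick_string("((A:1,B:1):1,C:2);")
        self.C = cnr.phylo_covariance(phy, ["A", "B", "C"])

    def test_lambda_zero_gives_diagonal(self):
        out = cnr.lambda_transform(self.C, 0.0).matrix
        assert np.array_equal(out, np.diag([2.0, 2.0, 2.0]))

    def test_lambda_one_is_identity_map(self):
        assert np.array_equal(cnr.lambda_transform(self.C, 1.0).matrix, self.C.matrix)

    def test_half_scales_off_diagonal_only(self):
        out = cnr.lambda_transform(self.C, 0.5).matrix
        assert out[0, 1] == 0.5 and out[0, 0] == 2.0

    @pytest.mark.parametrize("lam", [-0.1, 1.1])
    def test_out_of_range_rejected(self, lam):
        with pytest.raises(DataError):
            cnr.lambda_transform(self.C, lam)


class TestGLSSolve:
    def test_identity_covariance_reduces_to_mean(self):
        beta, *_ = cnr.gls_solve(np.array([1.0, 3.0]), intercept_only(2), np.eye(2))
        assert beta[0] == pytest.approx(2.0)

    def test_three_tip_hand_computed_intercept(self):
        V = np.array([[2.0, 1, 0], [1, 2, 0], [0, 0, 2]])
        beta, *_ = cnr.gls_solve(np.array([2.0, 2.0, 5.0]), intercept_only(3), V)
        assert beta[0] == pytest.approx(23 / 7, abs=1e-12)

    def test_scalar_covariance_equals_ols(self):
        rng = np.random.default_rng(0)
        X = DesignMatrix(["intercept", "x"], np.column_stack([np.ones(20), rng.normal(size=20)]))
        y = rng.normal(size=20)
        b1, *_ = cnr.gls_solve(y, X, np.eye(20))
        b2, *_ = cnr.gls_solve(y, X, 3.7 * np.eye(20))
        ols = np.linalg.lstsq(X.X, y, rcond=None)[0]
        assert np.allclose(b1, ols, atol=1e-10) and np.allclose(b2, ols, atol=1e-10)

    def test_rank_deficient_design_names_x(self):
        X = DesignMatrix(["intercept", "dup"], np.ones((5, 2)))
        with pytest.raises(FitError, match="[Xx]"):
            cnr.gls_solve(np.zeros(5), X, np.eye(5))

    def test_psd_singular_covariance_rescued_by_jitter(self):
        beta, *_ = cnr.gls_solve(
            np.array([1.0, 2.0, 3.0]), intercept_only(3), np.ones((3, 3))
        )
        assert np.isfinite(beta[0])

    def test_indefinite_covariance_names_v(self):
        V = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3 and -1
        with pytest.raises(FitError, match="V"):
            cnr.gls_solve(np.zeros(2), intercept_only(2), V)


class TestPGLSFit:
    def test_lambda_one_recovered_on_brownian_data(self):
        tree = cnr.simulate_tree(200, 5)
        C = cnr.phylo_covariance(tree, tree.tip_labels)
        L = np.linalg.cholesky(C.matrix + 1e-12 * np.eye(200))
        y = L @ np.random.default_rng(6).standard_normal(200)
        fit = cnr.pgls_fit(y, intercept_only(200), C)
        assert 0.85 <= fit.lambda_hat <= 1.0

    def test_lambda_near_zero_on_iid_noise(self):
        tree = cnr.simulate_tree(200, 5)
        C = cnr.phylo_covariance(tree, tree.tip_labels)
        y = np.random.default_rng(8).standard_normal(200)
        fit = cnr.pgls_fit(y, intercept_only(200), C)
        assert fit.lambda_hat < 0.15

    def test_lambda_zero_fit_equals_ols(self):
        """On an ultrametric tree, V(0) is proportional to I: PGLS == OLS."""
        import statsmodels.api as sm

        tree = cnr.simulate_tree(40, 9)
        C = cnr.phylo_covariance(tree, tree.tip_labels)
        rng = np.random.default_rng(10)
        x = rng.normal(size=40)
        y = 1 + 0.3 * x + rng.normal(size=40)
        X = DesignMatrix(["intercept", "x"], np.column_stack([np.ones(40), x]))
        fit = cnr.pgls_fit(y, X, C, lam=0.0)
        ols = sm.OLS(y, X.X).fit()
        assert np.allclose(fit.beta, ols.params, atol=1e-8)
        assert np.allclose(fit.se, ols.bse, atol=1e-8)
        assert np.allclose(fit.p_value, ols.pvalues, atol=1e-8)

    def test_profile_maximum_dominates_fine_grid(self):
        """The optimizer's loglik beats all 101 grid points (grid oracle)."""
        rng = np.random.default_rng(12)
        tree = cnr.simulate_tree(50, 12)
        C = cnr.phylo_covariance(tree, tree.tip_labels)
        L = np.linalg.cholesky(cnr.lambda_transform(C, 0.6).matrix + 1e-12 * np.eye(50))
        X = intercept_only(50)
        for _ in range(4):
            y = L @ rng.standard_normal(50)
            fit = cnr.pgls_fit(y, X, C)
            grid = [
                cnr.gls_solve(y, X, cnr.lambda_transform(C, g).matrix)[3]
                for g in np.linspace(0, 1, 101)
            ]
            assert fit.loglik >= max(grid) - 1e-6

    def test_shift_moves_only_intercept_scale_scales_beta(self):
        rng = np.random.default_rng(14)
        tree = cnr.simulate_tree(30, 14)
        C = cnr.phylo_covariance(tree, tree.tip_labels)
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        X = DesignMatrix(["intercept", "x"], np.column_stack([np.ones(30), x]))
        f0 = cnr.pgls_fit(y, X, C)
        fshift = cnr.pgls_fit(y + 5.0, X, C)
        assert fshift.beta[0] == pytest.approx(f0.beta[0] + 5.0, abs=1e-6)
        assert fshift.beta[1] == pytest.approx(f0.beta[1], abs=1e-6)
        fscale = cnr.pgls_fit(3.0 * y, X, C)
        assert np.allclose(fscale.beta, 3.0 * f0.beta, atol=1e-6)
        assert np.allclose(fscale.se, 3.0 * f0.se, atol=1e-6)
        assert np.allclose(fscale.t_stat, f0.t_stat, atol=1e-6)
        assert fscale.lambda_hat == pytest.approx(f0.lambda_hat, abs=1e-4)

    def test_non_finite_response_rejected(self):
        tree = cnr.simulate_tree(5, 1)
        C = cnr.phylo_covariance(tree, tree.tip_labels)
        y = np.array([1.0, 2.0, np.nan, 0.0, 1.0])
        with pytest.raises(DataError, match="finite"):
            cnr.pgls_fit(y, intercept_only(5), C)

    def test_agrees_with_r_nlme_corpagel(self, tmp_path):
        """Independent oracle: R's nlme::gls with ape::corPagel (ML)."""
        rng = np.random.default_rng(42)
        tree = cnr.simulate_tree(25, 42)
        tips = tree.tip_labels
        C = cnr.phylo_covariance(tree, tips)
        L = np.linalg.cholesky(cnr.lambda_transform(C, 0.6).matrix + 1e-12 * np.eye(25))
        x = rng.standard_normal(25)
        y = 1.0 + 0.5 * x + 0.3 * (L @ rng.standard_normal(25))
        X = DesignMatrix(["intercept", "x"], np.column_stack([np.ones(25), x]))
        fit = cnr.pgls_fit(y, X, C)
        tree.write(tmp_path / "t.nwk")
        pd.DataFrame({"species": tips, "x": x, "y": y}).to_csv(
            tmp_path / "d.csv", index=False
        )
        rcode = f"""
        suppressMessages({{library(ape); library(nlme)}})
        tree <- read.tree("{tmp_path}/t.nwk")
        d <- read.csv("{tmp_path}/d.csv"); rownames(d) <- d$species
        d <- d[tree$tip.label, ]
        m <- gls(y ~ x, data = d,
                 correlation = corPagel(0.5, tree, form = ~species), method = "ML")
        out <- c(coef(m), coef(m$modelStruct$corStruct, unconstrained = FALSE),
                 summary(m)$tTable[, "Std.Error"])
        cat(sprintf("%.10f", out), sep = "\\n")
        """
        res = subprocess.run(
            ["Rscript", "-"], input=rcode, capture_output=True, text=True, timeout=300
        )
        assert res.returncode == 0, res.stderr
        b0, b1, lam, se0, se1 = map(float, res.stdout.strip().splitlines())
        assert fit.beta[0] == pytest.approx(b0, abs=1e-5)
        assert fit.beta[1] == pytest.approx(b1, abs=1e-5)
        assert fit.lambda_hat == pytest.approx(lam, abs=1e-3)
        assert fit.se[0] == pytest.approx(se0, abs=1e-5)
        assert fit.se[1] == pytest.approx(se1, abs=1e-5)


class TestEncodeLifeforms:
    def test_three_form_design(self):
        recs = [
            SpeciesRecord("a", "tree", 10),
            SpeciesRecord("b", "perennial_herb", 10),
            SpeciesRecord("c", "annual_herb", 10),
        ]
        D = cnr.encode_lifeforms(recs)
        assert D.names == ["intercept", "perennial_herb", "annual_herb"]
        assert np.array_equal(D.X, [[1, 0, 0], [1, 1, 0], [1, 0, 1]])

    def test_all_tree_is_intercept_only(self, caplog):
        recs = [SpeciesRecord(f"t{i}", "tree", 10) for i in range(3)]
        with caplog.at_level("WARNING"):
            D = cnr.encode_lifeforms(recs)
        assert D.names == ["intercept"]

    def test_missing_baseline_rejected(self):
        recs = [SpeciesRecord("a", "annual_herb", 10)]
        with pytest.raises(DataError, match="baseline"):
            cnr.encode_lifeforms(recs)

    def test_noise_free_contrast_recovered_exactly(self):
        """Group means 1.0 (trees) vs 0.6 (annuals): coefficient is -0.4."""
        phy = Phylogeny.from_newick_string("(a:1,b:1,c:1,d:1,e:1,f:1);")
        recs = [
            SpeciesRecord(s, f, 10)
            for s, f in zip("abcdef", ["tree"] * 3 + ["annual_herb"] * 3)
        ]
        y = np.array([1.0, 1.0, 1.0, 0.6, 0.6, 0.6])
        D = cnr.encode_lifeforms(recs)
        C = cnr.phylo_covariance(phy, list("abcdef"))
        fit = cnr.pgls_fit(y, D, C)
        assert fit.coef("annual_herb") == pytest.approx(-0.4, abs=1e-10)
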