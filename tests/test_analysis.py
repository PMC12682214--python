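"""PCA and principal component regression: closed-form cases, independent
linear-algebra oracles, invariances, and the worked-example statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import capturedkit as ck
from capturedkit.analysis import (
    DegenerateColumnError,
    SpeciesMismatchError,
    analyze,
    orient_components,
    pc_regression,
    run_pca,
    standardize,
    variable_component_correlations,
)
from capturedkit.core_types import MarketDataset
from capturedkit.scoring import AnalysisInfeasibleError, ScoreMatrix


def make_matrix(values, prefix="S"):
    values = np.asarray(values, dtype=float)
    return ScoreMatrix(
        species=[f"{prefix}{i}" for i in range(values.shape[0])],
        variables=[f"v{j}" for j in range(values.shape[1])],
        values=values,
    )


def random_matrix(rng, n, p):
    return make_matrix(rng.normal(size=(n, p)) + rng.uniform(1, 3, size=p))


class TestStandardize:
    def test_closed_form_column(self):
        m = make_matrix([[1.0], [2.0], [3.0]])
        Z, means, sds = standardize(m)
        assert np.allclose(Z[:, 0], [-1.0, 0.0, 1.0])
        assert means[0] == 2.0 and sds[0] == 1.0

    def test_zero_variance_column_named(self):
        m = make_matrix([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        with pytest.raises(DegenerateColumnError, match="v1"):
            standardize(m)

    def test_medan_matrix_standardizes_cleanly(self, medan_matrix):
        Z, _, _ = standardize(medan_matrix)
        assert Z.shape == (10, 12)
        assert np.allclose(Z.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(Z.std(axis=0, ddof=1), 1.0, atol=1e-12)


class TestRunPca:
    def test_rank_one_matrix(self):
        u = np.array([1.0, 2.0, 3.0, 4.0])
        v = np.array([2.0, -1.0, 0.5])
        m = make_matrix(np.outer(u, v))
        pca = run_pca(m, mode="covariance")
        assert pca.proportion_variance[0] == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(pca.eigenvalues[1:], 0.0, atol=1e-12)

    def test_spherical_gaussian_has_flat_spectrum(self):
        rng = np.random.default_rng(42)
        m = make_matrix(rng.normal(size=(4000, 4)))
        pca = run_pca(m)
        assert np.allclose(pca.proportion_variance, 0.25, atol=0.02)

    def test_svd_matches_correlation_eigendecomposition(self):
        """Independent oracle: eigenvalues of the sample correlation matrix
        agree with the SVD path to 1e-9 on random matrices up to 8x6."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(3, 9))
            p = int(rng.integers(1, 7))
            m = random_matrix(rng, n, p)
            if np.any(m.values.std(axis=0, ddof=1) == 0):  # pragma: no cover
                continue
            pca = run_pca(m)
            Z, _, _ = standardize(m)
            corr = (Z.T @ Z) / (n - 1)
            eig = np.sort(np.linalg.eigvalsh(corr))[::-1]
            k = pca.eigenvalues.shape[0]
            assert np.allclose(pca.eigenvalues, eig[:k], atol=1e-9)

    def test_matches_sklearn(self, medan_matrix):
        sk = pytest.importorskip("sklearn.decomposition")
        Z, _, _ = standardize(medan_matrix)
        ref = sk.PCA().fit(Z)
        pca = run_pca(medan_matrix)
        assert np.allclose(pca.eigenvalues, ref.explained_variance_[:9], atol=1e-9)
        assert np.allclose(
            pca.proportion_variance, ref.explained_variance_ratio_[:9], atol=1e-9
        )

    def test_score_columns_orthogonal_and_variance_equals_eigenvalue(self, medan_matrix):
        pca = run_pca(medan_matrix)
        G = pca.scores.T @ pca.scores
        assert np.allclose(G - np.diag(np.diag(G)), 0.0, atol=1e-8)
        assert np.allclose(pca.scores.var(axis=0, ddof=1), pca.eigenvalues, atol=1e-9)

    def test_proportions_sum_to_one(self, medan_matrix):
        pca = run_pca(medan_matrix)
        assert pca.proportion_variance.sum() == pytest.approx(1.0, abs=1e-12)

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(11)
        m = random_matrix(rng, 8, 5)
        pca = run_pca(m)
        Z, _, _ = standardize(m)
        assert np.allclose(pca.scores @ pca.loadings.T, Z, atol=1e-9)

    def test_sign_rule_deterministic(self, medan_matrix):
        pca = run_pca(medan_matrix)
        for j in range(pca.loadings.shape[1]):
            col = pca.loadings[:, j]
            assert col[np.argmax(np.abs(col))] > 0

    def test_single_row_rejected(self):
        with pytest.raises(AnalysisInfeasibleError):
            run_pca(make_matrix([[1.0, 2.0]]))


class TestOrientComponents:
    def test_negative_correlation_flipped(self):
        rng = np.random.default_rng(0)
        m = random_matrix(rng, 10, 4)
        pca = run_pca(m)
        y = -pca.scores[:, 0] + rng.normal(scale=0.1, size=10)
        oriented = orient_components(pca, y)
        for j in range(oriented.scores.shape[1]):
            r = np.corrcoef(oriented.scores[:, j], y)[0, 1]
            assert r >= 0 or np.isclose(r, 0)

    def test_positive_correlation_unchanged(self):
        rng = np.random.default_rng(1)
        m = random_matrix(rng, 10, 3)
        pca = run_pca(m)
        y = pca.scores[:, 0]
        oriented = orient_components(pca, y)
        assert np.array_equal(oriented.scores[:, 0], pca.scores[:, 0])

    def test_loadings_flip_with_scores(self):
        rng = np.random.default_rng(2)
        m = random_matrix(rng, 12, 4)
        pca = run_pca(m)
        y = rng.normal(size=12)
        oriented = orient_components(pca, y)
        Z, _, _ = standardize(m)
        assert np.allclose(Z @ oriented.loadings, oriented.scores, atol=1e-9)


class TestPcRegression:
    def test_perfect_fit_on_pc1(self):
        rng = np.random.default_rng(3)
        m = random_matrix(rng, 9, 4)
        pca = run_pca(m)
        y = 5.0 + 2.0 * pca.scores[:, 0]
        reg = pc_regression(y, pca, k=1)
        assert reg.r_squared == pytest.approx(1.0, abs=1e-12)
        assert reg.residual_standard_error == pytest.approx(0.0, abs=1e-9)

    def test_matches_normal_equations_oracle(self):
        """Brute-force normal-equations solve reproduces coefficients, SEs,
        t, R^2 and F to 1e-9."""
        rng = np.random.default_rng(4)
        for _ in range(10):
            n, k = int(rng.integers(5, 9)), int(rng.integers(1, 3))
            m = random_matrix(rng, n, 4)
            pca = run_pca(m)
            y = rng.normal(size=n) * 10 + 50
            reg = pc_regression(y, pca, k=k)
            X = np.column_stack([np.ones(n), pca.scores[:, :k]])
            XtX_inv = np.linalg.inv(X.T @ X)
            beta = XtX_inv @ X.T @ y
            resid = y - X @ beta
            rss = resid @ resid
            tss = ((y - y.mean()) ** 2).sum()
            sigma2 = rss / (n - k - 1)
            se = np.sqrt(sigma2 * np.diag(XtX_inv))
            assert np.allclose(reg.coefficients, beta, atol=1e-9)
            assert np.allclose(reg.standard_errors, se, atol=1e-9)
            assert np.allclose(reg.t_values, beta / se, atol=1e-9)
            assert reg.r_squared == pytest.approx(1 - rss / tss, abs=1e-9)
            f = ((tss - rss) / k) / sigma2
            assert reg.f_statistic == pytest.approx(f, abs=1e-9)
            assert (reg.df_model, reg.df_resid) == (k, n - k - 1)

    def test_intercept_equals_response_mean(self):
        """PC scores are mean-centered, so the fitted intercept is the
        response mean for any input."""
        rng = np.random.default_rng(5)
        for _ in range(5):
            m = random_matrix(rng, 10, 5)
            pca = run_pca(m)
            y = rng.normal(size=10) * 100 + 300
            reg = pc_regression(y, pca, k=2)
            assert reg.coefficients[0] == pytest.approx(y.mean(), rel=1e-9)

    def test_insufficient_df_rejected(self):
        rng = np.random.default_rng(6)
        m = random_matrix(rng, 3, 4)
        pca = run_pca(m)
        with pytest.raises(AnalysisInfeasibleError):
            pc_regression(np.arange(3.0), pca, k=2)

    def test_t_equals_coef_over_se(self, medan_report):
        reg = medan_report.regression
        assert np.allclose(
            reg.t_values, reg.coefficients / reg.standard_errors, atol=1e-12
        )
        assert reg.adjusted_r_squared <= reg.r_squared


class TestInvariances:
    def test_scale_invariance(self, medan_matrix, medan):
        """Multiplying any column by a positive constant leaves
        correlation-mode proportions, R^2, F and |t| unchanged."""
        base = analyze(medan_matrix, medan.counts, k=2)
        scaled_values = medan_matrix.values.copy()
        scaled_values[:, 3] *= 7.5
        scaled = ScoreMatrix(
            species=medan_matrix.species,
            variables=medan_matrix.variables,
            values=scaled_values,
        )
        rep = analyze(scaled, medan.counts, k=2)
        assert np.allclose(
            rep.pca.proportion_variance, base.pca.proportion_variance, atol=1e-12
        )
        assert rep.regression.r_squared == pytest.approx(base.regression.r_squared, abs=1e-12)
        assert rep.regression.f_statistic == pytest.approx(base.regression.f_statistic, abs=1e-9)
        assert np.allclose(
            np.abs(rep.regression.t_values), np.abs(base.regression.t_values), atol=1e-9
        )

    def test_sign_invariance(self, medan_matrix, medan):
        """Flipping a component's sign leaves R^2, F, RSE, |t| and p alone."""
        y = np.array([medan.counts.counts[s] for s in medan_matrix.species], float)
        pca = run_pca(medan_matrix)
        flipped = orient_components(pca, -y)  # flips every correlated component
        a = pc_regression(y, pca, k=2)
        b = pc_regression(y, flipped, k=2)
        assert b.r_squared == pytest.approx(a.r_squared, abs=1e-12)
        assert b.f_statistic == pytest.approx(a.f_statistic, abs=1e-9)
        assert b.residual_standard_error == pytest.approx(a.residual_standard_error, abs=1e-9)
        assert np.allclose(np.abs(b.t_values), np.abs(a.t_values), atol=1e-9)
        assert np.allclose(b.p_values, a.p_values, atol=1e-12)

    def test_row_permutation_invariance(self, medan_matrix, medan):
        base = analyze(medan_matrix, medan.counts, k=2)
        rng = np.random.default_rng(8)
        perm = rng.permutation(10)
        permuted = ScoreMatrix(
            species=[medan_matrix.species[i] for i in perm],
            variables=medan_matrix.variables,
            values=medan_matrix.values[perm],
        )
        rep = analyze(permuted, medan.counts, k=2)
        assert rep.regression.r_squared == pytest.approx(base.regression.r_squared, abs=1e-12)
        assert rep.regression.f_statistic == pytest.approx(base.regression.f_statistic, abs=1e-9)
        assert np.allclose(
            rep.pca.proportion_variance, base.pca.proportion_variance, atol=1e-12
        )


class TestVariableComponentCorrelations:
    def test_rank_one_gives_unit_correlations(self):
        u = np.array([1.0, 3.0, -2.0, 0.5, 4.0])
        v = np.array([1.0, -2.0, 0.7])
        m = make_matrix(np.outer(u, v))
        pca = run_pca(m)
        Z, _, _ = standardize(m)
        corr = variable_component_correlations(Z, pca)
        assert np.allclose(np.abs(corr.matrix[:, 0]), 1.0, atol=1e-9)

    def test_loading_times_sqrt_eigenvalue_identity(self, medan_matrix):
        """Under correlation-mode PCA, corr(var j, PC k) equals
        loading(j,k) * sqrt(eigenvalue_k)."""
        pca = run_pca(medan_matrix)
        Z, _, _ = standardize(medan_matrix)
        corr = variable_component_correlations(Z, pca)
        expected = pca.loadings * np.sqrt(pca.eigenvalues)
        # components with (numerically) zero variance have no defined
        # correlation; check the identity where the eigenvalue is positive
        keep = pca.eigenvalues > 1e-8
        assert np.allclose(corr.matrix[:, keep], expected[:, keep], atol=1e-9)
        assert np.all(np.abs(corr.matrix) <= 1 + 1e-12)

    def test_uncorrelated_columns_have_diagonal_structure(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(3000, 3)) * np.array([3.0, 2.0, 1.0])
        pca = run_pca(make_matrix(X), mode="covariance")
        Zc = X - X.mean(axis=0)
        corr = variable_component_correlations(Zc, pca)
        off = corr.matrix - np.diag(np.diag(corr.matrix))
        assert np.all(np.abs(off) < 0.1)

    def test_rarity_negatively_associated_with_oriented_pc1(self, medan_report):
        corr = medan_report.correlations.to_dict()
        assert corr["conservation_value"]["PC1"] < 0
        # supply-side availability measures load positively
        assert corr["abundance"]["PC1"] > 0
        assert corr["habitat_access"]["PC1"] > 0
        assert corr["concealability"]["PC1"] > 0


class TestAnalyze:
    def test_worked_example_statistics(self, medan_report):
        reg = medan_report.regression
        assert 100 * medan_report.pca.proportion_variance[0] == pytest.approx(49.3, abs=0.05)
        assert reg.r_squared == pytest.approx(0.8462, abs=5e-5)
        assert reg.f_statistic == pytest.approx(19.26, abs=5e-3)
        assert (reg.df_model, reg.df_resid) == (2, 7)
        assert reg.residual_standard_error == pytest.approx(138.7, abs=0.05)
        assert reg.coefficients[0] == pytest.approx(195.30, abs=5e-3)
        assert reg.t_values[1] == pytest.approx(5.73, abs=5e-3)
        assert abs(reg.t_values[2]) == pytest.approx(2.39, abs=5e-3)

    def test_intercept_equals_mean_count(self, medan_report, medan):
        assert medan_report.regression.coefficients[0] == pytest.approx(
            medan.counts.total / 10, rel=1e-9
        )

    def test_species_mismatch_reports_difference(self, medan_matrix):
        counts = MarketDataset(records=[("Wrong species", 5)] + [
            (s, 1) for s in medan_matrix.species[1:]
        ])
        with pytest.raises(SpeciesMismatchError) as exc:
            analyze(medan_matrix, counts, k=2)
        assert "Wrong species" in str(exc.value)
        assert medan_matrix.species[0] in str(exc.value)

    def test_covariance_mode_runs(self, medan_matrix, medan):
        rep = analyze(medan_matrix, medan.counts, k=2, pca_mode="covariance")
        assert rep.pca.mode == "covariance"
        assert 0 <= rep.regression.r_squared <= 1

    def test_report_serializes(self, medan_report):
        import json

        payload = json.loads(medan_report.to_json())
        assert payload["regression"]["r_squared"] == pytest.approx(0.8462, abs=5e-5)
        text = medan_report.summary_text()
        assert "49.3%" in text and "0.8462" in text
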