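"""Principal component regression of market counts on framework scores.

Pipeline: standardize the score matrix column-wise, decompose it by SVD
(correlation-mode PCA by default), orient each component to correlate
positively with the observed counts, regress counts on the leading component
scores by OLS, and compute variable-component Pearson correlations (the
correlation-circle diagnostic).

Conventions
-----------
* Standardization uses the sample standard deviation (n-1 denominator).
* Eigenvalues follow the sample convention: eigenvalue_k equals the sample
  variance of score column k; scores are raw projections onto unit-norm
  loadings (variance = eigenvalue), not rescaled to unit variance.
* Deterministic sign rule: within each loading column the entry of largest
  absolute value is made positive (ties broken by lowest variable index),
  before any response-based orientation.
* Counts enter the OLS as a plain numeric response; no count GLM or
  transformation is applied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import statsmodels.api as sm

from .core_types import MarketDataset
from .scoring import AnalysisInfeasibleError, ScoreMatrix

__all__ = [
    "PcaMode",
    "DegenerateColumnError",
    "SpeciesMismatchError",
    "PCAResult",
    "RegressionResult",
    "VariableComponentCorrelations",
    "AnalysisReport",
    "standardize",
    "run_pca",
    "orient_components",
    "pc_regression",
    "variable_component_correlations",
    "analyze",
]

PcaMode = Literal["correlation", "covariance"]


class DegenerateColumnError(ValueError):
    """A matrix column has zero variance and cannot be standardized."""


class SpeciesMismatchError(KeyError):
    """Score matrix and market counts cover different species sets."""

    def __init__(self, only_in_matrix: set[str], only_in_counts: set[str]):
        self.only_in_matrix = only_in_matrix
        self.only_in_counts = only_in_counts
        super().__init__(
            f"species mismatch: only in score matrix {sorted(only_in_matrix)}, "
            f"only in counts {sorted(only_in_counts)}"
        )


@dataclass
class PCAResult:
    """Decomposition of a (standardized) score matrix.

    ``loadings`` is variables x components with unit-norm columns; ``scores``
    is species x components (projections of the centered data onto the
    loadings); ``eigenvalues`` are the sample variances of the score columns,
    non-increasing.
    """

    loadings: np.ndarray
    scores: np.ndarray
    eigenvalues: np.ndarray
    proportion_variance: np.ndarray
    variables: list[str]
    species: list[str]
    centering_means: np.ndarray
    scaling_sds: Optional[np.ndarray]
    mode: PcaMode = "correlation"

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


@dataclass
class RegressionResult:
    """OLS fit of counts on an intercept plus the leading PC scores.

    ``term_names[0]`` is the intercept; the remaining terms are components in
    order.  Degrees of freedom: residual df = n - k - 1, F on (k, n - k - 1).
    """

    term_names: list[str]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    r_squared: float
    adjusted_r_squared: float
    f_statistic: float
    f_pvalue: float
    df_model: int
    df_resid: int
    residual_standard_error: float
    n_obs: int

    def summary_text(self) -> str:
        """Fixed-format text summary in the layout of a standard
        principal-component-regression results table."""
        lines = [
            f"{'Variable':<14}{'Coefficient':>12}{'Std. error':>12}{'t':>8}{'Prob.':>8}",
        ]
        for name, b, se, t, p in zip(
            self.term_names, self.coefficients, self.standard_errors,
            self.t_values, self.p_values,
        ):
            lines.append(f"{name:<14}{b:>12.2f}{se:>12.2f}{t:>8.2f}{p:>8.2f}")
        lines += [
            f"Residual standard error: {self.residual_standard_error:.1f} "
            f"on {self.df_resid} degrees of freedom",
            f"Multiple R^2: {self.r_squared:.4f}   "
            f"Adjusted R^2: {self.adjusted_r_squared:.2f}",
            f"F-statistic: {self.f_statistic:.2f} on {self.df_model} and "
            f"{self.df_resid} DF   p: {self.f_pvalue:.3g}",
        ]
        return "\n".join(lines)


@dataclass
class VariableComponentCorrelations:
    """Pearson correlations of each original (standardized) variable with
    each component score column; the numbers behind a correlation-circle
    plot."""

    matrix: np.ndarray
    variables: list[str]
    components: list[str]

    def to_dict(self) -> dict[str, dict[str, float]]:
        return {
            var: {
                comp: float(self.matrix[i, j])
                for j, comp in enumerate(self.components)
            }
            for i, var in enumerate(self.variables)
        }


def standardize(matrix: ScoreMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Z-score each column (sample SD, n-1 denominator).

    Returns ``(standardized, means, sds)``.

    Raises
    ------
    DegenerateColumnError
        Naming the first zero-variance column encountered.
    """
    X = np.asarray(matrix.values, dtype=float)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(sds == 0)
    if zero.size:
        raise DegenerateColumnError(
            f"column {matrix.variables[zero[0]]!r} has zero variance"
        )
    return (X - means) / sds, means, sds


def run_pca(
    matrix: ScoreMatrix, mode: PcaMode = "correlation"
) -> PCAResult:
    """Principal component analysis via SVD of the centered (and, in
    correlation mode, scaled) score matrix.

    The number of components returned is min(n - 1, p).
    """
    n, p = matrix.values.shape
    if n < 2:
        raise AnalysisInfeasibleError("PCA requires at least 2 rows")
    if mode == "correlation":
        Z, means, sds = standardize(matrix)
    elif mode == "covariance":
        means = matrix.values.mean(axis=0)
        sds = None
        Z = matrix.values - means
    else:
        raise ValueError(f"unknown PCA mode {mode!r}")

    _, svals, vt = np.linalg.svd(Z, full_matrices=False)
    k = min(n - 1, p)
    svals, vt = svals[:k], vt[:k]
    loadings = vt.T  # p x k, unit-norm columns
    # deterministic sign: largest-|entry| of each loading column positive
    for j in range(k):
        col = loadings[:, j]
        i_max = int(np.argmax(np.abs(col)))  # argmax takes the lowest index on ties
        if col[i_max] < 0:
            loadings[:, j] = -col
    scores = Z @ loadings
    eigenvalues = svals**2 / (n - 1)
    total_var = (Z.var(axis=0, ddof=1)).sum()
    return PCAResult(
        loadings=loadings,
        scores=scores,
        eigenvalues=eigenvalues,
        proportion_variance=eigenvalues / total_var,
        variables=list(matrix.variables),
        species=list(matrix.species),
        centering_means=means,
        scaling_sds=sds,
        mode=mode,
    )


def orient_components(pca: PCAResult, response: Sequence[float]) -> PCAResult:
    """Flip each component (scores and loadings together) so its Pearson
    correlation with the response is non-negative.

    A component exactly uncorrelated with the response keeps the default
    sign-rule orientation.  Returns a new :class:`PCAResult`.
    """
    y = np.asarray(response, dtype=float)
    if y.shape[0] != pca.scores.shape[0]:
        raise ValueError("response length does not match number of species")
    scores = pca.scores.copy()
    loadings = pca.loadings.copy()
    yc = y - y.mean()
    for j in range(scores.shape[1]):
        cov = float(scores[:, j] @ yc)
        if cov < 0:
            scores[:, j] = -scores[:, j]
            loadings[:, j] = -loadings[:, j]
    return PCAResult(
        loadings=loadings,
        scores=scores,
        eigenvalues=pca.eigenvalues.copy(),
        proportion_variance=pca.proportion_variance.copy(),
        variables=list(pca.variables),
        species=list(pca.species),
        centering_means=pca.centering_means.copy(),
        scaling_sds=None if pca.scaling_sds is None else pca.scaling_sds.copy(),
        mode=pca.mode,
    )


def pc_regression(
    response: Sequence[float], pca: PCAResult, k: int = 2
) -> RegressionResult:
    """OLS of the response on an intercept plus the first ``k`` PC scores.

    Standard errors use the unbiased residual variance; p-values are
    two-sided from the t distribution on n - k - 1 df; F tests the full
    model against intercept-only.
    """
    y = np.asarray(response, dtype=float)
    n = y.shape[0]
    if not 1 <= k <= pca.n_components:
        raise ValueError(f"k must be in 1..{pca.n_components}, got {k}")
    if n <= k + 1:
        raise AnalysisInfeasibleError(
            f"need n > k + 1 observations for inference (n={n}, k={k})"
        )
    X = sm.add_constant(pca.scores[:, :k])
    fit = sm.OLS(y, X).fit()
    rss = float(fit.ssr)
    return RegressionResult(
        term_names=["(Intercept)"] + [f"PC{j + 1}" for j in range(k)],
        coefficients=np.asarray(fit.params),
        standard_errors=np.asarray(fit.bse),
        t_values=np.asarray(fit.tvalues),
        p_values=np.asarray(fit.pvalues),
        r_squared=float(fit.rsquared),
        adjusted_r_squared=float(fit.rsquared_adj),
        f_statistic=float(fit.fvalue),
        f_pvalue=float(fit.f_pvalue),
        df_model=int(fit.df_model),
        df_resid=int(fit.df_resid),
        residual_standard_error=float(np.sqrt(rss / fit.df_resid)),
        n_obs=n,
    )


def variable_component_correlations(
    standardized: np.ndarray, pca: PCAResult
) -> VariableComponentCorrelations:
    """Pearson correlation of each standardized variable with each score
    column.  Under correlation-mode PCA this equals
    loading(j, k) * sqrt(eigenvalue_k)."""
    Z = np.asarray(standardized, dtype=float)
    if Z.shape[1] != len(pca.variables):
        raise ValueError("standardized matrix and PCA variables disagree")
    k = pca.n_components
    corr = np.empty((Z.shape[1], k))
    for j in range(Z.shape[1]):
        for c in range(k):
            corr[j, c] = np.corrcoef(Z[:, j], pca.scores[:, c])[0, 1]
    return VariableComponentCorrelations(
        matrix=corr,
        variables=list(pca.variables),
        components=[f"PC{c + 1}" for c in range(k)],
    )


@dataclass
class AnalysisReport:
    """Bundle returned by :func:`analyze`: the oriented PCA, the regression
    fit and the variable-component correlation diagnostics."""

    pca: PCAResult
    regression: RegressionResult
    correlations: VariableComponentCorrelations
    dropped_variables: list[tuple[str, str]] = field(default_factory=list)

    def to_json(self, indent: int | None = 2) -> str:
        payload = {
            "pca": {
                "mode": self.pca.mode,
                "variables": self.pca.variables,
                "species": self.pca.species,
                "eigenvalues": self.pca.eigenvalues.tolist(),
                "proportion_variance": self.pca.proportion_variance.tolist(),
                "loadings": self.pca.loadings.tolist(),
                "scores": self.pca.scores.tolist(),
            },
            "regression": {
                "terms": self.regression.term_names,
                "coefficients": self.regression.coefficients.tolist(),
                "standard_errors": self.regression.standard_errors.tolist(),
                "t_values": self.regression.t_values.tolist(),
                "p_values": self.regression.p_values.tolist(),
                "r_squared": self.regression.r_squared,
                "adjusted_r_squared": self.regression.adjusted_r_squared,
                "f_statistic": self.regression.f_statistic,
                "f_pvalue": self.regression.f_pvalue,
                "df_model": self.regression.df_model,
                "df_resid": self.regression.df_resid,
                "residual_standard_error": self.regression.residual_standard_error,
            },
            "variable_component_correlations": self.correlations.to_dict(),
            "dropped_variables": self.dropped_variables,
        }
        return json.dumps(payload, indent=indent)

    def summary_text(self) -> str:
        pc1_pct = 100 * self.pca.proportion_variance[0]
        header = (
            f"Principal component regression ({self.pca.mode}-mode PCA, "
            f"n={self.regression.n_obs} species, "
            f"{len(self.pca.variables)} variables)\n"
            f"PC1 accounts for {pc1_pct:.1f}% of the variance\n"
        )
        return header + self.regression.summary_text()


def analyze(
    matrix: ScoreMatrix,
    counts: MarketDataset,
    k: int = 2,
    pca_mode: PcaMode = "correlation",
) -> AnalysisReport:
    """Full pipeline: standardize, PCA, orient components to the counts,
    regress, and compute variable-component correlations.

    The species sets of ``matrix`` and ``counts`` must be identical (order
    may differ; counts are aligned to the matrix row order).
    """
    m_set, c_set = set(matrix.species), set(counts.species)
    if m_set != c_set:
        raise SpeciesMismatchError(m_set - c_set, c_set - m_set)
    count_map = counts.counts
    y = np.array([count_map[name] for name in matrix.species], dtype=float)

    pca = run_pca(matrix, mode=pca_mode)
    pca = orient_components(pca, y)
    regression = pc_regression(y, pca, k=k)
    if pca.mode == "correlation":
        Z, _, _ = standardize(matrix)
    else:
        Z = matrix.values - matrix.values.mean(axis=0)
    correlations = variable_component_correlations(Z, pca)
    return AnalysisReport(
        pca=pca,
        regression=regression,
        correlations=correlations,
        dropped_variables=list(matrix.dropped_variables),
    )
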