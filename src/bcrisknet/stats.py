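"""Statistical core: prevalence intervals, chi-square with adjusted residuals,
and maximum-likelihood binomial logistic regression.

Prevalence intervals default to the Wilson score method (inverting the score
test), which behaves well at the ~2% prevalence typical of screening cohorts;
Clopper–Pearson and Wald are selectable.

The adjusted standardized Pearson residual for cell (i, j) of an r x c table
with observed O, expected E, row totals R_i, column totals C_j and grand
total n is

    r_ij = (O_ij - E_ij) / sqrt( E_ij (1 - R_i/n) (1 - C_j/n) )

Under independence each r_ij is approximately standard normal; |r| > 2 flags
a cell-level association.  In a 2x2 table r_ij^2 equals the chi-square
statistic in every cell.

``fit_logistic`` is a plain Newton/IRLS maximizer of the Bernoulli
log-likelihood with Wald standard errors from the inverse observed
information.  Complete or quasi-complete separation is detected and flagged
(diverging coefficients), not penalized away.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats import chi2_contingency
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "PrevalenceEstimate",
    "prevalence_ci",
    "ContingencyTable",
    "chi_square",
    "adjusted_residuals",
    "LogisticFit",
    "SeparationError",
    "fit_logistic",
    "univariate_screen",
]

RESIDUAL_THRESHOLD = 2.0


@dataclass
class PrevalenceEstimate:
    x: int
    n: int
    rate: float
    lower: float
    upper: float
    method: str

    def as_percent(self, ndigits: int = 1) -> tuple:
        return (
            round(100 * self.rate, ndigits),
            round(100 * self.lower, ndigits),
            round(100 * self.upper, ndigits),
        )


_CI_METHODS = {"wilson": "wilson", "clopper_pearson": "beta", "wald": "normal"}


def prevalence_ci(x: int, n: int, method: str = "wilson") -> PrevalenceEstimate:
    """Point prevalence x/n with a 95% confidence interval."""
    if n <= 0:
        raise ValueError("prevalence undefined for n = 0")
    if not 0 <= x <= n:
        raise ValueError(f"need 0 <= x <= n, got x={x}, n={n}")
    if method not in _CI_METHODS:
        raise ValueError(f"unknown CI method {method!r}, choose from {sorted(_CI_METHODS)}")
    lower, upper = proportion_confint(x, n, alpha=0.05, method=_CI_METHODS[method])
    rate = x / n
    # guard against 1-ulp overshoot at the boundaries (x = 0 or x = n)
    lower = float(np.clip(min(lower, rate), 0.0, 1.0))
    upper = float(np.clip(max(upper, rate), 0.0, 1.0))
    return PrevalenceEstimate(
        x=x, n=n, rate=rate, lower=lower, upper=upper, method=method
    )


class DegenerateTableError(ValueError):
    """A contingency table with a zero expected count."""


@dataclass
class ContingencyTable:
    """An r x c count table with chi-square and adjusted-residual machinery."""

    observed: np.ndarray
    row_labels: list = field(default_factory=list)
    col_labels: list = field(default_factory=list)

    def __post_init__(self):
        self.observed = np.asarray(self.observed, dtype=float)
        if self.observed.ndim != 2:
            raise ValueError("observed must be a 2-D array")
        if (self.observed < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.row_labels:
            self.row_labels = [f"r{i}" for i in range(self.observed.shape[0])]
        if not self.col_labels:
            self.col_labels = [f"c{j}" for j in range(self.observed.shape[1])]

    @property
    def n(self) -> float:
        return float(self.observed.sum())

    @property
    def expected(self) -> np.ndarray:
        r = self.observed.sum(axis=1, keepdims=True)
        c = self.observed.sum(axis=0, keepdims=True)
        return r @ c / self.n

    def chi_square(self):
        return chi_square(self.observed)

    def adjusted_residuals(self) -> np.ndarray:
        return adjusted_residuals(self.observed)

    def flagged(self, threshold: float = RESIDUAL_THRESHOLD) -> np.ndarray:
        """+1 / -1 for cells with residual beyond ±threshold, else 0."""
        r = self.adjusted_residuals()
        return np.where(r > threshold, 1, np.where(r < -threshold, -1, 0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.observed, index=self.row_labels,
                            columns=self.col_labels)


def chi_square(observed) -> tuple:
    """Pearson chi-square (no continuity correction): returns (X², df, p)."""
    obs = np.asarray(observed, dtype=float)
    r = obs.sum(axis=1)
    c = obs.sum(axis=0)
    if (r == 0).any() or (c == 0).any():
        raise DegenerateTableError(
            "table has an all-zero row or column (zero expected counts)"
        )
    stat, p, dof, _ = chi2_contingency(obs, correction=False)
    return float(stat), int(dof), float(p)


def adjusted_residuals(observed) -> np.ndarray:
    """Adjusted standardized Pearson residual matrix."""
    obs = np.asarray(observed, dtype=float)
    n = obs.sum()
    r = obs.sum(axis=1, keepdims=True)
    c = obs.sum(axis=0, keepdims=True)
    if (r == 0).any() or (c == 0).any():
        raise DegenerateTableError(
            "table has an all-zero row or column (zero expected counts)"
        )
    expected = r @ c / n
    denom = np.sqrt(expected * (1 - r / n) * (1 - c / n))
    with np.errstate(invalid="ignore", divide="ignore"):
        res = (obs - expected) / denom
    return res


# ---------------------------------------------------------------------------
# logistic regression


class SeparationError(ValueError):
    """The likelihood has no finite maximizer (complete separation or a
    degenerate outcome)."""


@dataclass
class LogisticFit:
    coef: np.ndarray
    se: np.ndarray
    names: list
    converged: bool
    iterations: int
    log_likelihood: float
    separation: bool = False

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def wald_z(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.coef / self.se

    @property
    def p_values(self) -> np.ndarray:
        return 2.0 * sps.norm.sf(np.abs(self.wald_z))

    @property
    def or_ci(self) -> np.ndarray:
        """(k, 2) array of 95% Wald CIs on the OR scale."""
        lo = np.exp(self.coef - 1.96 * self.se)
        hi = np.exp(self.coef + 1.96 * self.se)
        return np.column_stack([lo, hi])

    def summary_frame(self) -> pd.DataFrame:
        ci = self.or_ci
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": self.se,
                "or": self.odds_ratios,
                "or_ci_low": ci[:, 0],
                "or_ci_high": ci[:, 1],
                "z": self.wald_z,
                "p": self.p_values,
            },
            index=self.names,
        )


def _log_likelihood(eta, y):
    # numerically stable: log(1+exp(eta)) via logaddexp
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(
    X,
    y,
    names=None,
    add_intercept: bool = True,
    max_iter: int = 100,
    score_tol: float = 1e-8,
    ll_rtol: float = 1e-10,
) -> LogisticFit:
    """Maximum-likelihood binomial logistic fit by Newton/IRLS.

    Convergence when the maximum absolute score drops below ``score_tol`` or
    the relative log-likelihood change falls below ``ll_rtol``.  Standard
    errors come from the inverse observed information at the optimum.
    Separation (constant outcome, perfectly predictive column) yields a
    :class:`SeparationError` or a fit flagged ``separation=True`` with a
    warning, mirroring how diverging coefficients print as OR 0.00
    (0.00–0.00) in classical software output.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X and y have incompatible shapes")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise SeparationError("outcome is constant; the MLE does not exist")
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    names = list(names)
    if add_intercept:
        X = np.column_stack([np.ones(X.shape[0]), X])
        names = ["intercept"] + names
    n, k = X.shape
    if n < k:
        raise ValueError(f"need at least as many rows ({n}) as columns ({k})")

    beta = np.zeros(k)
    ll_old = _log_likelihood(X @ beta, y)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        score = X.T @ (y - p)
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        beta_new = beta + step
        ll_new = _log_likelihood(X @ beta_new, y)
        # step-halving keeps the log-likelihood monotone
        halvings = 0
        while ll_new < ll_old - 1e-12 and halvings < 30:
            step /= 2.0
            beta_new = beta + step
            ll_new = _log_likelihood(X @ beta_new, y)
            halvings += 1
        assert ll_new >= ll_old - 1e-9, "log-likelihood decreased in IRLS"
        beta = beta_new
        if np.max(np.abs(score)) < score_tol:
            ll_old = ll_new
            converged = True
            break
        if abs(ll_new - ll_old) <= ll_rtol * (abs(ll_old) + 1e-12):
            ll_old = ll_new
            converged = True
            break
        ll_old = ll_new

    separation = (not converged and np.max(np.abs(beta)) > 10.0) or (
        converged and np.max(np.abs(beta)) > 15.0
    )
    eta = X @ beta
    p = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
    w = p * (1.0 - p)
    info = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
        separation = True
    if separation:
        warnings.warn(
            "separation suspected: some coefficients diverge and their Wald "
            "statistics are unreliable",
            RuntimeWarning,
            stacklevel=2,
        )
    return LogisticFit(
        coef=beta, se=se, names=names, converged=converged,
        iterations=it, log_likelihood=ll_old, separation=separation,
    )


def _indicator_matrix(values: pd.Series):
    """Dummy-code a categorical Series, dropping the most frequent level as
    reference.  Returns (matrix, level names)."""
    counts = values.value_counts()
    reference = counts.index[0]
    levels = [l for l in counts.index if l != reference]
    if not levels:
        return np.empty((len(values), 0)), [], reference
    mat = np.column_stack([(values == l).astype(float).to_numpy() for l in levels])
    return mat, [str(l) for l in levels], reference


def univariate_screen(
    variables: pd.DataFrame,
    outcome: pd.Series,
    age: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Age-adjusted univariate pre-screen of candidate variables.

    For each column of ``variables`` a logistic model ``outcome ~ age +
    variable`` is fitted (categorical columns dummy-coded against their most
    frequent level); the variable's p is the minimum Wald p over its levels.
    Variables with p < ``alpha`` form the selected set for the joint model.
    Variables triggering separation are excluded with a warning flag.
    """
    y = outcome.astype(float)
    age_col = age.astype(float).to_numpy()[:, None]
    rows = []
    for col in variables.columns:
        v = variables[col]
        mask = v.notna() & outcome.notna() & age.notna()
        vi, yi, ai = v[mask], y[mask].to_numpy(), age_col[mask.to_numpy(), :]
        status = "ok"
        p_min = np.nan
        try:
            if pd.api.types.is_numeric_dtype(vi) and vi.nunique() > 6:
                design = np.column_stack([ai, vi.astype(float).to_numpy()])
                names = ["age", col]
                var_slice = slice(2, 3)
            else:
                mat, levels, ref = _indicator_matrix(vi)
                if not levels:
                    rows.append({"variable": col, "p": np.nan,
                                 "selected": False, "status": "constant"})
                    continue
                design = np.column_stack([ai, mat])
                names = ["age"] + [f"{col}={l}" for l in levels]
                var_slice = slice(2, 2 + len(levels))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                fit = fit_logistic(design, yi, names=names)
            if fit.separation:
                status = "separation"
            else:
                p_min = float(np.min(fit.p_values[var_slice]))
        except SeparationError:
            status = "separation"
        rows.append(
            {
                "variable": col,
                "p": p_min,
                "selected": bool(p_min < alpha) if status == "ok" else False,
                "status": status,
            }
        )
    return pd.DataFrame(rows)
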