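"""Luminance-controlled stepwise model selection and power utilities.

The analysis relates each eye-movement variable to nine image statistics.
Luminance is first regressed out of the response (ordinary least squares on
an intercept and mean L*), then a bidirectional stepwise search over the
candidate statistics minimizes AIC. Collinearity is diagnosed with variance
inflation factors. A repeated-measures ANOVA power routine reproduces the
within-factor noncentral-F sample-size computation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)


def residualize_luminance(y: np.ndarray, lum: np.ndarray) -> np.ndarray:
    """Residuals of OLS of the response on (intercept, luminance).

    With constant luminance the slope is undefined; the mean-centered
    response is returned with a warning.
    """
    y = np.asarray(y, dtype=float)
    lum = np.asarray(lum, dtype=float)
    if y.shape != lum.shape or y.ndim != 1:
        raise ValueError("y and lum must be equal-length vectors")
    if y.size < 3:
        raise ValueError("residualization needs at least 3 points")
    if np.ptp(lum) == 0:
        warnings.warn("constant luminance: returning mean-centered response")
        return y - y.mean()
    X = np.column_stack([np.ones_like(lum), lum])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def _ols_aic(y: np.ndarray, X: np.ndarray) -> float:
    """Gaussian-likelihood AIC, n*log(RSS/n) + 2k, for a design matrix that
    already includes the intercept column."""
    n = y.shape[0]
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + 2.0 * X.shape[1]


@dataclass
class RegressionResult:
    """Selected model of one response at one aggregation level."""

    response: str
    level: str
    predictors: list[str]
    table: pd.DataFrame  # estimate, std_error, t, p per selected predictor
    adj_r2: float
    aic_trace: list[tuple[str, float]]  # (model description, AIC) per step

    def __repr__(self):  # compact, Table-style
        sel = ", ".join(self.predictors) or "(intercept only)"
        return (
            f"RegressionResult({self.response} @ {self.level}: {sel}; "
            f"adj R2 = {self.adj_r2:.3f})"
        )


def _drop_rank_deficient(X: pd.DataFrame) -> pd.DataFrame:
    """Drop later columns that are linearly dependent on earlier ones."""
    keep: list[str] = []
    for col in X.columns:
        cand = X[keep + [col]].to_numpy(float)
        aug = np.column_stack([np.ones(len(X)), cand])
        if np.linalg.matrix_rank(aug) == aug.shape[1]:
            keep.append(col)
        else:
            logger.warning("dropping rank-deficient predictor %r", col)
    return X[keep]


def stepwise_aic(
    y: np.ndarray | pd.Series,
    X: pd.DataFrame,
    direction: str = "both",
    response_name: str = "response",
    level: str = "image",
    tie_tol: float = 1e-9,
) -> RegressionResult:
    """Greedy stepwise predictor selection minimizing AIC.

    Starts from the full model; at each step evaluates every single-column
    drop (and, with ``direction='both'``, every add-back) and takes the move
    with the lowest AIC. Ties within ``tie_tol`` are broken toward the
    smaller model, then alphabetically, making the search deterministic and
    invariant to column permutation. Rank-deficient designs are repaired by
    dropping offending columns first.
    """
    if direction not in ("both", "backward", "forward"):
        raise ValueError(f"unknown direction {direction!r}")
    y = np.asarray(y, dtype=float)
    if np.isnan(y).any() or X.isna().any().any():
        raise ValueError("stepwise regression requires complete data")
    X = _drop_rank_deficient(X)
    n = len(y)
    cols = list(X.columns)
    Xv = {c: X[c].to_numpy(float) for c in cols}
    ones = np.ones(n)

    def design(subset: tuple[str, ...]) -> np.ndarray:
        return np.column_stack([ones] + [Xv[c] for c in subset])

    current: tuple[str, ...] = tuple(sorted(cols)) if direction != "forward" else ()
    current_aic = _ols_aic(y, design(current))
    trace: list[tuple[str, float]] = [("start: " + (",".join(current) or "intercept"), current_aic)]

    while True:
        moves: list[tuple[float, int, tuple[str, ...], str]] = []
        if direction in ("both", "backward"):
            for c in current:
                subset = tuple(s for s in current if s != c)
                moves.append((_ols_aic(y, design(subset)), len(subset), subset, f"-{c}"))
        if direction in ("both", "forward"):
            for c in cols:
                if c not in current:
                    subset = tuple(sorted(current + (c,)))
                    moves.append((_ols_aic(y, design(subset)), len(subset), subset, f"+{c}"))
        if not moves:
            break
        # smallest AIC; ties toward the smaller model, then lexicographic
        moves.sort(key=lambda m: (round(m[0] / tie_tol), m[1], m[2]))
        best_aic, _, best_subset, label = moves[0]
        if best_aic < current_aic - tie_tol or (
            abs(best_aic - current_aic) <= tie_tol and len(best_subset) < len(current)
        ):
            current, current_aic = best_subset, best_aic
            trace.append((label, current_aic))
        else:
            break

    if level == "category" and n <= len(cols) + 3:
        warnings.warn(
            f"small-sample regression: n = {n} with {len(cols)} candidate "
            "predictors; estimates are fragile"
        )

    Xsel = sm.add_constant(X[list(current)], has_constant="add")
    fit = sm.OLS(y, Xsel).fit()
    table = pd.DataFrame(
        {
            "estimate": fit.params,
            "std_error": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
        }
    ).drop(index="const", errors="ignore")
    return RegressionResult(
        response=response_name,
        level=level,
        predictors=list(current),
        table=table,
        adj_r2=float(fit.rsquared_adj),
        aic_trace=trace,
    )


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factor 1/(1 - R^2_j) of each predictor regressed
    on the others (with intercept). Perfect collinearity reports inf."""
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least two predictors")
    out = {}
    ones = np.ones(len(X))
    for col in X.columns:
        yj = X[col].to_numpy(float)
        others = np.column_stack([ones] + [X[c].to_numpy(float) for c in X.columns if c != col])
        beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        tss = float(((yj - yj.mean()) ** 2).sum())
        rss = float(resid @ resid)
        if tss == 0 or rss / tss < 1e-15:
            out[col] = np.inf
        else:
            out[col] = 1.0 / (rss / tss)
    return pd.Series(out, name="vif")


def rm_anova_power(
    f: float,
    m: int,
    n: int,
    alpha: float = 0.05,
    rho: float = 0.5,
) -> float:
    """Power of the repeated-measures within-factor F test.

    Noncentrality lambda = f^2 * m * n / (1 - rho), df1 = m - 1,
    df2 = (n - 1)(m - 1); no sphericity correction. ``f`` is Cohen's f,
    ``m`` the number of measurement levels, ``rho`` the assumed correlation
    among repeated measures.
    """
    if f <= 0 or m < 2 or not (0 < alpha < 1) or not (0 <= rho < 1) or n < 2:
        raise ValueError("invalid power-analysis parameters")
    lam = f * f * m * n / (1.0 - rho)
    df1, df2 = m - 1, (n - 1) * (m - 1)
    fcrit = stats.f.ppf(1.0 - alpha, df1, df2)
    return float(1.0 - stats.ncf.cdf(fcrit, df1, df2, lam))


def required_n(
    f: float,
    m: int,
    alpha: float = 0.05,
    target_power: float = 0.8,
    rho: float = 0.5,
    max_n: int = 10_000,
) -> int:
    """Smallest number of subjects reaching the target power."""
    for n in range(2, max_n + 1):
        if rm_anova_power(f, m, n, alpha, rho) >= target_power:
            return n
    raise ValueError(
        f"target power {target_power} not reachable with n <= {max_n}"
    )


def luminance_controlled_stepwise(
    responses: pd.DataFrame,
    X: pd.DataFrame,
    luminance: np.ndarray | pd.Series,
    level: str = "image",
    direction: str = "both",
) -> dict[str, RegressionResult]:
    """Residualize each response on luminance, then run stepwise selection
    against the candidate image statistics. Returns one result per response
    column."""
    results = {}
    lum = np.asarray(luminance, dtype=float)
    for col in responses.columns:
        resid = residualize_luminance(responses[col].to_numpy(float), lum)
        results[col] = stepwise_aic(
            resid, X, direction=direction, response_name=col, level=level
        )
    return results
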