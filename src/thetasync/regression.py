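"""Ranked multiple linear regression with partial-variance decomposition.

Every variable (response and predictors) is replaced by mid-ranks before an
ordinary least-squares fit; the contribution of a predictor is the R^2 drop
when refitting without it. Group-level beta significance uses one-sample
t-tests with Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata, ttest_1samp

MAX_CONDITION = 1e6


@dataclass
class RegressionResult:
    betas: np.ndarray  # intercept first
    r_squared: float
    partial_r2: dict
    residuals: np.ndarray
    predictor_names: list[str]
    n_obs: int
    _ranked_design: np.ndarray = field(repr=False, default=None)
    _ranked_response: np.ndarray = field(repr=False, default=None)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [{"predictor": "(intercept)", "beta": self.betas[0],
                 "partial_r2": np.nan}]
        for i, name in enumerate(self.predictor_names):
            rows.append({"predictor": name, "beta": self.betas[i + 1],
                         "partial_r2": self.partial_r2.get(name, np.nan)})
        return pd.DataFrame(rows)


def _ols_r2(y: np.ndarray, X: np.ndarray):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return beta, r2, resid


def ranked_regression(
    response: np.ndarray,
    predictors: dict[str, np.ndarray] | list[np.ndarray],
    names: list[str] | None = None,
    rank_response: bool = True,
) -> RegressionResult:
    """Mid-rank OLS of the response on the predictors (with intercept)."""
    if isinstance(predictors, dict):
        names = list(predictors)
        cols = [np.asarray(predictors[k], dtype=float) for k in names]
    else:
        cols = [np.asarray(p, dtype=float) for p in predictors]
        names = names or [f"x{i + 1}" for i in range(len(cols))]
    y = np.asarray(response, dtype=float)
    n = y.size
    if any(c.size != n for c in cols):
        raise ValueError("response and predictors must have equal length")
    if n < 10 * len(cols):
        raise ValueError("need at least 10x more observations than predictors")
    for name, c in zip(names, cols):
        if np.ptp(c) == 0:
            raise ValueError(f"predictor '{name}' is constant")

    ry = rankdata(y) if rank_response else y
    rX = np.column_stack([rankdata(c) for c in cols])
    cond = np.linalg.cond(rX - rX.mean(axis=0))
    if cond > MAX_CONDITION:
        corr = np.corrcoef(rX, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        raise ValueError(
            f"collinear predictors (condition number {cond:.3g}): "
            f"'{names[i]}' vs '{names[j]}'"
        )
    X = np.column_stack([np.ones(n), rX])
    beta, r2, resid = _ols_r2(ry, X)

    partial = {}
    for k, name in enumerate(names):
        keep = [0] + [1 + i for i in range(len(names)) if i != k]
        _, r2_red, _ = _ols_r2(ry, X[:, keep])
        partial[name] = max(r2 - r2_red, 0.0)
    return RegressionResult(
        betas=beta, r_squared=r2, partial_r2=partial, residuals=resid,
        predictor_names=names, n_obs=n,
        _ranked_design=X, _ranked_response=ry,
    )


def partial_variance(result: RegressionResult, predictor: str) -> float:
    """R^2(full) - R^2(without the predictor), by refitting."""
    if predictor not in result.predictor_names:
        raise ValueError(f"predictor '{predictor}' not in model")
    return result.partial_r2[predictor]


def group_beta_significance(betas: np.ndarray, alpha: float = 0.05):
    """One-sample t-test of per-subject betas against zero, Bonferroni corrected.

    ``betas`` is subjects x predictors. Returns ``(p_values, significant)``.
    """
    betas = np.asarray(betas, dtype=float)
    if betas.ndim != 2 or betas.shape[0] < 3:
        raise ValueError("need a subjects x predictors matrix with >= 3 subjects")
    n_pred = betas.shape[1]
    p = np.empty(n_pred)
    for k in range(n_pred):
        col = betas[:, k]
        if np.ptp(col) == 0:
            p[k] = 1.0 if col[0] == 0 else 0.0
            continue
        p[k] = ttest_1samp(col, 0.0).pvalue
    significant = p < alpha / n_pred
    return p, significant
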