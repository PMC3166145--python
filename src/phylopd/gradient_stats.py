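"""Diversity-versus-depth inference along the water column.

Linear and quadratic ordinary-least-squares regressions of a per-sample
diversity value on log10(depth in metres), compared by AIC with the Gaussian
maximum-likelihood variance convention (the residual variance counts as a
free parameter, so k = 3 for the linear and k = 4 for the quadratic model);
plus a one-sample t-test of SES_MPD values against the null expectation of
zero across bootstrap trees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class DepthModelFit:
    model: str  # "linear" | "quadratic"
    coefficients: np.ndarray  # intercept first
    residual_variance: float  # ML estimate, RSS / n
    log_likelihood: float
    aic: float
    n: int
    r_squared: float


def _ols_fit(x: np.ndarray, y: np.ndarray, degree: int, name: str) -> DepthModelFit:
    n = y.size
    X = np.vander(x, degree + 1, increasing=True)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "design matrix is rank deficient (all depths identical?)"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    sigma2 = rss / n
    ll = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)
    k = degree + 2  # intercept + slopes + variance
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    return DepthModelFit(name, beta, sigma2, ll, 2 * k - 2 * ll, n, r2)


def fit_depth_models(
    values: dict[str, float] | pd.Series,
    depths: dict[str, float] | pd.Series,
) -> tuple[DepthModelFit, DepthModelFit, float]:
    """Fit linear and quadratic regressions of value on log10(depth).

    Returns (linear fit, quadratic fit, delta_aic) with
    delta_aic = AIC_linear - AIC_quadratic, so positive values favour the
    quadratic (unimodal) model.
    """
    values = dict(values)
    depths = dict(depths)
    keys = sorted(values)
    if set(keys) - set(depths):
        raise ValueError("every value needs a depth")
    y = np.array([values[k] for k in keys], dtype=float)
    d = np.array([depths[k] for k in keys], dtype=float)
    if (d <= 0).any():
        raise ValueError("depths must be > 0 for the log10 transform")
    if y.size < 4:
        raise ValueError("need at least 4 points for the quadratic model")
    x = np.log10(d)
    lin = _ols_fit(x, y, 1, "linear")
    quad = _ols_fit(x, y, 2, "quadratic")
    return lin, quad, lin.aic - quad.aic


def ses_vs_zero(ses_values) -> tuple[float, float, bool]:
    """One-sample two-sided t-test of SES values against zero.

    Returns (t, p, degenerate); degenerate is True when the values have zero
    variance (the t statistic is then undefined).
    """
    vals = np.asarray(list(ses_values), dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 values")
    scale = max(1.0, float(np.abs(vals).max()))
    if vals.std(ddof=1) < 1e-12 * scale:
        return math.nan, math.nan, True
    t, p = stats.ttest_1samp(vals, 0.0)
    return float(t), float(p), False


def model_comparison_table(results: pd.DataFrame) -> pd.DataFrame:
    """Model-comparison report from a per-(sample, tree) diversity table
    with columns sample, ses, depth_m."""
    rows = []
    by_tree = results.groupby("tree") if "tree" in results else [("ml", results)]
    for tree, grp in by_tree:
        vals = grp.set_index("sample")["ses"].to_dict()
        depths = grp.set_index("sample")["depth_m"].to_dict()
        if len(vals) < 4:
            continue
        lin, quad, delta = fit_depth_models(vals, depths)
        rows.append({
            "tree": tree, "aic_linear": lin.aic, "aic_quadratic": quad.aic,
            "delta_aic": delta, "r2_linear": lin.r_squared,
            "r2_quadratic": quad.r_squared, "n": lin.n,
        })
    return pd.DataFrame(rows)
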