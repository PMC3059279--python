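"""Agreement and repeated-measures statistics.

Implements the statistical toolbox used to compare two measurement
techniques applied to the same subjects: Bland-Altman limits of agreement,
ordinary-least-squares slope tested against unity, coefficient of
variation, paired t-tests, and Gaussian generalized estimating equations
(GEE) with an exchangeable working correlation and robust (sandwich)
standard errors for serial within-subject measures.  GEE fitting is
delegated to statsmodels.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .errors import InsufficientDataError, InvalidParameterError

__all__ = [
    "bland_altman",
    "slope_vs_unity",
    "coefficient_of_variation",
    "paired_t",
    "gee_exchangeable",
    "time_interaction_test",
]


def _pairs(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InvalidParameterError("x and y must have equal length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InvalidParameterError("x and y must be finite")
    return x, y


def bland_altman(x, y) -> dict:
    """Bland-Altman agreement summary of two methods measured pairwise.

    Differences are y - x; limits of agreement are mean ± 1.96 SD.
    """
    x, y = _pairs(x, y)
    if x.size < 2:
        raise InsufficientDataError("bland_altman needs >= 2 pairs")
    d = y - x
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    return {
        "n": int(x.size),
        "mean_diff": mean_diff,
        "sd_diff": sd_diff,
        "loa_low": mean_diff - 1.96 * sd_diff,
        "loa_high": mean_diff + 1.96 * sd_diff,
    }


def slope_vs_unity(x, y) -> dict:
    """OLS slope of y on x with a two-sided test of H0: slope = 1.

    Returns slope, intercept, the 95% CI of the slope and the p-value
    against unity.  Degenerate exact fits (zero residual variance) are
    resolved by the sign of |slope - 1|.
    """
    x, y = _pairs(x, y)
    if x.size < 3:
        raise InsufficientDataError("slope_vs_unity needs >= 3 pairs")
    if np.ptp(x) == 0:
        raise InvalidParameterError("x is constant; slope undefined")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    slope = float(fit.params[1])
    se = float(fit.bse[1])
    df = int(fit.df_resid)
    # An (numerically) exact fit has no residual dof to test against;
    # resolve by whether the slope itself is unity.
    exact = fit.ssr <= 1e-20 * float(np.sum(y * y)) or se == 0 or not np.isfinite(se)
    if exact:
        p = 1.0 if abs(slope - 1.0) <= 1e-8 else 0.0
        ci = (slope, slope)
    else:
        t_stat = (slope - 1.0) / se
        p = float(2 * stats.t.sf(abs(t_stat), df))
        tcrit = stats.t.ppf(0.975, df)
        ci = (slope - tcrit * se, slope + tcrit * se)
    return {
        "slope": slope,
        "intercept": float(fit.params[0]),
        "se": se,
        "ci95": (float(ci[0]), float(ci[1])),
        "p_vs_1": p,
        "n": int(x.size),
    }


def coefficient_of_variation(values) -> float:
    """Sample SD divided by the mean (a fraction, not a percentage)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InsufficientDataError("coefficient_of_variation needs >= 2 values")
    m = v.mean()
    if m == 0:
        raise InvalidParameterError("mean is zero; CV undefined")
    return float(v.std(ddof=1) / m)


def paired_t(x, y) -> dict:
    """Two-sided paired t-test; df = n - 1.

    Zero-variance differences are flagged: identical nonzero shifts give
    p -> 0 with ``zero_variance=True``; identical samples give t=0, p=1.
    """
    x, y = _pairs(x, y)
    if x.size < 2:
        raise InsufficientDataError("paired_t needs >= 2 pairs")
    d = x - y
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return {"t": 0.0, "df": n - 1, "p": 1.0, "zero_variance": True}
        return {"t": float(np.inf) * np.sign(d.mean()), "df": n - 1, "p": 0.0,
                "zero_variance": True}
    t_stat = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2 * stats.t.sf(abs(t_stat), df=n - 1))
    return {"t": t_stat, "df": n - 1, "p": p, "zero_variance": False}


def _check_gee_data(data: pd.DataFrame, cluster_col: str) -> None:
    if cluster_col not in data.columns:
        raise InvalidParameterError(f"missing cluster column {cluster_col!r}")
    if data[cluster_col].nunique() < 2:
        raise InsufficientDataError("GEE needs >= 2 clusters")


def gee_exchangeable(
    data: pd.DataFrame,
    formula: str,
    cluster_col: str = "cluster_id",
    maxiter: int = 100,
    cov_type: str = "bias_reduced",
) -> dict:
    """Gaussian identity-link GEE with exchangeable working correlation.

    Returns coefficient estimates with cluster-robust (sandwich) standard
    errors, two-sided p-values and the moment-estimated within-cluster
    correlation.  With singleton clusters the estimates coincide exactly
    with OLS.

    ``cov_type`` defaults to the Mancl-DeRouen bias-reduced sandwich: the
    uncorrected estimator is anti-conservative with few clusters (type-I
    error near 10% at nominal 5% for ten clusters), which matters because
    the cohorts this package targets have about ten subjects.  Pass
    ``cov_type="robust"`` for the plain sandwich.
    """
    _check_gee_data(data, cluster_col)
    singleton = data.groupby(cluster_col).size().max() == 1
    cov = sm.cov_struct.Independence() if singleton else sm.cov_struct.Exchangeable()
    model = smf.gee(
        formula,
        groups=cluster_col,
        data=data,
        family=sm.families.Gaussian(),
        cov_struct=cov,
    )
    rank = np.linalg.matrix_rank(model.exog)
    if rank < model.exog.shape[1]:
        raise InvalidParameterError("design matrix is rank deficient")
    fit = model.fit(maxiter=maxiter, cov_type=cov_type)
    if not getattr(fit, "converged", True):
        raise InsufficientDataError("GEE failed to converge")
    corr = 0.0 if singleton else float(np.atleast_1d(cov.dep_params)[0])
    return {
        "coefficients": fit.params,
        "robust_se": fit.bse,
        "p_values": fit.pvalues,
        "working_correlation": corr,
        "n_clusters": int(data[cluster_col].nunique()),
        "fit": fit,
    }


def time_interaction_test(
    data: pd.DataFrame,
    response: str = "response",
    technique_col: str = "technique",
    time_col: str = "time_min",
    cluster_col: str = "cluster_id",
) -> dict:
    """Technique x time interaction in a GEE model for serial measures.

    Fits ``response ~ technique + time + technique:time`` with exchangeable
    correlation and reports the interaction coefficient with its robust
    p-value — a drift test for whether one technique's measurements change
    over the acquisition window relative to the other's.
    """
    if time_col not in data.columns or data[time_col].nunique() < 2:
        raise InvalidParameterError("time covariate must have >= 2 distinct values")
    formula = f"{response} ~ {technique_col} + {time_col} + {technique_col}:{time_col}"
    res = gee_exchangeable(data, formula, cluster_col=cluster_col)
    inter = [name for name in res["coefficients"].index if ":" in name]
    if not inter:
        raise InvalidParameterError("no interaction term in fitted model")
    name = inter[0]
    return {
        "interaction_coef": float(res["coefficients"][name]),
        "p": float(res["p_values"][name]),
        "term": name,
        "gee": res,
    }
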