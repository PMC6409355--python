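"""Regression inference: correlation, variance decomposition, F and t tests.

The decomposition uses centred sums of squares

    TSS = sum (Y_i - Ybar)^2,  ESS = sum (Yhat_i - Ybar)^2,
    RSS = sum (Y_i - Yhat_i)^2,

which satisfy TSS = ESS + RSS whenever the fit contains an intercept.  The
overall F statistic is the standard one,

    F = (ESS / k) / (RSS / (n - k - 1))  ~  F(k, n - k - 1) under the null,

with k explanatory variables and n samples; only this form has the stated
null distribution.  A variant that scales by TSS instead of RSS is available
behind ``tss_denominator=True`` for comparison but carries no calibrated
p-value.  Coefficient t statistics are beta_j / se(beta_j) on n - k - 1
degrees of freedom, with two-sided p-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model_core import FitResult


@dataclass(frozen=True)
class VarianceDecomposition:
    tss: float
    ess: float
    rss: float
    n: int
    k: int


@dataclass(frozen=True)
class InferenceReport:
    """Goodness of fit and significance tests for one fitted model."""

    r_squared: float
    adj_r_squared: float
    f_stat: float
    f_pvalue: float
    t_stats: tuple[float, ...]
    t_pvalues: tuple[float, ...]


class ConstantVectorError(ValueError):
    """Correlation is undefined for a constant vector."""


def pearson_correlation(x, y) -> float:
    """cov(X, Y) / sqrt(var(X) var(Y)); the normalisation cancels."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length vectors of size >= 2")
    xc, yc = x - x.mean(), y - y.mean()
    vx, vy = float(xc @ xc), float(yc @ yc)
    if vx == 0.0 or vy == 0.0:
        raise ConstantVectorError("correlation undefined for a constant vector")
    return float((xc @ yc) / math.sqrt(vx * vy))


def variance_decomposition(y, fitted, n_params: int) -> VarianceDecomposition:
    """Centred TSS/ESS/RSS for a fit with ``n_params`` explanatory variables."""
    y = np.asarray(y, dtype=float).ravel()
    fitted = np.asarray(fitted, dtype=float).ravel()
    if y.shape != fitted.shape:
        raise ValueError("y and fitted must have equal length")
    ybar = y.mean()
    tss = float(((y - ybar) ** 2).sum())
    ess = float(((fitted - ybar) ** 2).sum())
    rss = float(((y - fitted) ** 2).sum())
    return VarianceDecomposition(tss=tss, ess=ess, rss=rss, n=y.size, k=n_params)


def r_squared(decomp: VarianceDecomposition) -> float:
    if decomp.tss <= 0:
        raise ValueError("R^2 undefined: TSS must be > 0")
    return 1.0 - decomp.rss / decomp.tss


def adjusted_r_squared(decomp: VarianceDecomposition) -> float:
    """1 - (1 - R^2)(n - 1)/(n - k - 1); may be negative for poor fits."""
    dof = decomp.n - decomp.k - 1
    if dof < 1:
        raise ValueError("adjusted R^2 needs n - k - 1 >= 1")
    r2 = r_squared(decomp)
    return 1.0 - (1.0 - r2) * (decomp.n - 1) / dof


def f_test(
    decomp: VarianceDecomposition,
    tss_denominator: bool = False,
) -> tuple[float, float]:
    """Overall model F statistic and upper-tail p-value on (k, n-k-1) df.

    A perfect fit (RSS = 0) reports F = inf, p = 0; a null fit (ESS = 0)
    reports F = 0, p = 1.
    """
    k, n = decomp.k, decomp.n
    dof = n - k - 1
    if k < 1 or dof < 1:
        raise ValueError("F test unavailable: need k >= 1 and n - k - 1 >= 1")
    denom_ss = decomp.tss if tss_denominator else decomp.rss
    if denom_ss == 0.0:
        return math.inf, 0.0
    f = (decomp.ess / k) / (denom_ss / dof)
    p = float(stats.f.sf(f, k, dof))
    return float(f), p


def t_tests(fit: FitResult) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Per-coefficient t = beta/se and two-sided p on n-k-1 df."""
    dof = fit.dof
    if dof < 1:
        raise ValueError("t tests unavailable: need n - k - 1 >= 1")
    tvals, pvals = [], []
    for b, se in zip(fit.beta, fit.se_beta):
        if not (se > 0):
            raise ValueError("t test undefined: non-positive standard error")
        t = b / se
        tvals.append(float(t))
        pvals.append(2.0 * float(stats.t.sf(abs(t), dof)))
    return tuple(tvals), tuple(pvals)


def inference_report(
    fit: FitResult,
    y: np.ndarray | None = None,
    tss_denominator: bool = False,
) -> InferenceReport:
    """Assemble goodness of fit plus F and t tests for a fitted model."""
    if y is None:
        y = fit.fitted + fit.residuals
    decomp = variance_decomposition(y, fit.fitted, n_params=fit.k)
    f_stat, f_p = f_test(decomp, tss_denominator=tss_denominator)
    t_stats, t_p = t_tests(fit)
    return InferenceReport(
        r_squared=r_squared(decomp),
        adj_r_squared=adjusted_r_squared(decomp),
        f_stat=f_stat,
        f_pvalue=f_p,
        t_stats=t_stats,
        t_pvalues=t_p,
    )
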