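"""Correlation tests between binned disparity and environmental series.

Disparity curves are compared with per-bin covariates (a temperature
proxy such as mean δ¹⁸O, or counts of unconnected continental
landmasses) by Spearman rank correlation, ordinary least squares, and a
generalized least-squares fit with AR(1) serially correlated residuals
over the ordered time bins.  A first-difference variant correlates
changes across successive bins.  Missing bins (no disparity estimate or
no covariate data) are dropped pairwise.  All p-values are two-sided
and uncorrected.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .trees import InputError

__all__ = [
    "bin_average",
    "spearman_test",
    "ols_fit",
    "gls_ar1_fit",
    "first_difference_test",
    "CorrelationResult",
    "correlate",
    "GLSResult",
]


def _complete_pairs(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InputError(f"length mismatch: {x.shape} vs {y.shape}")
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def bin_average(points: Sequence[tuple], bins) -> np.ndarray:
    """Arithmetic per-bin mean of an (age, value) point series.

    A point belongs to the bin with ``younger < age <= older``, so a
    point sitting exactly on a boundary goes to the older bin.  Empty
    bins are missing (NaN).
    """
    ages = np.array([p[0] for p in points], dtype=float)
    vals = np.array([p[1] for p in points], dtype=float)
    if np.any(ages < 0):
        raise InputError("point ages must be >= 0")
    out = np.full(len(bins), np.nan)
    for i, b in enumerate(bins):
        if b.older == b.younger:  # degenerate point bin (Recent)
            sel = ages == b.older
        else:
            sel = (ages > b.younger) & (ages <= b.older)
        if sel.any():
            out[i] = vals[sel].mean()
    if np.all(np.isnan(out)):
        warnings.warn("no covariate points fall in any bin", stacklevel=2)
    return out


def _spearman_r(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx ** 2).sum() * (ry ** 2).sum())
    if denom == 0:
        return np.nan
    return float((rx * ry).sum() / denom)


def spearman_test(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    The p-value is exact (full enumeration of rank permutations,
    two-sided) for n <= 9 and uses the t approximation above that.
    When either variable is entirely tied its ranks have zero variance;
    the correlation is then reported as 0 with p = 1 and a warning.
    """
    x, y = _complete_pairs(x, y)
    n = x.size
    if n < 3:
        raise InputError(f"need >= 3 complete pairs, got {n}")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        warnings.warn("all-tied ranks: Spearman correlation undefined, "
                      "reported as 0", stacklevel=2)
        return 0.0, 1.0
    r = _spearman_r(rx, ry)
    if n <= 9:
        rxc = rx - rx.mean()
        perms = np.array(list(itertools.permutations(ry)))
        pc = perms - ry.mean()
        denom = np.sqrt((rxc ** 2).sum() * (pc ** 2).sum(axis=1))
        rs = (pc @ rxc) / denom
        p = float(np.mean(np.abs(rs) >= np.abs(r) - 1e-12))
    else:
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
            p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return r, p


def ols_fit(x, y) -> tuple[float, float, float, float]:
    """Least-squares line fit: (slope, intercept, R^2, p of slope)."""
    x, y = _complete_pairs(x, y)
    if x.size < 3:
        raise InputError(f"need >= 3 complete pairs, got {x.size}")
    if np.ptp(x) == 0:
        raise InputError("x is constant; slope undefined")
    if np.ptp(y) == 0:  # flat response: zero slope, no variance explained
        return 0.0, float(y[0]), 0.0, 1.0
    res = stats.linregress(x, y)
    return (float(res.slope), float(res.intercept),
            float(res.rvalue ** 2), float(res.pvalue))


@dataclass
class GLSResult:
    slope: float
    intercept: float
    phi: float
    p_slope: float
    loglik: float
    converged: bool


def _gls_profile(x: np.ndarray, y: np.ndarray, phi: float):
    """GLS estimates and profile log-likelihood at a fixed AR(1) phi."""
    n = x.size
    X = np.column_stack([np.ones(n), x])
    idx = np.arange(n)
    R = phi ** np.abs(idx[:, None] - idx[None, :])
    Rinv = np.linalg.inv(R)
    XtRX = X.T @ Rinv @ X
    beta = np.linalg.solve(XtRX, X.T @ Rinv @ y)
    resid = y - X @ beta
    quad = float(resid @ Rinv @ resid)
    sigma2_ml = quad / n
    sign, logdet = np.linalg.slogdet(R)
    ll = -0.5 * (n * np.log(2 * np.pi) + n * np.log(max(sigma2_ml, 1e-300))
                 + logdet + n)
    return beta, XtRX, quad, ll


def gls_ar1_fit(x, y, phi: Optional[float] = None) -> GLSResult:
    """Linear fit with AR(1) residual correlation over the bin order.

    ``x`` and ``y`` must already be in temporal order; the AR(1)
    correlation acts on that ordering.  ``phi`` and the coefficients are
    found by profiled maximum likelihood over phi in (-1, 1); pass
    ``phi`` to fix it (``phi=0`` reproduces OLS exactly).  Failure to
    optimise is flagged on the result, not raised.
    """
    x, y = _complete_pairs(x, y)
    n = x.size
    if n < 5:
        raise InputError(f"need >= 5 complete pairs, got {n}")
    if np.ptp(x) == 0:
        raise InputError("x is constant; slope undefined")

    converged = True
    if phi is None:
        bound = 1 - 1e-6
        try:
            opt = optimize.minimize_scalar(
                lambda f: -_gls_profile(x, y, f)[3],
                bounds=(-bound, bound), method="bounded",
                options={"xatol": 1e-10})
            converged = bool(opt.success)
            phi_hat = float(opt.x)
        except np.linalg.LinAlgError:
            converged = False
            phi_hat = 0.0
    else:
        phi_hat = float(phi)

    beta, XtRX, quad, ll = _gls_profile(x, y, phi_hat)
    sigma2 = quad / (n - 2)
    cov = sigma2 * np.linalg.inv(XtRX)
    se = np.sqrt(cov[1, 1])
    if se == 0:
        p = 0.0 if beta[1] != 0 else 1.0
    else:
        t = beta[1] / se
        p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return GLSResult(slope=float(beta[1]), intercept=float(beta[0]),
                     phi=phi_hat, p_slope=p, loglik=ll, converged=converged)


def first_difference_test(x, y) -> tuple[float, float]:
    """Spearman test on changes across successive bins.

    Differences are taken between consecutive bins where both series
    are present at both endpoints; other differences are dropped.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InputError(f"length mismatch: {x.shape} vs {y.shape}")
    ok = np.isfinite(x) & np.isfinite(y)
    good = ok[:-1] & ok[1:]
    dx = (x[1:] - x[:-1])[good]
    dy = (y[1:] - y[:-1])[good]
    if dx.size < 3:
        raise InputError(
            f"need >= 3 complete difference pairs, got {dx.size}")
    return spearman_test(dx, dy)


@dataclass
class CorrelationResult:
    """All statistics for one disparity-vs-covariate comparison."""

    label: str
    n_pairs: int
    r_spearman: float
    p_spearman: float
    slope: float
    intercept: float
    r_squared: float
    p_ols: float
    gls_slope: float
    gls_phi: float
    p_gls: float
    gls_converged: bool
    r_first_diff: float = np.nan
    p_first_diff: float = np.nan

    def to_row(self) -> dict:
        return {
            "comparison": self.label, "n": self.n_pairs,
            "r_S": self.r_spearman, "p_S": self.p_spearman,
            "R2": self.r_squared, "slope": self.slope,
            "intercept": self.intercept, "p_OLS": self.p_ols,
            "gls_slope": self.gls_slope, "gls_phi": self.gls_phi,
            "p_GLS": self.p_gls,
            "r_S_first_diff": self.r_first_diff,
            "p_S_first_diff": self.p_first_diff,
        }


def correlate(covariate, disparity, label: str = "") -> CorrelationResult:
    """Run the full battery of tests for one aligned (covariate,
    disparity) bin series, oldest bin first."""
    cx, cy = _complete_pairs(covariate, disparity)
    r_s, p_s = spearman_test(covariate, disparity)
    slope, intercept, r2, p_ols = ols_fit(covariate, disparity)
    gls = gls_ar1_fit(covariate, disparity)
    try:
        r_fd, p_fd = first_difference_test(covariate, disparity)
    except InputError:
        r_fd, p_fd = np.nan, np.nan
    return CorrelationResult(
        label=label, n_pairs=cx.size,
        r_spearman=r_s, p_spearman=p_s,
        slope=slope, intercept=intercept, r_squared=r2, p_ols=p_ols,
        gls_slope=gls.slope, gls_phi=gls.phi, p_gls=gls.p_slope,
        gls_converged=gls.converged,
        r_first_diff=r_fd, p_first_diff=p_fd,
    )


def results_table(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in results])
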