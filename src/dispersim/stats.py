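"""Statistical toolkit: Pearson correlation / linear regression and Welch's t.

Implemented from the closed-form sum formulas (scipy provides only the
p-value tail probabilities via the t distribution); scipy.stats serves as a
parity cross-check in the test suite.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats as _sps

__all__ = ["pearson_and_regression", "welch_t_test", "ols"]


def ols(X, y, names: list[str] | None = None) -> dict:
    """Ordinary least squares with intercept for one or more predictors.

    ``X`` is (n, k); returns per-coefficient estimates and two-sided
    p-values (t distribution, n - k - 1 d.f.) keyed by ``names``
    (defaults to x1..xk), plus the intercept and R^2.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[0] == 1:
        X = X.T
    y = np.asarray(y, dtype=np.float64)
    n, k = X.shape
    if y.shape != (n,):
        raise ValueError("y must have one value per row of X")
    if n < k + 2:
        raise ValueError("need at least k + 2 observations")
    names = names or [f"x{i + 1}" for i in range(k)]
    design = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    dof = n - k - 1
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(design.T @ design)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2.0 * _sps.t.sf(np.abs(t), dof)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else math.nan
    return {
        "intercept": float(beta[0]),
        "coef": {nm: float(b) for nm, b in zip(names, beta[1:])},
        "p_values": {nm: float(pv) for nm, pv in zip(names, p[1:])},
        "r_squared": r2,
        "df": dof,
    }


def pearson_and_regression(x, y) -> dict:
    """Pearson r and the least-squares line y = slope*x + intercept.

    Returns ``{"r", "slope", "intercept", "p_value", "n"}`` where ``p_value``
    is the two-sided p for the slope (equivalently r) differing from zero,
    from the t distribution with n-2 degrees of freedom.

    Raises ``ValueError`` on length mismatch, n < 3, non-finite input, or
    zero variance in either variable.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")

    sxx = float(((x - x.mean()) ** 2).sum())
    syy = float(((y - y.mean()) ** 2).sum())
    sxy = float(((x - x.mean()) * (y - y.mean())).sum())
    if sxx == 0.0 or syy == 0.0:
        raise ValueError("zero variance in x or y")

    r = sxy / math.sqrt(sxx * syy)
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    r2 = min(r * r, 1.0)
    if r2 == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r2))
        p = 2.0 * float(_sps.t.sf(abs(t), df=n - 2))
    return {"r": r, "slope": slope, "intercept": intercept, "p_value": p, "n": n}


def welch_t_test(a, b) -> dict:
    """Welch's unequal-variance t test, two-sided.

    Returns ``{"t", "df", "p"}`` with Satterthwaite degrees of freedom.
    Identical-mean samples give t = 0; two degenerate (zero-variance)
    samples raise ``ValueError``.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    na, nb = a.size, b.size
    va = float(a.var(ddof=1))
    vb = float(b.var(ddof=1))
    se2 = va / na + vb / nb
    if se2 == 0.0:
        if float(a.mean()) == float(b.mean()):
            return {"t": 0.0, "df": float(na + nb - 2), "p": 1.0}
        raise ValueError("both samples are degenerate (zero variance)")
    t = (float(a.mean()) - float(b.mean())) / math.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * float(_sps.t.sf(abs(t), df=df))
    return {"t": t, "df": df, "p": p}
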