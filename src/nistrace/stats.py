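"""Statistical layer: correlations, collinearity screen, Gaussian log-link
GLMs with likelihood-ratio G tests, and tie-corrected Kruskal-Wallis.

The GLM fits E[y] = exp(b0 + b1*x) with Gaussian errors by iteratively
reweighted least squares. The slope test is the scaled deviance difference

    G = (D_null - D_full) / phi_full,      phi_full = D_full / (n - 2),

which for a Gaussian family equals the F statistic with (1, n-2) degrees of
freedom; ``p_slope`` therefore uses the exact F reference (the asymptotic
chi-square(1) p-value is exposed as ``p_slope_chi2``). Regression
diagnostics: Durbin-Watson on data-order response residuals (order-dependent
by construction) and the studentised Breusch-Pagan test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import het_breuschpagan
from statsmodels.stats.stattools import durbin_watson


@dataclass
class CorrelationResult:
    r: float
    p: float
    df: int
    method: str


@dataclass
class GLMResult:
    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    phi: float
    G: float
    p_slope: float
    p_slope_chi2: float
    dw: float
    bp_p: float
    n: int
    converged: bool
    n_iter: int


@dataclass
class KWResult:
    H: float
    Hc: float
    p: float
    k: int


def correlation(x, y, method: str = "pearson") -> CorrelationResult:
    """Pearson or Spearman correlation with a two-sided p-value (df = n-2)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(r=float(r), p=float(p), df=n - 2, method=method)


def collinearity_screen(
    predictors: pd.DataFrame, threshold: float = 0.8
) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Greedy collinearity exclusion among candidate predictors.

    For every pair with |r| > threshold the later-listed column is dropped.
    Returns (retained column names, dropped pairs as (kept, dropped, r)).
    """
    cols = list(predictors.columns)
    if len(cols) < 2:
        raise ValueError("need at least 2 predictors")
    dropped: set[str] = set()
    report: list[tuple[str, str, float]] = []
    for i, a in enumerate(cols):
        if a in dropped:
            continue
        for b in cols[i + 1:]:
            if b in dropped:
                continue
            r = float(np.corrcoef(predictors[a], predictors[b])[0, 1])
            if abs(r) > threshold:
                dropped.add(b)
                report.append((a, b, r))
    return [c for c in cols if c not in dropped], report


class GLMConvergenceError(RuntimeError):
    """IRLS failed to converge; carries the coefficient trace."""

    def __init__(self, message: str, trace: list[np.ndarray]):
        super().__init__(message)
        self.trace = trace


def glm_normal_log(
    y, x, max_iter: int = 200, tol: float = 1e-12
) -> GLMResult:
    """Gaussian GLM with log link of a response on a single predictor.

    Starting values come from OLS of log(y + delta) on x with delta half the
    smallest positive response (the log link constrains the fitted mean, not
    the data, so zero responses are admitted). Standard errors use the
    expected-information matrix scaled by the dispersion phi.
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    n = len(y)
    if n < 4:
        raise ValueError("need at least 4 observations")
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    X = np.column_stack([np.ones(n), x])
    pos = y[y > 0]
    delta = 0.5 * pos.min() if pos.size else 1.0
    beta = np.linalg.lstsq(X, np.log(np.maximum(y, 0.0) + delta), rcond=None)[0]
    trace = [beta.copy()]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        eta = np.clip(eta, -500, 500)
        mu = np.exp(eta)
        w = mu ** 2                      # (dmu/deta)^2 / Var, Var = 1
        z = eta + (y - mu) / mu          # working response
        XtW = X.T * w
        try:
            beta_new = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError as exc:
            raise GLMConvergenceError(f"singular IRLS system: {exc}", trace)
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        trace.append(beta.copy())
        if step < tol * (1.0 + np.max(np.abs(beta))):
            converged = True
            break
    if not converged:
        raise GLMConvergenceError(
            f"IRLS did not converge in {max_iter} iterations", trace
        )
    eta = np.clip(X @ beta, -500, 500)
    mu = np.exp(eta)
    resid = y - mu
    d_full = float(resid @ resid)
    d_null = float(np.sum((y - y.mean()) ** 2))  # intercept-only log-link MLE
    phi = d_full / (n - 2)
    if phi > 0:
        G = (d_null - d_full) / phi
        p_f = float(sps.f.sf(G, 1, n - 2))
        p_chi = float(sps.chi2.sf(G, 1))
    else:  # perfect fit
        G = float("inf")
        p_f = 0.0
        p_chi = 0.0
    cov = np.linalg.inv((X.T * mu ** 2) @ X) * (phi if phi > 0 else 0.0)
    se = np.sqrt(np.diag(cov))
    dw = float(durbin_watson(resid))
    try:
        _, bp_p, _, _ = het_breuschpagan(resid, X)
    except (ValueError, np.linalg.LinAlgError):
        bp_p = float("nan")
    return GLMResult(
        slope=float(beta[1]), intercept=float(beta[0]),
        se_slope=float(se[1]), se_intercept=float(se[0]),
        phi=float(phi), G=float(G), p_slope=p_f, p_slope_chi2=p_chi,
        dw=dw, bp_p=float(bp_p), n=n, converged=converged, n_iter=it,
    )


def kruskal_wallis(groups: list) -> KWResult:
    """Kruskal-Wallis H with the tie-corrected statistic Hc.

        H  = 12/(N(N+1)) * sum_j R_j^2/n_j - 3(N+1)
        Hc = H / (1 - sum_t (t^3 - t) / (N^3 - N))

    The p-value comes from the chi-square distribution with k-1 df on Hc.
    All-identical data give H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    groups = [np.asarray(g, float) for g in groups]
    if any(len(g) == 0 for g in groups):
        raise ValueError("groups must be nonempty")
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = sps.rankdata(pooled)  # average ranks for ties
    H = 0.0
    start = 0
    for g in groups:
        rj = ranks[start:start + len(g)].sum()
        H += rj ** 2 / len(g)
        start += len(g)
    H = 12.0 / (N * (N + 1)) * H - 3.0 * (N + 1)
    H = max(H, 0.0)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts))
    denom = 1.0 - tie_term / (N ** 3 - N)
    k = len(groups)
    if denom <= 0:  # every value identical
        return KWResult(H=0.0, Hc=0.0, p=1.0, k=k)
    Hc = H / denom
    p = float(sps.chi2.sf(Hc, k - 1))
    return KWResult(H=float(H), Hc=float(Hc), p=p, k=k)
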