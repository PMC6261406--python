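"""Shared logistic-regression machinery.

Maximum-likelihood fits go through statsmodels; quasi-separated designs
(small carrier counts are routine in rare-CNV tables) fall back to a
Firth-penalized fit, the standard Jeffreys-prior correction whose estimates
stay finite under separation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import norm

#: absolute coefficient beyond which a logit fit is treated as separated
_SEPARATION_COEF = 15.0
_SEPARATION_SE = 200.0


@dataclass
class LogitFit:
    """One fitted logistic model: coefficients on the log-odds scale."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    method: str  # "mle" or "firth"
    separation: bool
    n_obs: int
    converged: bool = True
    notes: list[str] = field(default_factory=list)

    def odds_ratio(self, name: str) -> float:
        with np.errstate(over="ignore"):
            return float(np.exp(self.params[name]))

    def conf_int(self, name: str, alpha: float = 0.05) -> tuple[float, float]:
        z = norm.ppf(1 - alpha / 2)
        lo = self.params[name] - z * self.bse[name]
        hi = self.params[name] + z * self.bse[name]
        with np.errstate(over="ignore"):
            return float(np.exp(lo)), float(np.exp(hi))


def _penalized_loglik(X, y, beta):
    eta = X @ beta
    p = expit(eta)
    eps = 1e-12
    ll = float(y @ np.log(p + eps) + (1 - y) @ np.log(1 - p + eps))
    w = p * (1 - p)
    info = (X.T * w) @ X
    # tiny ridge keeps exactly singular designs (e.g. a constant covariate)
    # comparable across iterations instead of collapsing to -inf
    sign, logdet = np.linalg.slogdet(info + 1e-10 * np.eye(info.shape[0]))
    if sign <= 0:
        return -np.inf
    return ll + 0.5 * logdet


def _firth_logit(X: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-8):
    """Firth-penalized logistic regression (Jeffreys prior bias reduction).

    Newton iterations with step-halving on the penalized log-likelihood;
    unlike plain ML, the penalized maximum is finite under separation.
    """
    n, k = X.shape
    beta = np.zeros(k)
    ll = _penalized_loglik(X, y, beta)
    for _ in range(max_iter):
        eta = X @ beta
        p = expit(eta)
        w = p * (1 - p)
        info = (X.T * w) @ X
        info_inv = np.linalg.pinv(info)
        # hat diagonal of sqrt(W) X (X'WX)^-1 X' sqrt(W)
        h = np.einsum("ij,jk,ik->i", X, info_inv, X) * w
        score = X.T @ (y - p + h * (0.5 - p))
        step = info_inv @ score
        # damp: halve the step until the penalized log-likelihood improves
        for _half in range(30):
            candidate = beta + step
            ll_new = _penalized_loglik(X, y, candidate)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-10:
                break
            step = step / 2.0
        else:
            break
        converged = np.max(np.abs(step)) < tol
        beta = candidate
        ll = ll_new
        if converged:
            break
    eta = X @ beta
    p = expit(eta)
    w = p * (1 - p)
    info = (X.T * w) @ X
    cov = np.linalg.pinv(info)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return beta, se


def fit_logit(X: pd.DataFrame, y: np.ndarray, firth_fallback: bool = True) -> LogitFit:
    """Fit ``y ~ X`` by ML logistic regression, Firth-correcting separation.

    ``X`` must already contain the intercept column.
    """
    names = list(X.columns)
    Xv = np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=float)
    separated = False
    notes: list[str] = []
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(yv, Xv).fit(disp=0, maxiter=200)
        params = np.asarray(res.params, dtype=float)
        bse = np.asarray(res.bse, dtype=float)
        pvals = np.asarray(res.pvalues, dtype=float)
        converged = bool(res.mle_retvals.get("converged", True))
        if (
            not converged
            or not np.all(np.isfinite(bse))
            or np.any(np.abs(params) > _SEPARATION_COEF)
            or np.any(bse > _SEPARATION_SE)
        ):
            separated = True
    except Exception as exc:  # PerfectSeparationError and kin
        separated = True
        notes.append(f"mle failed: {type(exc).__name__}")
        params = bse = pvals = None
        converged = False

    if separated and firth_fallback:
        beta, se = _firth_logit(Xv, yv)
        z = np.divide(beta, se, out=np.full_like(beta, np.nan), where=se > 0)
        pvals = 2 * norm.sf(np.abs(z))
        notes.append("separation detected; Firth-penalized estimates reported")
        return LogitFit(
            params=pd.Series(beta, index=names),
            bse=pd.Series(se, index=names),
            pvalues=pd.Series(pvals, index=names),
            method="firth",
            separation=True,
            n_obs=len(yv),
            notes=notes,
        )
    if params is None:
        raise RuntimeError("logistic fit failed and Firth fallback disabled")
    return LogitFit(
        params=pd.Series(params, index=names),
        bse=pd.Series(bse, index=names),
        pvalues=pd.Series(pvals, index=names),
        method="mle",
        separation=separated,
        n_obs=len(yv),
        converged=converged,
        notes=notes,
    )


def design_from_samples(samples, ancestry_component: str = "afr") -> pd.DataFrame:
    """Baseline covariate design: intercept, sex (M=1) and one admixture proportion.

    Only one of the three ancestry proportions enters a model at a time:
    the triple sums to 1, so including all three (plus intercept) would be
    collinear.
    """
    rows = {
        s.sample_id: {
            "const": 1.0,
            "sex_M": 1.0 if s.sex == "M" else 0.0,
            f"ancestry_{ancestry_component}": s.ancestry_component(ancestry_component),
        }
        for s in samples
    }
    return pd.DataFrame.from_dict(rows, orient="index")


def status_vector(samples) -> pd.Series:
    return pd.Series({s.sample_id: 1.0 if s.is_case else 0.0 for s in samples})
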