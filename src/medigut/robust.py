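"""Generalized linear model fitting, including robust quasi-likelihood estimation.

Two estimation routes share one result type:

* ``robust=False`` — ordinary maximum likelihood through ``statsmodels``
  (logistic for binary outcomes, Gaussian/OLS for continuous ones).
* ``robust=True`` — a Mallows-type robust quasi-likelihood estimator: the
  quasi-score is built from Huber-psi-truncated Pearson residuals, recentred
  by their model-implied expectation so the estimating equation stays
  Fisher-consistent, with optional down-weighting of high-leverage design
  rows. For the Gaussian family with the identity link this reduces to
  Huber M-estimation with MAD scale; for the binomial family it is the
  classic robust quasi-likelihood score for binary regression. Standard
  errors come from the M-estimation sandwich.

The truncation constant ``c`` defaults to 1.345 (95% Gaussian efficiency).
As ``c -> infinity`` the robust estimate coincides with maximum likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

__all__ = ["GlmFit", "fit_glm", "design_matrix"]

_FAMILIES = ("binomial", "gaussian")


@dataclass
class GlmFit:
    """A fitted GLM: point estimates, covariance and provenance flags."""

    family: str
    params: np.ndarray
    cov: np.ndarray
    names: list
    robust: bool
    c: float
    converged: bool
    n_obs: int
    scale: float = 1.0  # residual SD (gaussian); 1 for binomial
    separation_warning: bool = False
    x_weights: str = "none"

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    @property
    def zvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.se

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.zvalues))

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        z = stats.norm.ppf(0.5 + level / 2.0)
        return np.column_stack([self.params - z * self.se, self.params + z * self.se])

    def coef(self, name) -> float:
        return float(self.params[self.names.index(name)])

    def summary_frame(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "estimate": self.params,
                "se": self.se,
                "ci_lo": ci[:, 0],
                "ci_hi": ci[:, 1],
                "p": self.pvalues,
            },
            index=self.names,
        )


def design_matrix(df: pd.DataFrame, terms, add_intercept: bool = True) -> pd.DataFrame:
    """Assemble a numeric design matrix from named columns.

    Categorical (object/category) columns are dummy-encoded with the first
    level dropped; an intercept column is prepended unless disabled.
    """
    parts = []
    for term in terms:
        col = df[term]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=term, drop_first=True, dtype=float)
            parts.append(dummies)
        else:
            parts.append(col.astype(float).to_frame(term))
    X = pd.concat(parts, axis=1) if parts else pd.DataFrame(index=df.index)
    if add_intercept:
        X.insert(0, "intercept", 1.0)
    return X


def _as_matrix(X) -> tuple[np.ndarray, list]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    arr = np.asarray(X, dtype=float)
    return arr, [f"x{j}" for j in range(arr.shape[1])]


def _huber_psi(r: np.ndarray, c: float) -> np.ndarray:
    return np.clip(r, -c, c)


def _design_weights(X: np.ndarray, kind: str) -> np.ndarray:
    if kind == "none":
        return np.ones(X.shape[0])
    if kind == "hat":
        # Mallows weights sqrt(1 - h_ii) from the raw-design hat values
        Q, _ = np.linalg.qr(X)
        h = np.clip((Q**2).sum(axis=1), 0.0, 1.0 - 1e-10)
        return np.sqrt(1.0 - h)
    raise ValueError(f"unknown x_weights kind: {kind!r}")


def _binomial_score(beta, y, X, w, c):
    """Fisher-consistent robust quasi-score for binary logistic regression."""
    eta = X @ beta
    mu = expit(eta)
    v = np.clip(mu * (1.0 - mu), 1e-12, None)
    sv = np.sqrt(v)
    r = (y - mu) / sv
    psi = _huber_psi(r, c)
    # E[psi(R)] under the model: R takes (1-mu)/sv w.p. mu, -mu/sv w.p. 1-mu
    e_psi = _huber_psi((1.0 - mu) / sv, c) * mu + _huber_psi(-mu / sv, c) * (1.0 - mu)
    contrib = (psi - e_psi) * w * sv
    return contrib[:, None] * X  # per-observation score rows


def _gaussian_score(beta, y, X, w, c, sigma):
    r = (y - X @ beta) / sigma
    return (_huber_psi(r, c) * w * sigma)[:, None] * X


def _total_score_jacobian(score_fn, beta, eps=1e-6):
    p = beta.size
    J = np.empty((p, p))
    for j in range(p):
        step = eps * max(1.0, abs(beta[j]))
        bp, bm = beta.copy(), beta.copy()
        bp[j] += step
        bm[j] -= step
        J[:, j] = (score_fn(bp).sum(axis=0) - score_fn(bm).sum(axis=0)) / (2 * step)
    return J


def _sandwich(score_rows: np.ndarray, A: np.ndarray) -> np.ndarray:
    B = score_rows.T @ score_rows
    # pinv guards against a near-singular derivative (saturated logistic)
    Ainv = np.linalg.pinv(A, rcond=1e-12)
    cov = Ainv @ B @ Ainv.T
    return 0.5 * (cov + cov.T)


def fit_glm(
    y,
    X,
    family: str = "binomial",
    robust: bool = False,
    c: float = 1.345,
    x_weights: str = "none",
    max_iter: int = 200,
    tol: float = 1e-10,
) -> GlmFit:
    """Fit a binomial-logit or gaussian-identity GLM, optionally robustly.

    Parameters
    ----------
    y, X:
        Response vector and design matrix (DataFrame keeps column names;
        the intercept must already be a column — see :func:`design_matrix`).
    family:
        ``"binomial"`` (logit link, y in {0, 1}) or ``"gaussian"``.
    robust:
        Use the Mallows-type robust quasi-likelihood estimator instead of
        maximum likelihood.
    c:
        Huber truncation constant for the robust route.
    x_weights:
        ``"none"`` (default, matching the reference estimator's defaults)
        or ``"hat"`` for sqrt(1 - h_ii) leverage down-weighting.
    """
    if family not in _FAMILIES:
        raise ValueError(f"family must be one of {_FAMILIES}")
    Xm, names = _as_matrix(X)
    yv = np.asarray(y, dtype=float).ravel()
    if yv.shape[0] != Xm.shape[0]:
        raise ValueError("y and X have incompatible lengths")
    if np.linalg.matrix_rank(Xm) < Xm.shape[1]:
        raise ValueError("design matrix is rank deficient (collinear columns)")
    if family == "binomial" and not np.isin(yv, (0.0, 1.0)).all():
        raise ValueError("binomial family requires y in {0, 1}")

    if not robust:
        return _fit_ml(yv, Xm, names, family)
    if family == "gaussian":
        return _fit_robust_gaussian(yv, Xm, names, c, x_weights, max_iter, tol)
    return _fit_robust_binomial(yv, Xm, names, c, x_weights, max_iter, tol)


def _fit_ml(y, X, names, family) -> GlmFit:
    fam = sm.families.Binomial() if family == "binomial" else sm.families.Gaussian()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=fam).fit(maxiter=200)
    params = np.asarray(res.params, dtype=float)
    cov = np.asarray(res.cov_params(), dtype=float)
    sep = family == "binomial" and (np.abs(X @ params).max() > 30 or np.abs(params).max() > 25)
    scale = float(np.sqrt(res.scale)) if family == "gaussian" else 1.0
    return GlmFit(
        family=family,
        params=params,
        cov=cov,
        names=names,
        robust=False,
        c=np.inf,
        converged=bool(res.converged) if hasattr(res, "converged") else True,
        n_obs=y.size,
        scale=scale,
        separation_warning=bool(sep),
    )


def _fit_robust_gaussian(y, X, names, c, x_weights, max_iter, tol) -> GlmFit:
    w = _design_weights(X, x_weights)
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    sigma = 1.0
    converged = False
    for _ in range(max_iter):
        resid = y - X @ beta
        mad = np.median(np.abs(resid - np.median(resid)))
        sigma = max(mad / 0.674489750196082, 1e-12)
        r = resid / sigma
        # IRWLS weights: psi(r)/r, unity at r = 0
        om = np.where(np.abs(r) > 1e-12, _huber_psi(r, c) / np.where(r == 0, 1, r), 1.0) * w
        WX = X * om[:, None]
        beta_new = np.linalg.solve(X.T @ WX, WX.T @ y)
        if np.max(np.abs(beta_new - beta)) < tol * (1 + np.max(np.abs(beta))):
            beta = beta_new
            converged = True
            break
        beta = beta_new
    score_fn = lambda b: _gaussian_score(b, y, X, w, c, sigma)
    rows = score_fn(beta)
    A = _total_score_jacobian(score_fn, beta)
    cov = _sandwich(rows, A)
    return GlmFit(
        family="gaussian",
        params=beta,
        cov=cov,
        names=names,
        robust=True,
        c=c,
        converged=converged,
        n_obs=y.size,
        scale=float(sigma),
        x_weights=x_weights,
    )


def _fit_robust_binomial(y, X, names, c, x_weights, max_iter, tol) -> GlmFit:
    w = _design_weights(X, x_weights)
    beta = _fit_ml(y, X, names, "binomial").params.copy()
    score_fn = lambda b: _binomial_score(b, y, X, w, c)
    converged = False
    for _ in range(max_iter):
        U = score_fn(beta).sum(axis=0)
        if np.max(np.abs(U)) < tol * y.size:
            converged = True
            break
        A = _total_score_jacobian(score_fn, beta)
        try:
            step = np.linalg.solve(A, -U)
        except np.linalg.LinAlgError:
            step = -np.linalg.pinv(A, rcond=1e-12) @ U
            if not np.isfinite(step).all():
                break
        # damped Newton: halve until the score norm does not blow up
        lam, base = 1.0, np.linalg.norm(U)
        for _ in range(30):
            trial = beta + lam * step
            if np.linalg.norm(score_fn(trial).sum(axis=0)) <= base * (1 + 1e-8):
                break
            lam *= 0.5
        move = lam * np.max(np.abs(step))
        beta = beta + lam * step
        if move < tol * (1 + np.max(np.abs(beta))):
            converged = True
            break
    rows = score_fn(beta)
    A = _total_score_jacobian(score_fn, beta)
    cov = _sandwich(rows, A)
    sep = np.abs(X @ beta).max() > 30 or np.abs(beta).max() > 25
    return GlmFit(
        family="binomial",
        params=beta,
        cov=cov,
        names=names,
        robust=True,
        c=c,
        converged=converged,
        n_obs=y.size,
        scale=1.0,
        separation_warning=bool(sep),
        x_weights=x_weights,
    )
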