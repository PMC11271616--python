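"""Distance-based variance partitioning and diet-constrained ordination.

The community-level counterpart of the per-taxon screens: how much of the
inter-individual variation in overall microbiota composition does each
host variable explain (PERMANOVA on Aitchison distances), and does the
diet-explained part of that variation itself associate with disease (the
first constrained principal axis, redundancy-analysis style)?
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .robust import design_matrix, fit_glm

__all__ = [
    "aitchison_distance",
    "permanova_marginal",
    "VariancePartitionRecord",
    "ConstrainedAxis",
    "constrained_axis",
    "axis_disease_assoc",
]


def aitchison_distance(clr: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Euclidean distance between CLR rows (the Aitchison distance)."""
    d = squareform(pdist(clr.to_numpy(dtype=float), metric="euclidean"))
    return pd.DataFrame(d, index=clr.index, columns=clr.index)


@dataclass
class VariancePartitionRecord:
    variable: str
    r2: float
    pseudo_f: float
    p: float
    n_permutations: int
    n_samples: int
    seed: int | None
    exact: bool = False


def _gower_center(dist: np.ndarray) -> np.ndarray:
    a = -0.5 * dist**2
    row = a.mean(axis=0, keepdims=True)
    return a - row - row.T + a.mean()


def _model_matrix(values: pd.Series) -> np.ndarray:
    """Design columns (without intercept) for one predictor."""
    if values.dtype == object or isinstance(values.dtype, pd.CategoricalDtype):
        X = pd.get_dummies(values, drop_first=True, dtype=float).to_numpy()
    else:
        X = values.to_numpy(dtype=float)[:, None]
    return X


def _r2_and_f(G: np.ndarray, X: np.ndarray) -> tuple[float, float]:
    n = G.shape[0]
    Xc = np.column_stack([np.ones(n), X])
    Q, _ = np.linalg.qr(Xc)
    # SS relative to the intercept-only (centred) total
    ones = np.ones(n) / math.sqrt(n)
    ss_total = float(np.trace(G) - ones @ G @ ones)
    H = Q @ Q.T
    ss_model = float(np.trace(H @ G @ H) - ones @ G @ ones)
    df_model = Xc.shape[1] - 1
    df_resid = n - Xc.shape[1]
    ss_resid = ss_total - ss_model
    r2 = ss_model / ss_total
    f = (ss_model / df_model) / (ss_resid / df_resid)
    return r2, f


def permanova_marginal(
    dist: pd.DataFrame,
    variable: pd.Series,
    n_perm: int = 999,
    seed: int | None = 0,
    exact: bool = False,
) -> VariancePartitionRecord:
    """Marginal (one-variable) PERMANOVA of a distance matrix on one predictor.

    R2 = SS_model / SS_total from the Gower-centred inner-product matrix,
    the variable fitted alone (continuous, or dummy-coded categorical).
    P is the free-permutation tail probability
    ``(1 + #{perm F >= observed F}) / (1 + n_perm)``; with ``exact=True``
    all ``n!`` label permutations are enumerated instead (small n only).

    Samples with a missing variable value are dropped (complete cases),
    recorded via ``n_samples``.
    """
    variable = variable.reindex(dist.index)
    keep = variable.notna().to_numpy()
    variable = variable[keep]
    D = dist.to_numpy(dtype=float)[np.ix_(keep, keep)]
    n = D.shape[0]
    if variable.nunique() < 2:
        raise ValueError(f"variable {variable.name!r} is constant on complete cases")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    G = _gower_center(D)
    X = _model_matrix(variable)
    r2_obs, f_obs = _r2_and_f(G, X)

    if exact:
        if n > 8:
            raise ValueError("exact enumeration is limited to n <= 8 samples")
        count, total = 0, 0
        for perm in itertools.permutations(range(n)):
            _, f = _r2_and_f(G, X[list(perm)])
            count += f >= f_obs - 1e-12
            total += 1
        p = count / total
        return VariancePartitionRecord(
            str(variable.name), r2_obs, f_obs, p, total, n, None, exact=True
        )

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        _, f = _r2_and_f(G, X[perm])
        hits += f >= f_obs - 1e-12
    p = (1 + hits) / (1 + n_perm)
    return VariancePartitionRecord(str(variable.name), r2_obs, f_obs, p, n_perm, n, seed)


@dataclass
class ConstrainedAxis:
    """First principal axis of the CLR variation explained by one constraint."""

    scores: pd.Series            # unit-variance per-sample axis scores
    variance_explained: float    # fraction of (residualized) CLR variance
    constraint: str
    conditioners: tuple


def constrained_axis(
    clr: pd.DataFrame,
    constraint: pd.Series,
    conditioners: pd.DataFrame | None = None,
) -> ConstrainedAxis:
    """Diet-constrained principal component of the CLR matrix.

    Both the CLR columns and the constraining variable are residualized on
    the conditioning covariates (always including an intercept); each
    residualized CLR column is regressed on the residualized constraint,
    and the axis is the first left singular vector of the rank-1
    fitted-value matrix. Scores are standardized to unit variance and
    oriented to correlate positively with the constraint.
    """
    idx = clr.index
    y = constraint.reindex(idx).to_numpy(dtype=float)
    Y = clr.to_numpy(dtype=float)
    n = len(idx)
    if conditioners is not None and len(conditioners.columns) > 0:
        Z = design_matrix(conditioners.reindex(idx), list(conditioners.columns))
        Zm = Z.to_numpy(dtype=float)
    else:
        Zm = np.ones((n, 1))
    Q, _ = np.linalg.qr(Zm)
    resid = lambda M: M - Q @ (Q.T @ M)
    q = resid(y[:, None]).ravel()
    if np.linalg.norm(q) < 1e-10 * max(np.linalg.norm(y), 1.0):
        raise ValueError("constraint is collinear with the conditioning covariates")
    Yr = resid(Y - Y.mean(axis=0, keepdims=True))
    coef = (q @ Yr) / (q @ q)          # per-taxon slope on the constraint
    fitted = np.outer(q, coef)         # rank-1 by construction
    U, S, _ = np.linalg.svd(fitted, full_matrices=False)
    scores = U[:, 0] * S[0]
    sd = scores.std(ddof=1)
    if sd == 0:
        raise ValueError("constrained axis is degenerate (no explained variation)")
    scores = scores / sd
    if np.corrcoef(scores, q)[0, 1] < 0:
        scores = -scores
    var_explained = float(S[0] ** 2 / (Yr**2).sum()) if (Yr**2).sum() > 0 else 0.0
    return ConstrainedAxis(
        scores=pd.Series(scores, index=idx, name=f"pc_{constraint.name}"),
        variance_explained=var_explained,
        constraint=str(constraint.name),
        conditioners=tuple(conditioners.columns) if conditioners is not None else (),
    )


def axis_disease_assoc(axis: ConstrainedAxis, frame: pd.DataFrame) -> dict:
    """ML logistic record: disease ~ axis score + library size + Bristol + age + sex + energy."""
    sub = frame.set_index("participant_id").join(axis.scores.rename("_axis"), how="inner")
    covs = ["library_size_10k", "bristol", "age_ffq", "sex", "energy"]
    sub = sub.dropna(subset=["_axis", "status", *covs])
    X = design_matrix(sub, ["_axis", *covs])
    fit = fit_glm(sub["status"], X, family="binomial")
    i = fit.names.index("_axis")
    est, se = float(fit.params[i]), float(fit.se[i])
    return {
        "outcome": "disease",
        "term": axis.scores.name,
        "estimate": est,
        "se": se,
        "ci_lo": est - 1.96 * se,
        "ci_hi": est + 1.96 * se,
        "or": float(np.exp(est)),
        "or_lo": float(np.exp(est - 1.96 * se)),
        "or_hi": float(np.exp(est + 1.96 * se)),
        "p": float(fit.pvalues[i]),
        "n": len(sub),
        "converged": fit.converged,
    }
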