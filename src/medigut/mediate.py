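"""Quasi-Bayesian causal mediation for a binary outcome and a continuous mediator.

Within the potential-outcomes framework, the exposure (a diet measure) can
affect disease both directly and through a mediator (a taxon's CLR
abundance). Two fitted models are combined:

* a Gaussian mediator model  ``m ~ diet + covariates``
* a logistic outcome model   ``disease ~ diet + m + covariates``

Parameter uncertainty is propagated by drawing both coefficient vectors
from multivariate normals centred at the estimates with the fits'
covariances (the quasi-Bayesian approximation). For each draw,
counterfactual mediator values ``m(a)`` are simulated at the control and
treated exposure levels — including Gaussian residual noise at the fitted
residual SD, which is required for correct averaging through the
nonlinear (logistic) outcome model — and each participant's outcome
probability ``p(a, m(a'))`` is evaluated on the four exposure/mediator
combinations. The average causal mediation effect (ACME, indirect),
average direct effect (ADE) and total effect (TE) on the probability
scale satisfy ``TE = ACME + ADE`` exactly within every draw; reported
point estimates are means over draws with percentile confidence
intervals and a Monte-Carlo two-sided p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .robust import GlmFit

__all__ = [
    "MediationConfig",
    "MediationResult",
    "quasi_bayes_draws",
    "estimate_mediation",
    "classify_mediation",
]


@dataclass
class MediationConfig:
    """Monte-Carlo settings for one mediation analysis.

    ``treat_value``/``control_value`` are the two exposure levels compared
    (default 1 and 0, i.e. one unit — one SD for a standardized diet
    measure, one point for the raw aMED score).
    """

    n_draws: int = 10_000
    seed: int = 0
    treat_value: float = 1.0
    control_value: float = 0.0
    ci_level: float = 0.95

    def __post_init__(self):
        if self.n_draws < 1000:
            raise ValueError("n_draws must be >= 1000 for stable interval estimates")
        if self.treat_value == self.control_value:
            raise ValueError("treat_value must differ from control_value")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")


@dataclass
class MediationResult:
    """Indirect/direct/total effects on probability-difference and OR scales."""

    acme_diff: float
    ade_diff: float
    te_diff: float
    acme_ci: tuple
    ade_ci: tuple
    te_ci: tuple
    acme_p: float
    ade_p: float
    te_p: float
    acme_or: float
    ade_or: float
    te_or: float
    acme_or_ci: tuple
    ade_or_ci: tuple
    te_or_ci: tuple
    proportion_mediated: float
    proportion_mediated_stable: bool
    classification: str = "none"
    draws: pd.DataFrame | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "acme_diff", "ade_diff", "te_diff", "acme_p", "ade_p", "te_p",
            "acme_or", "ade_or", "te_or", "proportion_mediated",
            "proportion_mediated_stable", "classification")}
        for k in ("acme_ci", "ade_ci", "te_ci", "acme_or_ci", "ade_or_ci", "te_or_ci"):
            lo, hi = getattr(self, k)
            d[f"{k}_lo"], d[f"{k}_hi"] = lo, hi
        return d


def quasi_bayes_draws(fit: GlmFit, n_draws: int, seed: int) -> np.ndarray:
    """Draw coefficient vectors from N(estimates, fit covariance).

    Deterministic given the seed. A covariance matrix that is not positive
    semidefinite (beyond numerical noise) is rejected with a condition
    report.
    """
    if not fit.converged:
        raise ValueError("refusing to draw from a non-converged fit")
    cov = np.asarray(fit.cov, dtype=float)
    eig = np.linalg.eigvalsh(cov)
    if eig.min() < -1e-8 * max(eig.max(), 1.0):
        raise ValueError(
            f"covariance is not positive semidefinite (eigenvalues {eig.min():.3e}"
            f"..{eig.max():.3e}, condition {eig.max() / max(abs(eig.min()), 1e-300):.3e})"
        )
    if eig.min() < 0:  # clip numerical noise so the factorization is clean
        vals, vecs = np.linalg.eigh(cov)
        cov = (vecs * np.clip(vals, 0.0, None)) @ vecs.T
    rng = np.random.default_rng(seed)
    return rng.multivariate_normal(
        fit.params, cov, size=int(n_draws), method="svd", check_valid="ignore"
    )


def _mc_pvalue(draws: np.ndarray) -> float:
    """Two-sided Monte-Carlo p: 2 * min(frac <= 0, frac >= 0), capped at 1."""
    p = 2.0 * min(np.mean(draws <= 0.0), np.mean(draws >= 0.0))
    return float(min(p, 1.0))


def _odds(p):
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return p / (1.0 - p)


def estimate_mediation(
    mediator_fit: GlmFit,
    outcome_fit: GlmFit,
    X_mediator: pd.DataFrame,
    X_outcome: pd.DataFrame,
    diet_col: str,
    mediator_col: str,
    config: MediationConfig | None = None,
) -> MediationResult:
    """Estimate ACME, ADE and TE of a diet measure on disease through one taxon.

    Parameters
    ----------
    mediator_fit:
        Gaussian fit of the mediator on diet + covariates; its design is
        ``X_mediator`` (same column order as the fit).
    outcome_fit:
        Binomial fit of disease on diet + mediator + covariates; design
        ``X_outcome``.
    diet_col, mediator_col:
        Column names of the exposure (in both designs) and of the mediator
        (in the outcome design).
    """
    config = config or MediationConfig()
    if mediator_fit.family != "gaussian":
        raise ValueError("mediator model must be gaussian")
    if outcome_fit.family != "binomial":
        raise ValueError("outcome model must be binomial")
    if mediator_col not in X_outcome.columns:
        raise ValueError(f"mediator column {mediator_col!r} absent from the outcome design")
    for df, label in ((X_mediator, "mediator"), (X_outcome, "outcome")):
        if diet_col not in df.columns:
            raise ValueError(f"diet column {diet_col!r} absent from the {label} design")
    if list(X_mediator.columns) != list(mediator_fit.names):
        raise ValueError("X_mediator columns do not match the mediator fit")
    if list(X_outcome.columns) != list(outcome_fit.names):
        raise ValueError("X_outcome columns do not match the outcome fit")

    n = len(X_outcome)
    n_draws = config.n_draws
    rng_seed = np.random.default_rng(config.seed)
    seeds = rng_seed.integers(0, 2**31 - 1, size=3)
    theta_m = quasi_bayes_draws(mediator_fit, n_draws, int(seeds[0]))  # (D, pm)
    theta_y = quasi_bayes_draws(outcome_fit, n_draws, int(seeds[1]))   # (D, po)

    Xm = X_mediator.to_numpy(dtype=float)
    mcols = list(X_mediator.columns)
    j_diet_m = mcols.index(diet_col)
    Xm_t, Xm_c = Xm.copy(), Xm.copy()
    Xm_t[:, j_diet_m] = config.treat_value
    Xm_c[:, j_diet_m] = config.control_value

    # counterfactual mediators, common residual noise across the two arms
    noise = np.random.default_rng(int(seeds[2])).standard_normal((n_draws, n))
    sigma = mediator_fit.scale
    mu_t = theta_m @ Xm_t.T  # (D, n)
    mu_c = theta_m @ Xm_c.T
    m_t = mu_t + sigma * noise
    m_c = mu_c + sigma * noise

    Xo = X_outcome.to_numpy(dtype=float)
    ocols = list(X_outcome.columns)
    j_diet_o = ocols.index(diet_col)
    j_med_o = ocols.index(mediator_col)
    keep = [j for j in range(Xo.shape[1]) if j not in (j_diet_o, j_med_o)]
    base = theta_y[:, keep] @ Xo[:, keep].T  # (D, n): covariate part of eta
    b_diet = theta_y[:, j_diet_o][:, None]
    b_med = theta_y[:, j_med_o][:, None]

    def prob(a_value, m):
        return expit(base + b_diet * a_value + b_med * m)

    p_tt = prob(config.treat_value, m_t)
    p_tc = prob(config.treat_value, m_c)
    p_ct = prob(config.control_value, m_t)
    p_cc = prob(config.control_value, m_c)

    # per-draw participant means
    P = {k: v.mean(axis=1) for k, v in
         (("tt", p_tt), ("tc", p_tc), ("ct", p_ct), ("cc", p_cc))}
    delta_t = P["tt"] - P["tc"]   # ACME under treated
    delta_c = P["ct"] - P["cc"]   # ACME under control
    zeta_t = P["tt"] - P["ct"]    # ADE with mediator at m(t)
    zeta_c = P["tc"] - P["cc"]    # ADE with mediator at m(c)
    acme = 0.5 * (delta_t + delta_c)
    ade = 0.5 * (zeta_t + zeta_c)
    te = delta_t + zeta_c         # == delta_c + zeta_t == acme + ade per draw

    # odds-ratio scale from draw-wise mean counterfactual probabilities,
    # averaging the two decompositions on the log-OR scale
    or_acme = np.sqrt(_odds(P["tt"]) / _odds(P["tc"]) * _odds(P["ct"]) / _odds(P["cc"]))
    or_ade = np.sqrt(_odds(P["tt"]) / _odds(P["ct"]) * _odds(P["tc"]) / _odds(P["cc"]))
    or_te = _odds(P["tt"]) / _odds(P["cc"])

    alpha = 1.0 - config.ci_level
    qs = (100 * alpha / 2, 100 * (1 - alpha / 2))
    ci = lambda v: tuple(np.percentile(v, qs))

    te_ci = ci(te)
    te_excludes_zero = te_ci[0] > 0 or te_ci[1] < 0
    with np.errstate(divide="ignore", invalid="ignore"):
        pm_draws = np.where(te != 0, acme / te, np.nan)
    proportion_mediated = float(np.nanmedian(pm_draws))

    result = MediationResult(
        acme_diff=float(acme.mean()),
        ade_diff=float(ade.mean()),
        te_diff=float(te.mean()),
        acme_ci=ci(acme),
        ade_ci=ci(ade),
        te_ci=te_ci,
        acme_p=_mc_pvalue(acme),
        ade_p=_mc_pvalue(ade),
        te_p=_mc_pvalue(te),
        acme_or=float(or_acme.mean()),
        ade_or=float(or_ade.mean()),
        te_or=float(or_te.mean()),
        acme_or_ci=ci(or_acme),
        ade_or_ci=ci(or_ade),
        te_or_ci=ci(or_te),
        proportion_mediated=proportion_mediated,
        proportion_mediated_stable=bool(te_excludes_zero),
        draws=pd.DataFrame({"acme": acme, "ade": ade, "te": te}),
    )
    result.classification = classify_mediation(result)
    return result


def classify_mediation(result: MediationResult, alpha: float = 0.05) -> str:
    """Label a mediation result: consistent, competitive, or none.

    ``consistent`` — significant indirect effect with the same sign as the
    total effect (the mediator transmits part of the overall association).
    ``competitive`` — significant indirect effect opposing the total
    effect's sign (the mediator partially offsets it).
    """
    if result.acme_p >= alpha or result.acme_diff == 0:
        return "none"
    if np.sign(result.acme_diff) == np.sign(result.te_diff):
        return "consistent"
    return "competitive"
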