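"""Association screens: diet -> disease, taxa -> disease, diet -> taxa.

Three regression families, mirroring a case-control diet-microbiome
analysis:

* **diet -> disease** — ordinary ML logistic regression of case status on
  one diet measure at a time, adjusted for age at FFQ completion, sex and
  total energy intake.
* **taxa -> disease** — robust quasi-likelihood logistic regression of
  case status on one Z-scored taxon CLR value at a time, adjusted for
  library size, Bristol stool group, age and sex (plus presence/absence
  records for designated rarely-detected taxa).
* **diet -> taxa** — robust linear regression of each taxon's CLR value
  on one Z-scored diet measure, with the same covariates plus energy.

Every record carries the link-scale estimate, SE, Wald 95% CI and
two-sided p; Benjamini-Hochberg q-values are attached within each screen.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .robust import GlmFit, design_matrix, fit_glm
from .taxa import bristol_group, zscore

__all__ = [
    "bh_adjust",
    "build_analysis_frame",
    "screen_diet_disease",
    "screen_taxa_disease",
    "screen_diet_taxa",
    "select_mediator_candidates",
    "pairwise_spearman",
    "interaction_scan",
    "STRONG_ASSOCIATION_THRESHOLD",
]

#: absolute estimate labelled a "strong association" in reports
STRONG_ASSOCIATION_THRESHOLD = 0.70

_TAXA_COVARIATES = ["library_size_10k", "bristol", "age_ffq", "sex"]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    ``q_i = min over {j : p_(j) >= p_(i)} of p_(j) * m / j``, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def build_analysis_frame(
    participants: pd.DataFrame,
    ffq: pd.DataFrame,
    amed: pd.DataFrame | None = None,
    counts: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Merge metadata, intakes, aMED scores and stool covariates on participant id.

    Adds ``library_size_10k`` (total count / 10,000) and the categorical
    ``bristol`` group for participants with a stool sample.
    """
    frame = participants.merge(
        ffq.drop(columns=[c for c in ("sex", "energy") if c in ffq.columns]),
        on="participant_id",
        how="inner",
    )
    if amed is not None:
        frame = frame.merge(amed[["participant_id", "amed_score"]], on="participant_id", how="left")
    if counts is not None:
        libs = counts.sum(axis=1).rename("library_size")
        frame = frame.merge(libs, left_on="participant_id", right_index=True, how="left")
        frame["library_size_10k"] = frame["library_size"] / 1e4
    if "bristol_type" in frame.columns:
        frame["bristol"] = [
            bristol_group(t) if pd.notna(t) else np.nan for t in frame["bristol_type"]
        ]
    return frame


def _record_from_fit(fit: GlmFit, term: str, outcome: str, n: int) -> dict:
    i = fit.names.index(term)
    est, se = float(fit.params[i]), float(fit.se[i])
    lo, hi = est - 1.96 * se, est + 1.96 * se
    rec = {
        "outcome": outcome,
        "term": term,
        "estimate": est,
        "se": se,
        "ci_lo": lo,
        "ci_hi": hi,
        "p": float(fit.pvalues[i]),
        "n": n,
        "converged": fit.converged,
    }
    if fit.family == "binomial":
        rec["or"] = float(np.exp(est))
        rec["or_lo"], rec["or_hi"] = float(np.exp(lo)), float(np.exp(hi))
    return rec


def _finalize(records: list[dict]) -> pd.DataFrame:
    out = pd.DataFrame(records)
    if not out.empty:
        out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def screen_diet_disease(
    frame: pd.DataFrame,
    diet_vars,
    extra_covariates: tuple = (),
    standardize: tuple = (),
) -> pd.DataFrame:
    """One ML logistic record per diet measure: status ~ diet + age + sex + energy.

    Diet variables listed in ``standardize`` are Z-scored before modelling
    (used for continuous component intakes); binary component scores and
    the 0-7 aMED itself enter on their native scales. ``extra_covariates``
    adds e.g. race or overweight status.
    """
    records = []
    covs = ["age_ffq", "sex", "energy", *extra_covariates]
    for var in diet_vars:
        sub = frame.dropna(subset=[var, "status", *covs]).copy()
        if var in standardize:
            sub[var] = zscore(sub[var])
        X = design_matrix(sub, [var, *covs])
        fit = fit_glm(sub["status"], X, family="binomial")
        records.append(_record_from_fit(fit, var, "disease", len(sub)))
    return _finalize(records)


def screen_taxa_disease(
    frame: pd.DataFrame,
    clr: pd.DataFrame,
    taxa=None,
    presence: pd.DataFrame | None = None,
    robust: bool = True,
) -> pd.DataFrame:
    """Per-taxon (robust) logistic: status ~ taxon Z + library size + Bristol + age + sex.

    ``clr`` is indexed by participant id. Optional ``presence`` holds 0/1
    presence columns for designated taxa (modelled unstandardized).
    Zero-variance taxa are skipped with a log record in the result frame's
    ``attrs["skipped"]``.
    """
    taxa = list(clr.columns) if taxa is None else list(taxa)
    records, skipped = [], []
    merged = frame.set_index("participant_id")
    for taxon in taxa:
        sub = merged.join(clr[taxon].rename("_taxon"), how="inner").dropna(
            subset=["_taxon", "status", *_TAXA_COVARIATES]
        )
        if sub["_taxon"].nunique() < 2:
            skipped.append(taxon)
            continue
        sub = sub.copy()
        sub["_taxon"] = zscore(sub["_taxon"])
        X = design_matrix(sub, ["_taxon", *_TAXA_COVARIATES])
        fit = fit_glm(sub["status"], X, family="binomial", robust=robust)
        rec = _record_from_fit(fit, "_taxon", "disease", len(sub))
        rec["term"] = taxon
        records.append(rec)
    if presence is not None:
        for taxon in presence.columns:
            sub = merged.join(presence[taxon].rename("_pres"), how="inner").dropna(
                subset=["_pres", "status", *_TAXA_COVARIATES]
            )
            if sub["_pres"].nunique() < 2:
                skipped.append(f"presence:{taxon}")
                continue
            X = design_matrix(sub, ["_pres", *_TAXA_COVARIATES])
            fit = fit_glm(sub["status"], X, family="binomial", robust=False)
            rec = _record_from_fit(fit, "_pres", "disease", len(sub))
            rec["term"] = f"presence:{taxon}"
            records.append(rec)
    out = _finalize(records)
    out.attrs["skipped"] = skipped
    return out


def screen_diet_taxa(
    frame: pd.DataFrame,
    clr: pd.DataFrame,
    diet_vars,
    taxa=None,
    robust: bool = True,
) -> pd.DataFrame:
    """Per (diet, taxon) robust linear record: CLR ~ diet Z + covariates + energy.

    The diet measure is standardized; the taxon CLR outcome is not, so the
    estimate is the CLR change per 1-SD diet increase. Records whose
    absolute estimate reaches 0.70 carry ``strong = True``.
    """
    taxa = list(clr.columns) if taxa is None else list(taxa)
    records = []
    merged = frame.set_index("participant_id")
    covs = [*_TAXA_COVARIATES, "energy"]
    for var in diet_vars:
        for taxon in taxa:
            sub = merged.join(clr[taxon].rename("_clr"), how="inner").dropna(
                subset=["_clr", var, *covs]
            )
            sub = sub.copy()
            sub["_diet"] = zscore(sub[var])
            X = design_matrix(sub, ["_diet", *covs])
            fit = fit_glm(sub["_clr"], X, family="gaussian", robust=robust)
            rec = _record_from_fit(fit, "_diet", taxon, len(sub))
            rec["term"] = var
            rec["strong"] = abs(rec["estimate"]) >= STRONG_ASSOCIATION_THRESHOLD
            records.append(rec)
    return _finalize(records)


def select_mediator_candidates(
    diet_taxa_records: pd.DataFrame,
    taxa_disease_records: pd.DataFrame,
    diet_vars=("amed_score", "fiber"),
    alpha: float = 0.05,
) -> list:
    """Taxa significantly tied (raw P < alpha) to diet AND to disease.

    The diet side requires P < alpha for at least one of ``diet_vars`` in
    the diet->taxa screen; the disease side requires P < alpha in the
    taxa->disease screen (abundance records, not presence flags).
    """
    dt = diet_taxa_records[diet_taxa_records["term"].isin(diet_vars)]
    diet_hits = set(dt.loc[dt["p"] < alpha, "outcome"])
    td = taxa_disease_records[~taxa_disease_records["term"].astype(str).str.startswith("presence:")]
    disease_hits = set(td.loc[td["p"] < alpha, "term"])
    ordered = [t for t in taxa_disease_records["term"] if t in diet_hits & disease_hits]
    return ordered


def pairwise_spearman(table: pd.DataFrame) -> pd.DataFrame:
    """Spearman rank correlation for every pair of numeric columns (ties mid-ranked).

    Constant columns yield NaN entries (flagged in ``attrs["undefined"]``).
    """
    num = table.select_dtypes(include=[np.number])
    if len(num) < 3:
        raise ValueError("need at least 3 rows for rank correlations")
    cols = list(num.columns)
    rho = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    undefined = [c for c in cols if num[c].nunique() < 2]
    for i, a in enumerate(cols):
        for j in range(i + 1, len(cols)):
            b = cols[j]
            if a in undefined or b in undefined:
                val = np.nan
            else:
                val = stats.spearmanr(num[a], num[b]).statistic
            rho.loc[a, b] = rho.loc[b, a] = val
    rho.attrs["undefined"] = undefined
    return rho


def interaction_scan(frame: pd.DataFrame, diet_vars) -> pd.DataFrame:
    """Test diet x age and diet x sex interactions on disease odds.

    For each diet measure, refits the diet->disease logistic model with a
    product term and reports the interaction coefficient's record.
    """
    records = []
    for var in diet_vars:
        sub = frame.dropna(subset=[var, "status", "age_ffq", "sex", "energy"]).copy()
        sub["_sex_num"] = (sub["sex"].astype(str) == "F").astype(float)
        for mod, modcol in (("age", "age_ffq"), ("sex", "_sex_num")):
            sub[f"_{var}_x_{mod}"] = sub[var] * sub[modcol]
            X = design_matrix(sub, [var, "age_ffq", "_sex_num", "energy", f"_{var}_x_{mod}"])
            fit = fit_glm(sub["status"], X, family="binomial")
            rec = _record_from_fit(fit, f"_{var}_x_{mod}", "disease", len(sub))
            rec["term"] = f"{var}:{mod}"
            records.append(rec)
    return _finalize(records)
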