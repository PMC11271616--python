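"""Cohort eligibility filtering and end-to-end orchestration.

Two nested analysis sets are formed before any statistics:

* **Diet group** — participants whose FFQ was completed before age 22 and
  passes the FFQ quality exclusions (missing items, implausible energy).
* **Diet-microbiota subgroup** — Diet-group members with a stool sample
  within +/-90 days of the FFQ (inclusive) and no antibiotic or
  corticosteroid exposure in the 30 days before stool collection. When a
  participant has several eligible stool/FFQ records the earliest stool
  sample is kept.

``run_all`` chains simulation (optional), diet scoring, taxa preparation,
the three association screens, mediation of selected candidates, and the
ordination analyses, writing per-stage TSVs plus a JSON summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diet import apply_ffq_exclusions, compute_sex_specific_medians, score_amed
from .mediate import MediationConfig, estimate_mediation
from .ordinate import aitchison_distance, axis_disease_assoc, constrained_axis, permanova_marginal
from .robust import design_matrix, fit_glm
from .screen import (
    build_analysis_frame,
    screen_diet_disease,
    screen_diet_taxa,
    screen_taxa_disease,
    select_mediator_candidates,
)
from .synth import SimulationConfig, generate_cohort, write_cohort
from .taxa import clr_transform, filter_by_prevalence

log = logging.getLogger("medigut")

__all__ = ["EligibilityRule", "RunConfig", "eligibility_filter", "run_all", "load_tables"]


@dataclass
class EligibilityRule:
    """Cut-offs defining the Diet group and Diet-microbiota subgroup."""

    ffq_age_max: float = 22.0        # exclusive: age at FFQ must be < this
    stool_window_days: int = 90      # inclusive on both ends
    med_washout_days: int = 30       # antibiotics/corticosteroids before stool
    multiple_records_rule: str = "earliest"

    def __post_init__(self):
        if min(self.ffq_age_max, self.stool_window_days, self.med_washout_days) <= 0:
            raise ValueError("eligibility thresholds must be positive")


@dataclass
class RunConfig:
    """Everything one pipeline run needs; round-trips losslessly to YAML."""

    out_dir: str = "medigut_out"
    metadata_path: str | None = None
    ffq_path: str | None = None
    counts_path: str | None = None
    simulate: bool = True
    seed: int = 0
    n_cases: int = 44
    n_controls: int = 51
    n_taxa: int = 50
    pseudo_count: float = 0.5
    min_rel_abundance: float = 1e-4
    min_frac_samples: float = 0.10
    mediation_draws: int = 10_000
    n_permutations: int = 999
    diet_vars: tuple = ("amed_score", "whole_grains", "fiber", "iron")
    mediation_diet_vars: tuple = ("amed_score", "fiber")
    candidate_alpha: float = 0.05
    rules: EligibilityRule = field(default_factory=EligibilityRule)

    def to_yaml(self, path) -> None:
        payload = asdict(self)
        payload["diet_vars"] = list(self.diet_vars)
        payload["mediation_diet_vars"] = list(self.mediation_diet_vars)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        rules = EligibilityRule(**payload.pop("rules", {}))
        payload["diet_vars"] = tuple(payload.get("diet_vars", cls.diet_vars))
        payload["mediation_diet_vars"] = tuple(
            payload.get("mediation_diet_vars", cls.mediation_diet_vars)
        )
        return cls(rules=rules, **payload)


def _dates(series: pd.Series) -> pd.Series:
    return pd.to_datetime(series, format="ISO8601", errors="coerce")


def eligibility_filter(
    participants: pd.DataFrame,
    ffq: pd.DataFrame,
    rules: EligibilityRule | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Partition the roster into Diet group, Diet-microbiota subgroup and exclusions.

    Returns ``(diet_group, subgroup, exclusion_log)``; the log has one row
    per (participant, reason) and, together with the kept sets, exactly
    partitions the input roster.
    """
    rules = rules or EligibilityRule()
    log_rows = []

    # collapse multiple records per participant: earliest stool sample first
    work = participants.copy()
    work["_stool"] = _dates(work.get("stool_date"))
    if work["participant_id"].duplicated().any():
        if rules.multiple_records_rule != "earliest":
            raise ValueError(f"unknown multiple-records rule {rules.multiple_records_rule!r}")
        order = work["_stool"].fillna(pd.Timestamp.max)
        work = (
            work.assign(_order=order)
            .sort_values(["participant_id", "_order"])
            .drop_duplicates("participant_id", keep="first")
            .drop(columns="_order")
        )

    # Diet group: age cap + FFQ quality
    age_ok = work["age_ffq"] < rules.ffq_age_max
    for pid in work.loc[~age_ok, "participant_id"]:
        log_rows.append({"participant_id": pid, "stage": "diet_group", "reason": "ffq_after_age_cap"})
    kept_ffq, excluded_ffq = apply_ffq_exclusions(
        ffq[ffq["participant_id"].isin(work.loc[age_ok, "participant_id"])]
    )
    for exc in excluded_ffq:
        for reason in exc.reasons:
            log_rows.append(
                {"participant_id": exc.participant_id, "stage": "diet_group", "reason": reason}
            )
    diet_ids = set(kept_ffq["participant_id"])
    diet_group = work[work["participant_id"].isin(diet_ids)].drop(columns="_stool")

    # subgroup: stool within the window, medication washout
    sub_rows = []
    ffq_dates = _dates(work.set_index("participant_id")["ffq_date"])
    stool_dates = work.set_index("participant_id")["_stool"]
    med_dates = _dates(work.set_index("participant_id").get("med_exposure_date"))
    for pid in diet_group["participant_id"]:
        row = work.loc[work["participant_id"] == pid].iloc[0]
        if not bool(row.get("has_stool", pd.notna(stool_dates[pid]))):
            log_rows.append({"participant_id": pid, "stage": "subgroup", "reason": "no_stool_sample"})
            continue
        if pd.isna(stool_dates[pid]):
            log_rows.append({"participant_id": pid, "stage": "subgroup", "reason": "missing_stool_date"})
            continue
        gap = abs((stool_dates[pid] - ffq_dates[pid]).days)
        if gap > rules.stool_window_days:
            log_rows.append({"participant_id": pid, "stage": "subgroup", "reason": "stool_outside_window"})
            continue
        med = med_dates.get(pid, pd.NaT)
        if pd.notna(med):
            lead = (stool_dates[pid] - med).days
            if 0 <= lead <= rules.med_washout_days:
                log_rows.append(
                    {"participant_id": pid, "stage": "subgroup", "reason": "recent_medication"}
                )
                continue
        sub_rows.append(pid)
    subgroup = diet_group[diet_group["participant_id"].isin(sub_rows)]
    exclusion_log = pd.DataFrame(log_rows, columns=["participant_id", "stage", "reason"])
    return diet_group, subgroup, exclusion_log


def load_tables(config: RunConfig):
    """Read the three input TSVs named in the config."""
    for attr in ("metadata_path", "ffq_path", "counts_path"):
        if getattr(config, attr) is None:
            raise ValueError(f"{attr} must be set when simulate is off")
    participants = pd.read_csv(config.metadata_path, sep="\t")
    ffq = pd.read_csv(config.ffq_path, sep="\t")
    counts = pd.read_csv(config.counts_path, sep="\t", index_col=0)
    return participants, ffq, counts


def run_all(config: RunConfig) -> dict:
    """Execute every stage and write the report bundle; returns the summary dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    stage_seeds = {k: int(s) for k, s in zip(
        ("simulate", "mediation", "permanova"), rng.integers(0, 2**31 - 1, 3)
    )}

    if config.simulate:
        sim = SimulationConfig(
            n_cases=config.n_cases, n_controls=config.n_controls,
            n_taxa=config.n_taxa, seed=stage_seeds["simulate"],
        )
        cohort = generate_cohort(sim)
        write_cohort(cohort, out / "synthetic_inputs")
        participants, ffq, counts = cohort.participants, cohort.ffq, cohort.counts
    else:
        participants, ffq, counts = load_tables(config)

    diet_group, subgroup, exclusion_log = eligibility_filter(participants, ffq, config.rules)
    exclusion_log.to_csv(out / "exclusions.tsv", sep="\t", index=False)
    log.info("diet group n=%d, subgroup n=%d, exclusions=%d",
             len(diet_group), len(subgroup), len(exclusion_log))

    # diet scoring against eligible-control medians
    ffq_diet = ffq[ffq["participant_id"].isin(diet_group["participant_id"])]
    status = diet_group.set_index("participant_id")["status"]
    controls_ffq = ffq_diet[status.reindex(ffq_diet["participant_id"]).to_numpy() == 0]
    medians = compute_sex_specific_medians(controls_ffq)
    amed = score_amed(ffq_diet, medians)
    amed.to_csv(out / "amed_scores.tsv", sep="\t", index=False)

    # taxa prep on subgroup stool samples
    sub_counts = counts.loc[counts.index.intersection(subgroup["participant_id"])]
    clr = clr_transform(sub_counts, pseudo=config.pseudo_count)
    retained = filter_by_prevalence(
        sub_counts, min_rel=config.min_rel_abundance, min_frac_samples=config.min_frac_samples
    )
    clr.to_csv(out / "clr.tsv", sep="\t")

    frame_diet = build_analysis_frame(diet_group, ffq_diet, amed)
    frame_sub = build_analysis_frame(
        subgroup, ffq_diet, amed, counts=sub_counts
    )

    diet_disease = screen_diet_disease(frame_diet, config.diet_vars)
    taxa_disease = screen_taxa_disease(frame_sub, clr, taxa=retained)
    diet_taxa = screen_diet_taxa(frame_sub, clr, config.mediation_diet_vars, taxa=retained)
    diet_disease.to_csv(out / "screen_diet_disease.tsv", sep="\t", index=False)
    taxa_disease.to_csv(out / "screen_taxa_disease.tsv", sep="\t", index=False)
    diet_taxa.to_csv(out / "screen_diet_taxa.tsv", sep="\t", index=False)

    candidates = select_mediator_candidates(
        diet_taxa, taxa_disease, diet_vars=config.mediation_diet_vars,
        alpha=config.candidate_alpha,
    )
    mediation_rows = []
    med_seed = np.random.default_rng(stage_seeds["mediation"])
    for diet_var in config.mediation_diet_vars:
        for taxon in candidates:
            res = _mediate_one(frame_sub, clr, diet_var, taxon,
                               config.mediation_draws, int(med_seed.integers(0, 2**31 - 1)))
            row = {"diet": diet_var, "taxon": taxon, **res.to_dict()}
            mediation_rows.append(row)
    mediation_table = pd.DataFrame(mediation_rows)
    mediation_table.to_csv(out / "mediation.tsv", sep="\t", index=False)

    # ordination: variance partition + constrained axes
    dist = aitchison_distance(clr)
    fsub = frame_sub.set_index("participant_id").loc[clr.index]
    permanova_vars = {
        "race": fsub["race"], "fruit": fsub["fruit"], "fiber": fsub["fiber"],
        "amed_score": fsub["amed_score"], "status": fsub["status"],
    }
    pseed = np.random.default_rng(stage_seeds["permanova"])
    partition = []
    for name, series in permanova_vars.items():
        rec = permanova_marginal(dist, series.rename(name), n_perm=config.n_permutations,
                                 seed=int(pseed.integers(0, 2**31 - 1)))
        partition.append(asdict(rec))
    partition_table = pd.DataFrame(partition)
    partition_table.to_csv(out / "variance_partition.tsv", sep="\t", index=False)

    axis_records = []
    for var in config.mediation_diet_vars:
        axis = constrained_axis(clr, fsub[var].rename(var))
        axis.scores.to_csv(out / f"axis_{var}.tsv", sep="\t")
        axis_records.append({**axis_disease_assoc(axis, frame_sub),
                             "variance_explained": axis.variance_explained})
    axis_table = pd.DataFrame(axis_records)
    axis_table.to_csv(out / "axis_disease.tsv", sep="\t", index=False)

    summary = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": stage_seeds,
        "n_diet_group": int(len(diet_group)),
        "n_subgroup": int(len(subgroup)),
        "n_taxa_retained": len(retained),
        "diet_disease": diet_disease.to_dict(orient="records"),
        "mediator_candidates": candidates,
        "mediation": mediation_table.to_dict(orient="records"),
        "variance_partition": partition_table.to_dict(orient="records"),
        "axis_disease": axis_table.to_dict(orient="records"),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=str))
    return summary


def _mediate_one(frame_sub, clr, diet_var, taxon, n_draws, seed,
                 robust: bool = False):
    """Fit mediator/outcome models for one (diet, taxon) pair and mediate."""
    sub = frame_sub.set_index("participant_id").join(clr[taxon].rename("_m"), how="inner")
    covs = ["energy", "library_size_10k", "bristol", "age_ffq", "sex"]
    sub = sub.dropna(subset=["_m", diet_var, "status", *covs]).copy()
    if diet_var != "amed_score":  # continuous nutrients enter standardized
        sd = sub[diet_var].std(ddof=1)
        sub[diet_var] = (sub[diet_var] - sub[diet_var].mean()) / sd
    Xm = design_matrix(sub, [diet_var, *covs])
    Xo = design_matrix(sub, [diet_var, "_m", *covs])
    mfit = fit_glm(sub["_m"], Xm, family="gaussian", robust=robust)
    ofit = fit_glm(sub["status"], Xo, family="binomial", robust=robust)
    return estimate_mediation(
        mfit, ofit, Xm, Xo, diet_col=diet_var, mediator_col="_m",
        config=MediationConfig(n_draws=n_draws, seed=seed),
    )
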