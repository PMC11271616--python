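"""FFQ eligibility filters and the 7-component alternative Mediterranean diet score.

The aMED score used here has seven components: fruit, vegetables, legumes,
whole-grain foods, fish, processed-and-red meat combined, and the
MUFA:SFA ratio. (Nuts and ethanol, present in the 9-component original,
are structurally absent because the food-frequency instrument does not
capture them; the maximum score remains 7.) One point is awarded when
intake strictly exceeds the sex-specific median intake of the controls —
strictly below the median for meat, the only "unhealthy" component — and
zero points on exact equality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "HEALTHY_COMPONENTS",
    "MEAT_COMPONENT",
    "AMED_COMPONENTS",
    "FfqExclusion",
    "apply_ffq_exclusions",
    "compute_sex_specific_medians",
    "score_amed",
    "dichotomize_components",
]

#: components scored "1 point if intake > median"
HEALTHY_COMPONENTS = (
    "fruit",
    "vegetables",
    "legumes",
    "whole_grain_foods",
    "fish",
    "mufa_sfa",
)
#: the single reverse-scored component: "1 point if intake < median"
MEAT_COMPONENT = "processed_red_meat"
AMED_COMPONENTS = HEALTHY_COMPONENTS + (MEAT_COMPONENT,)

# eligibility cut-offs for a usable FFQ record
MAX_MISSING_ITEMS = 15          # >= this many missing answers -> excluded
ENERGY_LOW_KCAL = 500.0         # exclusive lower bound on plausible energy
ENERGY_HIGH_KCAL = 3500.0       # exclusive upper bound


@dataclass
class FfqExclusion:
    """One excluded FFQ record with machine-readable reason codes."""

    participant_id: object
    reasons: list = field(default_factory=list)


def _require_columns(df: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"FFQ table is missing required columns: {missing}")


def apply_ffq_exclusions(records: pd.DataFrame) -> tuple[pd.DataFrame, list[FfqExclusion]]:
    """Drop FFQ records with too many missing items or implausible energy.

    A record is excluded iff ``n_missing_items >= 15`` or total energy is
    below 500 or above 3500 kcal/day. A record whose energy is missing is
    excluded with reason ``"unassessable"``.

    Returns ``(kept, excluded)`` where *kept* preserves the input row order
    and *excluded* lists one :class:`FfqExclusion` per dropped record.
    """
    _require_columns(records, ["participant_id", "energy", "n_missing_items"])
    excluded: list[FfqExclusion] = []
    keep_mask = []
    for _, row in records.iterrows():
        reasons = []
        energy = row["energy"]
        if pd.isna(energy):
            reasons.append("unassessable")
        else:
            if energy < ENERGY_LOW_KCAL:
                reasons.append("low_energy")
            if energy > ENERGY_HIGH_KCAL:
                reasons.append("high_energy")
        if not pd.isna(row["n_missing_items"]) and row["n_missing_items"] >= MAX_MISSING_ITEMS:
            reasons.append("too_many_missing_items")
        keep_mask.append(not reasons)
        if reasons:
            excluded.append(FfqExclusion(row["participant_id"], reasons))
    kept = records.loc[np.asarray(keep_mask, dtype=bool)].copy()
    return kept, excluded


def _with_ratio(records: pd.DataFrame) -> pd.DataFrame:
    """Attach the per-participant MUFA:SFA ratio column."""
    _require_columns(records, ["mufa", "sfa"])
    out = records.copy()
    if (out["sfa"] <= 0).any():
        bad = out.loc[out["sfa"] <= 0, "participant_id"].tolist()
        raise ValueError(f"non-positive SFA intake, MUFA:SFA undefined for: {bad}")
    out["mufa_sfa"] = out["mufa"] / out["sfa"]
    return out


def compute_sex_specific_medians(controls: pd.DataFrame) -> pd.DataFrame:
    """Per-sex, per-component median intakes among controls.

    The MUFA:SFA ratio is formed per participant *before* the median is
    taken. Even-n medians use the midpoint of the two central order
    statistics. Returns a frame indexed by sex with one column per aMED
    component.

    Raises if any sex stratum present in the data has no control records
    (every sex that appears must contribute at least one row).
    """
    base_cols = [c for c in AMED_COMPONENTS if c != "mufa_sfa"]
    _require_columns(controls, ["sex"] + base_cols)
    if controls.empty:
        raise ValueError("no control records to compute medians from")
    ratio = _with_ratio(controls)
    medians = ratio.groupby("sex")[list(AMED_COMPONENTS)].median()
    if medians.isna().any().any():
        raise ValueError("missing component intakes prevent median computation")
    return medians


def _component_points(record: pd.Series, medians_for_sex: pd.Series) -> pd.Series:
    points = {}
    for comp in HEALTHY_COMPONENTS:
        points[comp] = int(record[comp] > medians_for_sex[comp])
    points[MEAT_COMPONENT] = int(record[MEAT_COMPONENT] < medians_for_sex[MEAT_COMPONENT])
    return pd.Series(points, dtype=int)


def score_amed(records: pd.DataFrame, medians: pd.DataFrame) -> pd.DataFrame:
    """Score the 0-7 aMED for each record against sex-specific control medians.

    Returns one row per input record: ``participant_id``, the seven binary
    component points, and their sum ``amed_score``.
    """
    base_cols = [c for c in AMED_COMPONENTS if c != "mufa_sfa"]
    _require_columns(records, ["participant_id", "sex"] + base_cols)
    ratio = _with_ratio(records)
    rows = []
    for _, record in ratio.iterrows():
        sex = record["sex"]
        if sex not in medians.index:
            raise ValueError(f"no control medians available for sex {sex!r}")
        points = _component_points(record, medians.loc[sex])
        row = {"participant_id": record["participant_id"], **points.to_dict()}
        row["amed_score"] = int(points.sum())
        rows.append(row)
    out = pd.DataFrame(rows)
    return out.set_index(records.index)


def dichotomize_components(records: pd.DataFrame, medians: pd.DataFrame) -> pd.DataFrame:
    """Per-component binary scores (same above/below-median rule as the aMED).

    Identical cut-offs to :func:`score_amed`, emitted per component for use
    as separate regression terms.
    """
    scored = score_amed(records, medians)
    return scored[["participant_id", *AMED_COMPONENTS]]
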