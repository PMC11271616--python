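"""Synthetic case-control cohorts with diet-microbiota-disease structure.

The generator emulates the *post-bioinformatics* state of a pediatric
case-control diet-microbiome study: a metadata table, an FFQ-derived
intake table, and a samples x taxa count table, together with a ground
truth record of every effect used.

Generative model (per super-population individual):

1. A latent diet-healthfulness ``h ~ N(0, 1)`` drives the seven
   Mediterranean-diet food components (log-normal around sex-specific
   medians, meat loaded negatively) and fiber, whole-grain and iron
   intakes. The realized aMED score is the count of components beyond
   their sex-specific population medians; the fiber loading is calibrated
   so that Spearman rho(fiber, aMED) is about 0.71 at large n.
2. Taxon log-abundances are ``baseline_j + gamma_j * s + noise`` where
   ``s`` is the standardized realized aMED score; a softmax converts them
   to composition, and counts are drawn multinomially at a log-normal
   library size. Driving taxa by the realized score (rather than by ``h``
   itself) makes the diet -> taxa path a genuine mediation path, so the
   true mediated effect of "set the aMED to a" is well defined.
3. Disease status follows a logistic model with a direct diet effect
   (``beta_direct`` log-odds per aMED point), taxon effects ``b_j`` per
   CLR unit, and age/sex/energy covariate effects.
4. The case-control sample is drawn by rejection from the
   super-population until the requested numbers of cases and controls are
   reached. As in any case-control design the logistic intercept is
   design-biased; slope coefficients remain consistent.

``oracle_acme`` computes the true average causal mediation effect for a
taxon by direct counterfactual simulation at the true parameters; it is
the independent oracle for mediation-recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SyntheticCohort",
    "generate_cohort",
    "oracle_acme",
    "write_cohort",
    "default_effects",
]

# ---------------------------------------------------------------------------
# generator constants (fixed study conditions, not tuning knobs)

#: sex-specific population median intakes (g/day except noted); males +15%
_COMPONENT_MEDIANS_F = {
    "fruit": 150.0,
    "vegetables": 120.0,
    "legumes": 10.0,
    "whole_grain_foods": 50.0,
    "fish": 20.0,
    "processed_red_meat": 80.0,
}
_MALE_INTAKE_FACTOR = 1.15

#: loading of log-intake on the latent healthfulness h and residual log-SD.
#: meat loads negatively (healthier eaters consume less of it).
_COMPONENT_LOADING = {
    "fruit": 0.41,
    "vegetables": 0.375,
    "legumes": 0.34,
    "whole_grain_foods": 0.375,
    "fish": 0.26,
    "processed_red_meat": -0.34,
}
_COMPONENT_RESID_SD = {
    "fruit": 0.45,
    "vegetables": 0.45,
    "legumes": 0.60,
    "whole_grain_foods": 0.50,
    "fish": 0.60,
    "processed_red_meat": 0.45,
}

# MUFA:SFA — the ratio's log loads on h, SFA roughly flat
_MUFA_SFA_LOADING = 0.26
_MUFA_SFA_RESID_SD = 0.40

#: fiber loading calibrated so Spearman rho(fiber, aMED) ~ 0.71 at n = 2000
_FIBER_MEDIAN = 10.5        # g/day
_FIBER_LOADING = 0.52
_FIBER_RESID_SD = 0.26
_IRON_MEDIAN = 8.0          # mg/day
_IRON_LOADING = 0.25
_IRON_RESID_SD = 0.35
_WHOLE_GRAINS_MEDIAN = 0.40  # oz-equivalents/day
_ENERGY_MEDIAN = 1100.0      # kcal/day
_ENERGY_LOG_SD = 0.41

_TAXA_NOISE_SD = 0.60        # per-taxon log-abundance residual SD
_BASELINE_SLOPE = -0.15      # geometric rank-abundance profile

#: Bristol stool types 1..7, roughly hard 20% / medium 73% / loose 7%
_BRISTOL_PROBS = np.array([0.08, 0.12, 0.20, 0.30, 0.23, 0.05, 0.02])

_DISEASE_INTERCEPT = -2.2    # super-population intercept (design-biased in the sample)
_MAX_BATCHES = 500


def default_effects(n_taxa: int) -> tuple[np.ndarray, np.ndarray]:
    """Default diet->taxon (gamma) and taxon->disease (b) effect vectors.

    Three mediator taxa (one diet-enriched protective, one diet-depleted
    risk taxon, one competitive), one diet-only and one disease-only
    taxon; all other paths zero.
    """
    if n_taxa < 16:
        raise ValueError("default effect pattern needs n_taxa >= 16")
    gamma = np.zeros(n_taxa)
    b = np.zeros(n_taxa)
    gamma[2], b[2] = 0.9, -0.8    # fiber-fed, protective (consistent mediator)
    gamma[5], b[5] = -0.8, 0.9    # depleted by healthy diet, raises risk (consistent)
    gamma[8], b[8] = 0.6, 0.7     # enriched by healthy diet, raises risk (competitive)
    gamma[12] = 0.7               # diet-associated only
    b[15] = 0.6                   # disease-associated only
    return gamma, b


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort generator."""

    n_cases: int = 44
    n_controls: int = 51
    n_taxa: int = 50
    seed: int = 0
    beta_direct: float = float(np.log(0.66))  # log-odds per aMED point
    gamma: np.ndarray | None = None           # diet -> taxon, log-abundance per SD of aMED
    b: np.ndarray | None = None               # taxon -> disease, log-odds per CLR unit
    target_rho_fiber_amed: float = 0.71
    library_size_mean: float = 20_000.0
    library_size_dispersion: float = 0.35     # log-scale SD
    covariate_effects: dict = field(
        default_factory=lambda: {"age": 0.08, "sex_female": 0.30, "log_energy": 0.0}
    )
    missingness_rate: float = 0.03
    stool_fraction: float = 0.62
    intercept: float = _DISEASE_INTERCEPT

    def __post_init__(self):
        if self.n_cases + self.n_controls < 10:
            raise ValueError("n_cases + n_controls must be at least 10")
        if self.library_size_mean <= 0 or self.library_size_dispersion <= 0:
            raise ValueError("library size parameters must be positive")
        if not 0.0 <= self.missingness_rate <= 1.0:
            raise ValueError("missingness_rate must be in [0, 1]")
        if not 0.0 <= self.target_rho_fiber_amed <= 1.0:
            raise ValueError("target_rho_fiber_amed must be in [0, 1]")
        if self.gamma is None or self.b is None:
            g, bb = default_effects(self.n_taxa)
            if self.gamma is None:
                self.gamma = g
            if self.b is None:
                self.b = bb
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if len(self.gamma) != self.n_taxa or len(self.b) != self.n_taxa:
            raise ValueError("gamma and b must each have length n_taxa")


@dataclass
class GroundTruth:
    """True effects behind a cohort, plus counterfactual mediation oracles."""

    beta_direct: float
    gamma: np.ndarray
    b: np.ndarray
    covariate_effects: dict
    intercept: float
    amed_mean: float
    amed_sd: float
    oracle_acme_diff: np.ndarray | None = None  # per taxon; None until computed
    oracle_ade_diff: np.ndarray | None = None
    amed_true: pd.Series | None = None          # generation-time aMED of sampled cohort


@dataclass
class SyntheticCohort:
    participants: pd.DataFrame
    ffq: pd.DataFrame
    counts: pd.DataFrame
    truth: GroundTruth


# ---------------------------------------------------------------------------


def _amed_sd() -> float:
    """SD of the generation-time aMED via Gauss-Hermite quadrature.

    Component points given h are independent Bernoulli(Phi(a_k h)) with
    effective loading a_k = |loading_k| / resid_sd_k (meat's reverse rule
    flips its negative loading back to positive). The mean is exactly 3.5.
    """
    a = [abs(_COMPONENT_LOADING[k]) / _COMPONENT_RESID_SD[k] for k in _COMPONENT_LOADING]
    a.append(_MUFA_SFA_LOADING / _MUFA_SFA_RESID_SD)
    a = np.asarray(a)
    nodes, weights = np.polynomial.hermite_e.hermegauss(61)
    weights = weights / np.sqrt(2 * np.pi)
    ph = norm.cdf(np.outer(nodes, a))  # (q, 7)
    var_within = (ph * (1 - ph) * weights[:, None]).sum()
    mean_h = ph.sum(axis=1)
    var_between = (weights * (mean_h - 3.5) ** 2).sum()
    return float(np.sqrt(var_within + var_between))


_AMED_MEAN = 3.5
_AMED_SD = _amed_sd()


def _draw_components(rng, h, male):
    """Log-normal component intakes; returns dict of arrays plus point flags."""
    intakes = {}
    points = {}
    for comp, lam in _COMPONENT_LOADING.items():
        sd = _COMPONENT_RESID_SD[comp]
        shift = lam * h + sd * rng.standard_normal(h.size)
        med = _COMPONENT_MEDIANS_F[comp] * np.where(male, _MALE_INTAKE_FACTOR, 1.0)
        intakes[comp] = med * np.exp(shift)
        if comp == "processed_red_meat":
            points[comp] = (shift < 0).astype(int)
        else:
            points[comp] = (shift > 0).astype(int)
    # MUFA:SFA via correlated fat intakes
    ratio_shift = _MUFA_SFA_LOADING * h + _MUFA_SFA_RESID_SD * rng.standard_normal(h.size)
    sfa = 14.0 * np.exp(0.30 * rng.standard_normal(h.size))
    intakes["sfa"] = sfa
    intakes["mufa"] = 0.9 * sfa * np.exp(ratio_shift)  # median ratio 0.9
    points["mufa_sfa"] = (ratio_shift > 0).astype(int)
    amed = sum(points.values())
    return intakes, points, np.asarray(amed)


def _simulate_counts(rng, s, gamma, n_taxa, lib_mean, lib_disp):
    """Multinomial counts at a log-normal library size; softmax composition."""
    baseline = _BASELINE_SLOPE * np.arange(n_taxa)
    logab = (
        baseline[None, :]
        + np.outer(s, gamma)
        + _TAXA_NOISE_SD * rng.standard_normal((s.size, n_taxa))
    )
    logab -= logab.max(axis=1, keepdims=True)
    probs = np.exp(logab)
    probs /= probs.sum(axis=1, keepdims=True)
    libs = np.maximum(
        1, np.round(lib_mean * np.exp(lib_disp * rng.standard_normal(s.size) - lib_disp**2 / 2))
    ).astype(np.int64)
    return rng.multinomial(libs, probs)


def _simulate_batch(rng, n, config: SimulationConfig):
    """One super-population batch; returns a dict of per-individual arrays."""
    h = rng.standard_normal(n)
    male = rng.random(n) < 0.31
    age = np.clip(rng.normal(17.0, 2.2, n), 8.0, 24.0)
    energy = _ENERGY_MEDIAN * np.exp(_ENERGY_LOG_SD * rng.standard_normal(n))
    intakes, points, amed = _draw_components(rng, h, male)
    s = (amed - _AMED_MEAN) / _AMED_SD

    fiber = _FIBER_MEDIAN * np.exp(_FIBER_LOADING * h + _FIBER_RESID_SD * rng.standard_normal(n))
    iron = _IRON_MEDIAN * np.exp(_IRON_LOADING * h + _IRON_RESID_SD * rng.standard_normal(n))
    whole_grains = (
        _WHOLE_GRAINS_MEDIAN
        * (intakes["whole_grain_foods"] / _COMPONENT_MEDIANS_F["whole_grain_foods"])
        * np.exp(0.15 * rng.standard_normal(n))
    )

    counts = _simulate_counts(
        rng, s, config.gamma, config.n_taxa, config.library_size_mean, config.library_size_dispersion
    )
    clr = _clr_rows(counts)

    ce = config.covariate_effects
    eta = (
        config.intercept
        + config.beta_direct * amed
        + clr @ config.b
        + ce.get("age", 0.0) * (age - 17.0)
        + ce.get("sex_female", 0.0) * (~male)
        + ce.get("log_energy", 0.0) * (np.log(energy) - np.log(_ENERGY_MEDIAN))
    )
    status = (rng.random(n) < expit(eta)).astype(int)
    return {
        "h": h,
        "male": male,
        "age": age,
        "energy": energy,
        "intakes": intakes,
        "amed": amed,
        "fiber": fiber,
        "iron": iron,
        "whole_grains": whole_grains,
        "counts": counts,
        "status": status,
    }


def _clr_rows(counts: np.ndarray, pseudo: float = 0.5) -> np.ndarray:
    logged = np.log(counts + pseudo)
    return logged - logged.mean(axis=1, keepdims=True)


def generate_cohort(config: SimulationConfig, compute_oracles: bool = False,
                    n_mc_oracle: int = 20_000) -> SyntheticCohort:
    """Draw a case-control cohort from the generative model.

    Rejection-samples super-population individuals until ``n_cases`` cases
    and ``n_controls`` controls are collected. Bit-reproducible for a
    fixed config (including seed).

    Parameters
    ----------
    compute_oracles:
        Also fill the ground truth's per-taxon counterfactual ACME/ADE
        oracles (zero-path taxa are zero by construction and skipped).
    """
    rng = np.random.default_rng(config.seed)
    need_cases, need_controls = config.n_cases, config.n_controls
    batch_size = max(4 * (need_cases + need_controls), 200)
    kept = {"case": [], "control": []}
    n_seen = {"case": 0, "control": 0}
    for _ in range(_MAX_BATCHES):
        batch = _simulate_batch(rng, batch_size, config)
        for label, want in (("case", 1), ("control", 0)):
            idx = np.flatnonzero(batch["status"] == want)
            n_seen[label] += idx.size
            if len(kept[label]) < (need_cases if label == "case" else need_controls):
                kept[label].append((batch, idx))
        if (
            sum(i.size for _, i in kept["case"]) >= need_cases
            and sum(i.size for _, i in kept["control"]) >= need_controls
        ):
            break
    else:
        raise RuntimeError(
            f"could not collect {need_cases} cases / {need_controls} controls after "
            f"{_MAX_BATCHES} batches; the disease intercept ({config.intercept}) puts "
            "too little probability mass on one class"
        )

    rows = _assemble(kept, need_cases, need_controls)
    participants, ffq, counts, amed_true = _tabulate(rows, rng, config)

    truth = GroundTruth(
        beta_direct=config.beta_direct,
        gamma=config.gamma.copy(),
        b=config.b.copy(),
        covariate_effects=dict(config.covariate_effects),
        intercept=config.intercept,
        amed_mean=_AMED_MEAN,
        amed_sd=_AMED_SD,
        amed_true=amed_true,
    )
    if compute_oracles:
        acme = np.zeros(config.n_taxa)
        ade = np.zeros(config.n_taxa)
        for j in range(config.n_taxa):
            if config.gamma[j] == 0.0 or config.b[j] == 0.0:
                continue  # no mediated path
            acme[j], ade[j] = oracle_acme(
                truth, config, j, n_mc=n_mc_oracle, seed=config.seed + 7_000_000 + j,
                return_ade=True,
            )
        truth.oracle_acme_diff = acme
        truth.oracle_ade_diff = ade
    return SyntheticCohort(participants=participants, ffq=ffq, counts=counts, truth=truth)


def _assemble(kept, need_cases, need_controls):
    out = []
    for label, need in (("case", need_cases), ("control", need_controls)):
        taken = 0
        for batch, idx in kept[label]:
            take = idx[: need - taken]
            for i in take:
                out.append((batch, int(i)))
            taken += take.size
            if taken >= need:
                break
    return out


def _tabulate(rows, rng, config: SimulationConfig):
    n = len(rows)
    pids = [f"P{i:04d}" for i in range(n)]
    get = lambda key: np.array([batch[key][i] for batch, i in rows])
    getin = lambda key: np.array([batch["intakes"][key][i] for batch, i in rows])

    ffq_day = rng.integers(0, 365, n)
    ffq_date = pd.Timestamp("2019-01-01") + pd.to_timedelta(ffq_day, unit="D")
    has_stool = rng.random(n) < config.stool_fraction
    gap_kind = rng.random(n)
    gap = np.where(
        gap_kind < 0.80,
        rng.integers(0, 31, n),
        np.where(gap_kind < 0.93, rng.integers(31, 91, n), rng.integers(91, 160, n)),
    ) * np.where(rng.random(n) < 0.5, 1, -1)
    stool_date = ffq_date + pd.to_timedelta(gap, unit="D")
    med_flag = rng.random(n) < 0.08
    med_offset = rng.integers(1, 61, n)  # days before stool collection
    med_date = stool_date - pd.to_timedelta(med_offset, unit="D")
    bristol = rng.choice(np.arange(1, 8), size=n, p=_BRISTOL_PROBS)

    n_missing = rng.poisson(2.0, n)
    high_missing = rng.random(n) < config.missingness_rate
    n_missing = np.where(high_missing, rng.integers(15, 26, n), np.minimum(n_missing, 14))

    participants = pd.DataFrame(
        {
            "participant_id": pids,
            "status": get("status"),
            "sex": np.where(get("male"), "M", "F"),
            "age_ffq": get("age"),
            "race": np.where(rng.random(n) < 0.28, "White", "non-White"),
            "energy": get("energy"),
            "bristol_type": np.where(has_stool, bristol, np.nan),
            "has_stool": has_stool,
            "ffq_date": ffq_date.strftime("%Y-%m-%d"),
            "stool_date": np.where(has_stool, stool_date.strftime("%Y-%m-%d"), None),
            "med_exposure_date": np.where(
                has_stool & med_flag, med_date.strftime("%Y-%m-%d"), None
            ),
        }
    )
    ffq = pd.DataFrame({"participant_id": pids, "sex": participants["sex"]})
    for comp in _COMPONENT_LOADING:
        ffq[comp] = getin(comp)
    ffq["mufa"] = getin("mufa")
    ffq["sfa"] = getin("sfa")
    ffq["whole_grains"] = get("whole_grains")
    ffq["fiber"] = get("fiber")
    ffq["iron"] = get("iron")
    ffq["energy"] = get("energy")
    ffq["n_missing_items"] = n_missing

    count_mat = np.array([batch["counts"][i] for batch, i in rows])
    taxa_ids = [f"g__Taxon{j:03d}" for j in range(config.n_taxa)]
    counts = pd.DataFrame(count_mat, index=pids, columns=taxa_ids).loc[has_stool]
    counts.index.name = "sample_id"

    amed_true = pd.Series(get("amed"), index=pids, name="amed_true")
    return participants, ffq, counts, amed_true


# ---------------------------------------------------------------------------
# counterfactual oracle


def oracle_acme(
    truth: GroundTruth,
    config: SimulationConfig,
    taxon: int,
    n_mc: int = 20_000,
    seed: int = 0,
    treat_value: float = 1.0,
    control_value: float = 0.0,
    decomposition: str = "average",
    return_ade: bool = False,
):
    """True ACME of the aMED on disease through one taxon, by simulation.

    For exposure levels ``a`` in {control, treat} (aMED points), the
    microbiome composition is simulated with the standardized score set to
    ``s(a)``; the mediator is taxon ``taxon``'s CLR value, other taxa
    follow the *exposure* condition (their response to diet belongs to the
    direct path of this single-mediator estimand). Returns the mean of
    ``p(a, m(treat)) - p(a, m(control))`` over simulated individuals, at
    the true parameters. ``decomposition`` selects the treated condition,
    the control condition, or their average (matching the estimator's
    reported headline).
    """
    if not 0 <= taxon < config.n_taxa:
        raise IndexError(f"taxon index {taxon} out of range")
    if n_mc < 10_000:
        raise ValueError("n_mc must be at least 10^4 for a stable oracle")
    if decomposition not in ("average", "treated", "control"):
        raise ValueError("decomposition must be average/treated/control")
    rng = np.random.default_rng(seed)
    male = rng.random(n_mc) < 0.31
    age = np.clip(rng.normal(17.0, 2.2, n_mc), 8.0, 24.0)
    energy = _ENERGY_MEDIAN * np.exp(_ENERGY_LOG_SD * rng.standard_normal(n_mc))

    s_levels = {
        "c": (control_value - truth.amed_mean) / truth.amed_sd,
        "t": (treat_value - truth.amed_mean) / truth.amed_sd,
    }
    clr_by_level = {}
    for key, s_val in s_levels.items():
        counts = _simulate_counts(
            rng,
            np.full(n_mc, s_val),
            truth.gamma,
            config.n_taxa,
            config.library_size_mean,
            config.library_size_dispersion,
        )
        clr_by_level[key] = _clr_rows(counts)

    ce = truth.covariate_effects
    cov_eta = (
        ce.get("age", 0.0) * (age - 17.0)
        + ce.get("sex_female", 0.0) * (~male)
        + ce.get("log_energy", 0.0) * (np.log(energy) - np.log(_ENERGY_MEDIAN))
    )
    b = truth.b
    bj = b[taxon]
    mask_other = np.ones(config.n_taxa, dtype=bool)
    mask_other[taxon] = False

    def p(a_key, m_key):
        """p(disease | exposure condition a, taxon mediator from condition m)."""
        a_val = treat_value if a_key == "t" else control_value
        other = clr_by_level[a_key][:, mask_other] @ b[mask_other]
        med = bj * clr_by_level[m_key][:, taxon]
        eta = truth.intercept + truth.beta_direct * a_val + other + med + cov_eta
        return expit(eta)

    p_tt, p_tc = p("t", "t").mean(), p("t", "c").mean()
    p_ct, p_cc = p("c", "t").mean(), p("c", "c").mean()
    delta_t, delta_c = p_tt - p_tc, p_ct - p_cc
    zeta_t, zeta_c = p_tt - p_ct, p_tc - p_cc
    if decomposition == "treated":
        acme, ade = delta_t, zeta_t
    elif decomposition == "control":
        acme, ade = delta_c, zeta_c
    else:
        acme, ade = 0.5 * (delta_t + delta_c), 0.5 * (zeta_t + zeta_c)
    if truth.gamma[taxon] == 0.0 or bj == 0.0:
        acme = 0.0  # no mediated path by construction
    return (float(acme), float(ade)) if return_ade else float(acme)


# ---------------------------------------------------------------------------
# writers


def write_cohort(cohort: SyntheticCohort, outdir) -> dict:
    """Write metadata/FFQ/count TSVs and a ground-truth JSON; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "metadata": outdir / "metadata.tsv",
        "ffq": outdir / "ffq.tsv",
        "counts": outdir / "counts.tsv",
        "truth": outdir / "truth.json",
    }
    cohort.participants.to_csv(paths["metadata"], sep="\t", index=False)
    cohort.ffq.to_csv(paths["ffq"], sep="\t", index=False)
    cohort.counts.to_csv(paths["counts"], sep="\t")
    truth = cohort.truth
    payload = {
        "beta_direct": truth.beta_direct,
        "gamma": truth.gamma.tolist(),
        "b": truth.b.tolist(),
        "covariate_effects": truth.covariate_effects,
        "intercept": truth.intercept,
        "amed_mean": truth.amed_mean,
        "amed_sd": truth.amed_sd,
        "oracle_acme_diff": None if truth.oracle_acme_diff is None else truth.oracle_acme_diff.tolist(),
        "oracle_ade_diff": None if truth.oracle_ade_diff is None else truth.oracle_ade_diff.tolist(),
        "amed_true": None if truth.amed_true is None else truth.amed_true.to_dict(),
    }
    paths["truth"].write_text(json.dumps(payload, indent=1))
    return {k: str(v) for k, v in paths.items()}
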