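import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from medigut.screen import (
    bh_adjust,
    build_analysis_frame,
    interaction_scan,
    pairwise_spearman,
    screen_diet_disease,
    screen_diet_taxa,
    screen_taxa_disease,
    select_mediator_candidates,
)
from medigut.diet import compute_sex_specific_medians, score_amed
from medigut.taxa import clr_transform


def bh_bruteforce(p):
    """Literal step-up definition: q_i = min over {j: p_(j) >= p_(i)} of p_(j) m / j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    sorted_p = p[order]
    for i in range(m):
        candidates = [sorted_p[j] * m / (j + 1) for j in range(i, m)]
        q[order[i]] = min(1.0, min(candidates))
    return q


class TestBenjaminiHochberg:
    def test_hand_stepped_quadruple(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_ones_stay_one(self):
        assert np.allclose(bh_adjust(np.ones(5)), 1.0)

    def test_matches_bruteforce_definition(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 40))
            assert np.max(np.abs(bh_adjust(p) - bh_bruteforce(p))) < 1e-12

    def test_q_between_p_and_one(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=30)
        q = bh_adjust(p)
        assert ((q >= p - 1e-15) & (q <= 1.0)).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
                    min_size=1, max_size=30))
    def test_stepup_property(self, p):
        q = bh_adjust(p)
        assert np.max(np.abs(q - bh_bruteforce(p))) < 1e-12
        # monotone in the sorted order
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


@pytest.fixture(scope="module")
def frames(big_cohort):
    cohort, _ = big_cohort
    controls = cohort.ffq[
        cohort.participants.set_index("participant_id")["status"]
        .reindex(cohort.ffq["participant_id"]).to_numpy() == 0
    ]
    medians = compute_sex_specific_medians(controls)
    amed = score_amed(cohort.ffq, medians)
    frame = build_analysis_frame(cohort.participants, cohort.ffq, amed, counts=cohort.counts)
    clr = clr_transform(cohort.counts)
    return cohort, frame, clr


class TestDietDiseaseScreen:
    def test_protective_diet_effect_recovered(self, frames):
        cohort, frame, _ = frames
        out = screen_diet_disease(frame, ["amed_score", "fiber"])
        amed = out[out["term"] == "amed_score"].iloc[0]
        # generator direct effect is protective; mediated paths add to it
        assert amed["or"] < 1.0 and amed["p"] < 0.05

    def test_covariate_order_irrelevant(self, frames):
        _, frame, _ = frames
        a = screen_diet_disease(frame, ["amed_score"])
        shuffled = frame[list(frame.columns)[::-1]]
        b = screen_diet_disease(shuffled, ["amed_score"])
        assert a["estimate"].iloc[0] == pytest.approx(b["estimate"].iloc[0], rel=1e-9)

    def test_null_diet_variable_is_null(self, frames):
        _, frame, _ = frames
        rng = np.random.default_rng(0)
        frame = frame.assign(noise_var=rng.normal(size=len(frame)))
        out = screen_diet_disease(frame, ["noise_var"])
        assert out["ci_lo"].iloc[0] < 0 < out["ci_hi"].iloc[0]


class TestTaxaScreens:
    def test_null_taxon_ci_covers_zero(self, frames):
        cohort, frame, clr = frames
        null_taxa = [f"g__Taxon{j:03d}" for j in (20, 30, 40)]  # gamma = b = 0
        out = screen_taxa_disease(frame, clr, taxa=null_taxa)
        covered = ((out["ci_lo"] < 0) & (out["ci_hi"] > 0)).sum()
        assert covered >= 2

    def test_strong_taxon_detected_with_correct_sign(self, frames):
        cohort, frame, clr = frames
        out = screen_taxa_disease(frame, clr, taxa=["g__Taxon005"])  # b = +0.9
        rec = out.iloc[0]
        assert rec["estimate"] > 0 and rec["p"] < 0.05

    def test_duplicated_rows_shrink_se_keep_estimate(self, frames):
        cohort, frame, clr = frames
        out1 = screen_taxa_disease(frame, clr, taxa=["g__Taxon005"], robust=False)
        doubled = pd.concat([frame, frame.assign(participant_id=frame["participant_id"] + "_b")])
        clr2 = pd.concat([clr, clr.set_index(clr.index + "_b")])
        out2 = screen_taxa_disease(doubled, clr2, taxa=["g__Taxon005"], robust=False)
        # sample-SD z-scoring shifts by O(1/n) when rows double; the fit itself is exact
        assert out2["estimate"].iloc[0] == pytest.approx(out1["estimate"].iloc[0], rel=2e-3)
        assert out2["se"].iloc[0] < out1["se"].iloc[0]

    def test_diet_taxa_sign_recovery_and_directionality(self, frames):
        cohort, frame, clr = frames
        out = screen_diet_taxa(frame, clr, ["amed_score"], taxa=["g__Taxon002", "g__Taxon020"])
        enriched = out[out["outcome"] == "g__Taxon002"].iloc[0]  # gamma = +0.9
        null = out[out["outcome"] == "g__Taxon020"].iloc[0]
        assert enriched["estimate"] > 0 and enriched["p"] < 0.05
        assert null["ci_lo"] < 0 < null["ci_hi"]

    def test_zero_variance_taxon_skipped(self, frames):
        cohort, frame, clr = frames
        clr = clr.copy()
        clr["flat"] = 0.0
        out = screen_taxa_disease(frame, clr, taxa=["flat", "g__Taxon005"])
        assert "flat" in out.attrs["skipped"]
        assert (out["term"] == "g__Taxon005").any()


class TestCandidateSelection:
    def _records(self, rows, outcome_key):
        return pd.DataFrame(rows).rename(columns={"taxon": outcome_key})

    def test_hand_enumerated_rule(self):
        diet = pd.DataFrame(
            {
                "outcome": [f"t{i}" for i in range(10)],
                "term": ["amed_score"] * 10,
                "p": [0.01, 0.2, 0.03, 0.8, 0.04, 0.04, 0.5, 0.001, 0.9, 0.049],
            }
        )
        disease = pd.DataFrame(
            {
                "term": [f"t{i}" for i in range(10)],
                "p": [0.03, 0.01, 0.2, 0.04, 0.04, 0.06, 0.01, 0.049, 0.9, 0.3],
            }
        )
        got = select_mediator_candidates(diet, disease)
        expected = [f"t{i}" for i in range(10)
                    if diet["p"][i] < 0.05 and disease["p"][i] < 0.05]
        assert got == expected

    def test_boundary_cases(self):
        diet = pd.DataFrame({"outcome": ["a", "b"], "term": ["fiber"] * 2, "p": [0.04, 0.04]})
        disease = pd.DataFrame({"term": ["a", "b"], "p": [0.03, 0.06]})
        assert select_mediator_candidates(diet, disease) == ["a"]


class TestSpearman:
    def test_monotone_pairs(self):
        df = pd.DataFrame({"x": [1, 2, 3, 4], "y": [10, 20, 30, 40], "z": [4, 3, 2, 1]})
        rho = pairwise_spearman(df)
        assert rho.loc["x", "y"] == pytest.approx(1.0)
        assert rho.loc["x", "z"] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(25, 3)), columns=list("abc"))
        rho = pairwise_spearman(df)
        for x, y in (("a", "b"), ("a", "c"), ("b", "c")):
            oracle = np.corrcoef(stats.rankdata(df[x]), stats.rankdata(df[y]))[0, 1]
            assert rho.loc[x, y] == pytest.approx(oracle, abs=1e-12)

    def test_constant_column_flagged(self):
        df = pd.DataFrame({"x": [1, 2, 3], "c": [5, 5, 5]})
        rho = pairwise_spearman(df)
        assert np.isnan(rho.loc["x", "c"]) and rho.attrs["undefined"] == ["c"]


class TestInteractionScan:
    def test_age_centering_leaves_interaction_p_unchanged(self, frames):
        _, frame, _ = frames
        out = interaction_scan(frame, ["amed_score"])
        centered = frame.assign(age_ffq=frame["age_ffq"] - frame["age_ffq"].mean())
        out_c = interaction_scan(centered, ["amed_score"])
        a = out[out["term"] == "amed_score:age"]["p"].iloc[0]
        b = out_c[out_c["term"] == "amed_score:age"]["p"].iloc[0]
        assert a == pytest.approx(b, abs=1e-6)

    def test_no_interaction_generator_rarely_significant(self, frames):
        _, frame, _ = frames
        out = interaction_scan(frame, ["amed_score", "fiber"])
        # 4 null interaction tests; all significant would be a red flag
        assert (out["p"] < 0.05).sum() <= 1
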