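import numpy as np
import pandas as pd
import pytest

from medigut.diet import (
    AMED_COMPONENTS,
    HEALTHY_COMPONENTS,
    MEAT_COMPONENT,
    apply_ffq_exclusions,
    compute_sex_specific_medians,
    dichotomize_components,
    score_amed,
)


def _ffq(**overrides):
    base = {
        "participant_id": "P0",
        "sex": "F",
        "fruit": 100.0,
        "vegetables": 100.0,
        "legumes": 10.0,
        "whole_grain_foods": 40.0,
        "fish": 15.0,
        "processed_red_meat": 80.0,
        "mufa": 12.0,
        "sfa": 14.0,
        "energy": 1100.0,
        "n_missing_items": 0,
    }
    base.update(overrides)
    return base


class TestExclusions:
    def test_low_energy_excluded(self):
        kept, excluded = apply_ffq_exclusions(pd.DataFrame([_ffq(energy=400)]))
        assert kept.empty and excluded[0].reasons == ["low_energy"]

    def test_just_inside_both_bounds_kept(self):
        kept, excluded = apply_ffq_exclusions(
            pd.DataFrame([_ffq(n_missing_items=14, energy=1100)])
        )
        assert len(kept) == 1 and not excluded

    def test_boundary_energies_are_inclusive(self):
        kept, _ = apply_ffq_exclusions(
            pd.DataFrame([_ffq(energy=500), _ffq(participant_id="P1", energy=3500)])
        )
        assert len(kept) == 2

    def test_toy_roster_keeps_three(self):
        rows = [
            _ffq(participant_id=f"P{i}", n_missing_items=m, energy=e)
            for i, (m, e) in enumerate(
                [(0, 450), (20, 1000), (0, 3600), (0, 500), (14, 3500), (0, 2000)]
            )
        ]
        kept, excluded = apply_ffq_exclusions(pd.DataFrame(rows))
        assert list(kept["participant_id"]) == ["P3", "P4", "P5"]
        assert len(excluded) == 3

    def test_missing_energy_is_unassessable(self):
        _, excluded = apply_ffq_exclusions(pd.DataFrame([_ffq(energy=np.nan)]))
        assert excluded[0].reasons == ["unassessable"]


class TestMedians:
    def test_odd_and_even_sample_conventions(self):
        rows = [
            _ffq(participant_id=f"P{i}", sex="F", fruit=v) for i, v in enumerate([1, 2, 3])
        ] + [
            _ffq(participant_id=f"Q{i}", sex="M", fruit=v) for i, v in enumerate([1, 2, 3, 4])
        ]
        med = compute_sex_specific_medians(pd.DataFrame(rows))
        assert med.loc["F", "fruit"] == 2
        assert med.loc["M", "fruit"] == 2.5

    def test_matches_sort_based_oracle(self, ffq_table):
        med = compute_sex_specific_medians(ffq_table)
        work = ffq_table.assign(mufa_sfa=ffq_table["mufa"] / ffq_table["sfa"])
        for sex in ("F", "M"):
            sub = work[work["sex"] == sex]
            for comp in AMED_COMPONENTS:
                v = np.sort(sub[comp].to_numpy())
                n = len(v)
                oracle = v[n // 2] if n % 2 else 0.5 * (v[n // 2 - 1] + v[n // 2])
                assert med.loc[sex, comp] == pytest.approx(oracle)

    def test_ratio_formed_before_median(self):
        # median of ratios differs from ratio of medians for this triple
        rows = [
            _ffq(participant_id=f"P{i}", mufa=m, sfa=s)
            for i, (m, s) in enumerate([(1, 10), (4, 2), (9, 3)])
        ]
        med = compute_sex_specific_medians(pd.DataFrame(rows))
        assert med.loc["F", "mufa_sfa"] == pytest.approx(2.0)  # median of (0.1, 2, 3)

    def test_nonpositive_sfa_rejected(self):
        with pytest.raises(ValueError, match="SFA"):
            compute_sex_specific_medians(pd.DataFrame([_ffq(sfa=0.0)]))

    def test_empty_controls_rejected(self):
        with pytest.raises(ValueError):
            compute_sex_specific_medians(pd.DataFrame([_ffq()]).iloc[:0])


class TestScoring:
    @pytest.fixture()
    def medians(self, ffq_table):
        return compute_sex_specific_medians(ffq_table)

    def test_everything_healthy_scores_seven(self, medians):
        rec = _ffq(
            fruit=1e4, vegetables=1e4, legumes=1e4, whole_grain_foods=1e4, fish=1e4,
            processed_red_meat=0.0, mufa=1e4, sfa=1.0,
        )
        out = score_amed(pd.DataFrame([rec]), medians)
        assert out["amed_score"].iloc[0] == 7

    def test_exact_medians_score_zero(self, medians):
        rec = dict(_ffq(), **{c: medians.loc["F", c] for c in AMED_COMPONENTS if c != "mufa_sfa"})
        rec["mufa"] = medians.loc["F", "mufa_sfa"] * 2.0
        rec["sfa"] = 2.0
        out = score_amed(pd.DataFrame([rec]), medians)
        assert out["amed_score"].iloc[0] == 0

    def test_componentwise_hand_rule(self, ffq_table, medians):
        out = score_amed(ffq_table, medians)
        work = ffq_table.assign(mufa_sfa=ffq_table["mufa"] / ffq_table["sfa"])
        for i, row in work.iterrows():
            ref = medians.loc[row["sex"]]
            for comp in HEALTHY_COMPONENTS:
                assert out.loc[i, comp] == int(row[comp] > ref[comp])
            assert out.loc[i, MEAT_COMPONENT] == int(row[MEAT_COMPONENT] < ref[MEAT_COMPONENT])

    def test_points_sum_to_score_and_range(self, ffq_table, medians):
        out = score_amed(ffq_table, medians)
        assert (out[list(AMED_COMPONENTS)].sum(axis=1) == out["amed_score"]).all()
        assert out["amed_score"].between(0, 7).all()

    def test_monotone_in_healthy_and_meat(self, ffq_table, medians):
        base = score_amed(ffq_table, medians)["amed_score"]
        more_fruit = ffq_table.assign(fruit=ffq_table["fruit"] * 10)
        assert (score_amed(more_fruit, medians)["amed_score"] >= base).all()
        more_meat = ffq_table.assign(processed_red_meat=ffq_table["processed_red_meat"] * 10)
        assert (score_amed(more_meat, medians)["amed_score"] <= base).all()

    def test_record_order_irrelevant(self, ffq_table, medians):
        fwd = score_amed(ffq_table, medians).set_index("participant_id")
        rev = score_amed(ffq_table.iloc[::-1], medians).set_index("participant_id")
        pd.testing.assert_frame_equal(fwd.sort_index(), rev.sort_index())

    def test_unknown_sex_stratum_rejected(self, ffq_table, medians):
        odd = pd.DataFrame([_ffq(sex="X")])
        with pytest.raises(ValueError, match="sex"):
            score_amed(odd, medians)

    def test_dichotomization_shares_the_scoring_rule(self, ffq_table, medians):
        scored = score_amed(ffq_table, medians)
        binary = dichotomize_components(ffq_table, medians)
        pd.testing.assert_frame_equal(
            binary[list(AMED_COMPONENTS)], scored[list(AMED_COMPONENTS)]
        )
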