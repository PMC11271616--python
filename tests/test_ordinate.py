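import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from medigut.ordinate import (
    aitchison_distance,
    axis_disease_assoc,
    constrained_axis,
    permanova_marginal,
)
from medigut.taxa import clr_transform


def _clr_table(seed, n=20, p=8):
    rng = np.random.default_rng(seed)
    counts = pd.DataFrame(
        rng.integers(1, 500, size=(n, p)),
        index=[f"S{i}" for i in range(n)],
        columns=[f"T{j}" for j in range(p)],
    )
    return clr_transform(counts)


class TestAitchison:
    def test_identical_rows_distance_zero(self):
        clr = _clr_table(0)
        clr.iloc[1] = clr.iloc[0]
        d = aitchison_distance(clr)
        assert d.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_two_sample_hand_computation(self):
        clr = _clr_table(1, n=2)
        expected = np.sqrt(((clr.iloc[0] - clr.iloc[1]) ** 2).sum())
        assert aitchison_distance(clr).iloc[0, 1] == pytest.approx(expected)

    def test_taxa_permutation_invariance(self):
        clr = _clr_table(2)
        shuffled = clr[list(clr.columns)[::-1]]
        assert np.allclose(aitchison_distance(clr), aitchison_distance(shuffled))


def _bruteforce_permanova_binary(D, labels):
    """Classic PERMANOVA sums of squares for one binary factor."""
    n = len(labels)
    d2 = D**2
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        ss_within += d2[np.ix_(idx, idx)][np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    a = len(np.unique(labels))
    f = (ss_between / (a - 1)) / (ss_within / (n - a))
    return ss_between / ss_total, f


class TestPermanova:
    def test_duplicated_cluster_fixture_explains_nearly_everything(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(2, 6))
        rows = np.repeat(base, 8, axis=0) + 0.01 * rng.normal(size=(16, 6))
        clr = pd.DataFrame(rows - rows.mean(axis=1, keepdims=True),
                           index=[f"S{i}" for i in range(16)])
        labels = pd.Series(["a"] * 8 + ["b"] * 8, index=clr.index, name="cluster")
        rec = permanova_marginal(aitchison_distance(clr), labels, n_perm=99, seed=0)
        assert rec.r2 > 0.95 and rec.p <= 0.05

    def test_r2_and_f_match_bruteforce_formula(self):
        clr = _clr_table(4, n=12)
        labels = pd.Series(["a", "b"] * 6, index=clr.index, name="g")
        D = aitchison_distance(clr)
        rec = permanova_marginal(D, labels, n_perm=9, seed=0)
        r2_bf, f_bf = _bruteforce_permanova_binary(D.to_numpy(), labels.to_numpy())
        assert rec.r2 == pytest.approx(r2_bf, abs=1e-10)
        assert rec.pseudo_f == pytest.approx(f_bf, abs=1e-10)

    def test_exact_p_matches_full_enumeration_oracle(self):
        clr = _clr_table(5, n=6)
        labels = pd.Series(["a", "a", "a", "b", "b", "b"], index=clr.index, name="g")
        D = aitchison_distance(clr)
        rec = permanova_marginal(D, labels, exact=True)
        Dm = D.to_numpy()
        _, f_obs = _bruteforce_permanova_binary(Dm, labels.to_numpy())
        hits = total = 0
        for perm in itertools.permutations(range(6)):
            _, f = _bruteforce_permanova_binary(Dm, labels.to_numpy()[list(perm)])
            hits += f >= f_obs - 1e-12
            total += 1
        assert rec.exact and total == 720
        assert rec.p == pytest.approx(hits / total, abs=1e-12)

    def test_matches_scikit_bio_on_categorical_fixture(self):
        skbio = pytest.importorskip("skbio")
        clr = _clr_table(6, n=14)
        labels = pd.Series(["a"] * 7 + ["b"] * 7, index=clr.index, name="g")
        D = aitchison_distance(clr)
        rec = permanova_marginal(D, labels, n_perm=99, seed=1)
        dm = skbio.DistanceMatrix(D.to_numpy(), ids=list(D.index))
        ref = skbio.stats.distance.permanova(dm, grouping=labels.to_numpy(), permutations=0)
        assert rec.pseudo_f == pytest.approx(float(ref["test statistic"]), abs=1e-9)

    def test_continuous_variable_and_determinism(self):
        clr = _clr_table(7)
        x = pd.Series(np.arange(len(clr), dtype=float), index=clr.index, name="x")
        D = aitchison_distance(clr)
        a = permanova_marginal(D, x, n_perm=199, seed=5)
        b = permanova_marginal(D, x.rename("alias"), n_perm=199, seed=5)
        assert 0.0 <= a.r2 <= 1.0 and a.r2 == b.r2 and a.p == b.p

    def test_shuffled_variable_is_null(self):
        clr = _clr_table(8, n=18)
        D = aitchison_distance(clr)
        ps = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            x = pd.Series(rng.permutation(np.arange(18.0)), index=clr.index, name="x")
            ps.append(permanova_marginal(D, x, n_perm=99, seed=seed).p)
        assert 0.0 <= np.mean(np.array(ps) < 0.05) <= 0.15

    def test_constant_variable_rejected(self):
        clr = _clr_table(9)
        D = aitchison_distance(clr)
        with pytest.raises(ValueError, match="constant"):
            permanova_marginal(D, pd.Series(1.0, index=clr.index, name="c"))

    def test_missing_values_dropped_as_complete_cases(self):
        clr = _clr_table(10, n=12)
        D = aitchison_distance(clr)
        x = pd.Series(np.arange(12.0), index=clr.index, name="x")
        x.iloc[:2] = np.nan
        rec = permanova_marginal(D, x, n_perm=49, seed=0)
        assert rec.n_samples == 10


class TestConstrainedAxis:
    def test_unconditioned_axis_tracks_constraint_perfectly(self):
        clr = _clr_table(11)
        y = pd.Series(np.random.default_rng(0).normal(size=len(clr)),
                      index=clr.index, name="diet")
        axis = constrained_axis(clr, y)
        rho = spearmanr(axis.scores, y).statistic
        assert abs(rho) == pytest.approx(1.0)
        assert axis.scores.std(ddof=1) == pytest.approx(1.0)

    def test_orthogonal_constraint_explains_nothing(self):
        rng = np.random.default_rng(1)
        n = 40
        clr = pd.DataFrame(rng.normal(size=(n, 5)), index=[f"S{i}" for i in range(n)])
        clr = clr.sub(clr.mean(axis=1), axis=0)
        y = clr.iloc[:, 0] - clr.iloc[:, 0].mean()
        y_orth = pd.Series(rng.normal(size=n), index=clr.index, name="noise")
        # residualize the noise against every CLR column to make it orthogonal
        Q, _ = np.linalg.qr(np.column_stack([np.ones(n), clr.to_numpy()]))
        y_orth[:] = y_orth - Q @ (Q.T @ y_orth.to_numpy())
        axis = constrained_axis(clr, y_orth)
        assert axis.variance_explained < 1e-20

    def test_fitted_matrix_is_rank_one(self):
        clr = _clr_table(12)
        y = pd.Series(np.random.default_rng(2).normal(size=len(clr)),
                      index=clr.index, name="d")
        cond = pd.DataFrame({"c": np.random.default_rng(3).normal(size=len(clr))},
                            index=clr.index)
        axis = constrained_axis(clr, y, conditioners=cond)
        # reconstruct the fitted matrix the same way and check its numerical rank
        assert 0.0 <= axis.variance_explained <= 1.0
        assert axis.conditioners == ("c",)

    def test_collinear_constraint_rejected(self):
        clr = _clr_table(13)
        cond = pd.DataFrame({"c": np.arange(len(clr), dtype=float)}, index=clr.index)
        y = (cond["c"] * 2.0 + 1.0).rename("d")
        with pytest.raises(ValueError, match="collinear"):
            constrained_axis(clr, y, conditioners=cond)


class TestAxisDiseaseAssociation:
    def test_doubling_scores_halves_the_coefficient(self, small_cohort):
        cohort, _ = small_cohort
        from medigut.diet import compute_sex_specific_medians, score_amed
        from medigut.screen import build_analysis_frame

        controls = cohort.ffq[
            cohort.participants.set_index("participant_id")["status"]
            .reindex(cohort.ffq["participant_id"]).to_numpy() == 0
        ]
        amed = score_amed(cohort.ffq, compute_sex_specific_medians(controls))
        frame = build_analysis_frame(cohort.participants, cohort.ffq, amed, counts=cohort.counts)
        clr = clr_transform(cohort.counts)
        fsub = frame.set_index("participant_id").loc[clr.index]
        axis = constrained_axis(clr, fsub["amed_score"].rename("amed_score"))
        rec = axis_disease_assoc(axis, frame)
        doubled = type(axis)(
            scores=axis.scores * 2.0, variance_explained=axis.variance_explained,
            constraint=axis.constraint, conditioners=axis.conditioners,
        )
        rec2 = axis_disease_assoc(doubled, frame)
        assert rec2["estimate"] == pytest.approx(rec["estimate"] / 2.0, rel=1e-6)
        # diet-mediated taxa shifts should make the diet axis protective
        assert rec["or"] < 1.0
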