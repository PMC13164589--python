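"""Rank tests, compact letters, LDA and jackknifed classification."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from karyodelim import datasets
from karyodelim.io_tables import TraitMatrix
from karyodelim.morphometrics import (
    compact_letters,
    confidence_ellipses,
    dunn_posthoc,
    jackknife_confusion,
    kruskal_wallis,
    lda_classify,
    lda_fit,
    lda_scores,
    standardize,
    summarize_traits,
    trait_comparison_table,
    wilks_lambda,
)
from karyodelim.synthetic_data import simulate_study_traits


class TestKruskalWallis:
    def test_hand_computed_example(self):
        res = kruskal_wallis([np.array([1, 2, 3]), np.array([4, 5, 6])])
        assert res.H_statistic == pytest.approx(3.857, abs=5e-4)
        assert res.df == 1

    def test_all_values_equal(self):
        res = kruskal_wallis([np.array([2.0, 2.0]), np.array([2.0, 2.0])])
        assert res.H_statistic == 0.0
        assert res.p_value == 1.0

    def test_tie_correction_reported(self):
        res = kruskal_wallis([np.array([1, 1, 2]), np.array([2, 3, 3])])
        assert 0 < res.tie_correction < 1

    def test_permutation_null_mean_is_k_minus_one(self):
        """Under the permutation null without ties, E[H] = k - 1."""
        values = np.arange(1, 7, dtype=float)
        hs = [
            kruskal_wallis([values[list(idx)], np.delete(values, list(idx))]).H_statistic
            for idx in itertools.combinations(range(6), 3)
        ]
        assert np.mean(hs) == pytest.approx(1.0, abs=1e-9)

    def test_two_group_h_is_monotone_in_rank_sum_deviation(self):
        """With two groups KW is a monotone transform of the rank-sum statistic."""
        values = np.arange(1, 9, dtype=float)
        rows = []
        for idx in itertools.combinations(range(8), 4):
            a = values[list(idx)]
            b = np.delete(values, list(idx))
            w_dev = abs(a.sum() - 4 * 4.5)  # |W - E[W]|
            rows.append((w_dev, kruskal_wallis([a, b]).H_statistic))
        rows.sort()
        devs, hs = zip(*rows)
        assert all(h2 >= h1 - 1e-12 for h1, h2 in zip(hs, hs[1:]))

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([np.array([1.0, 2.0])])


class TestDunn:
    def test_two_groups_adjusted_equals_raw(self):
        out = dunn_posthoc({"a": np.arange(5.0), "b": np.arange(5.0) + 3})
        assert len(out) == 1
        assert out["p_adj"].iloc[0] == pytest.approx(out["p"].iloc[0])

    def test_bh_step_up_hand_example(self):
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([0.01, 0.02, 0.04], method="fdr_bh")[1]
        assert adj == pytest.approx([0.03, 0.03, 0.04])

    def test_separated_groups_all_significant(self):
        groups = {
            "a": np.arange(1.0, 9.0),
            "b": np.arange(11.0, 19.0),
            "c": np.arange(21.0, 29.0),
        }
        out = dunn_posthoc(groups)
        assert (out["p_adj"] < 0.05).all()

    def test_z_matches_direct_formula_without_ties(self):
        groups = {"a": np.array([1.0, 4.0, 5.0]), "b": np.array([2.0, 3.0, 6.0, 7.0])}
        out = dunn_posthoc(groups, adjust=None)
        pooled = np.concatenate(list(groups.values()))
        N = len(pooled)
        ranks = stats.rankdata(pooled)
        ra, rb = ranks[:3].mean(), ranks[3:].mean()
        se = np.sqrt(N * (N + 1) / 12 * (1 / 3 + 1 / 4))
        assert out["z"].iloc[0] == pytest.approx((ra - rb) / se, rel=1e-12)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            dunn_posthoc({"a": np.arange(4.0)})


class TestCompactLetters:
    def test_no_significant_pairs_single_letter(self):
        out = compact_letters(["A", "B", "C"], {})
        assert out == {"A": "a", "B": "a", "C": "a"}

    def test_insert_absorb_hand_example(self):
        sig = {("A", "B"): True, ("A", "C"): True}
        assert compact_letters(["A", "B", "C"], sig) == {"A": "a", "B": "b", "C": "b"}

    def test_all_pairs_differ(self):
        sig = {p: True for p in itertools.combinations("ABC", 2)}
        out = compact_letters(["A", "B", "C"], sig)
        assert len({out["A"], out["B"], out["C"]}) == 3

    def test_chain_structure_shares_middle_group(self):
        # A != C but B differs from neither: B shares a letter with both
        sig = {("A", "C"): True}
        out = compact_letters(["A", "B", "C"], sig)
        assert set(out["B"]) & set(out["A"])
        assert set(out["B"]) & set(out["C"])
        assert not set(out["A"]) & set(out["C"])

    def test_groups_sharing_letter_never_differ(self, rng):
        groups = list("ABCDE")
        for _ in range(25):
            sig = {
                pair: bool(rng.random() < 0.4)
                for pair in itertools.combinations(groups, 2)
            }
            out = compact_letters(groups, sig)
            for a, b in itertools.combinations(groups, 2):
                share = set(out[a]) & set(out[b])
                if sig[(a, b)]:
                    assert not share, (sig, out)
            assert all(out[g] for g in groups)


class TestStandardize:
    def test_single_trait_hand_example(self):
        out = standardize(pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
        assert out["x"].tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_idempotent_and_centered(self, rng):
        X = pd.DataFrame(rng.normal(5, 3, (40, 3)), columns=list("abc"))
        z = standardize(X)
        assert np.allclose(z.mean(), 0.0, atol=1e-12)
        assert np.allclose(z.std(ddof=1), 1.0)
        assert np.allclose(standardize(z), z)

    def test_zero_variance_trait_named(self):
        with pytest.raises(ValueError, match="flat"):
            standardize(pd.DataFrame({"flat": [1.0, 1.0], "ok": [1.0, 2.0]}))


@pytest.fixture(scope="module")
def toy_lda():
    rng = np.random.default_rng(11)
    centers = {"a": (0, 0), "b": (4, 1), "c": (2, 5)}
    rows, labels = [], []
    for g, c in centers.items():
        rows.append(rng.normal(c, 1.0, size=(15, 2)))
        labels += [g] * 15
    X = pd.DataFrame(np.vstack(rows), columns=["t1", "t2"])
    return X, pd.Series(labels)


class TestLDA:
    def test_two_groups_one_trait_single_axis(self):
        X = pd.DataFrame({"t": [1.0, 2.0, 3.0, 7.0, 8.0, 9.0]})
        model = lda_fit(X, ["a"] * 3 + ["b"] * 3)
        assert model.scalings.shape == (1, 1)
        assert model.scalings[0, 0] > 0  # sign canonical

    def test_axes_match_reference_implementation(self, toy_lda):
        sklearn = pytest.importorskip("sklearn.discriminant_analysis")
        X, labels = toy_lda
        model = lda_fit(X, labels)
        ref = sklearn.LinearDiscriminantAnalysis(solver="eigen")
        ref.fit(X.to_numpy(), labels.to_numpy())
        for j in range(model.scalings.shape[1]):
            ours = model.scalings[:, j] / np.linalg.norm(model.scalings[:, j])
            theirs = ref.scalings_[:, j] / np.linalg.norm(ref.scalings_[:, j])
            assert abs(float(ours @ theirs)) == pytest.approx(1.0, abs=1e-8)
        # eigenvalue ratios are convention-free
        assert model.eigenvalues[0] / model.eigenvalues[1] == pytest.approx(
            ref.explained_variance_ratio_[0] / ref.explained_variance_ratio_[1], rel=1e-6
        )

    def test_classification_matches_reference(self, toy_lda):
        sklearn = pytest.importorskip("sklearn.discriminant_analysis")
        X, labels = toy_lda
        model = lda_fit(X, labels)
        ref = sklearn.LinearDiscriminantAnalysis(solver="svd")
        ref.fit(X.to_numpy(), labels.to_numpy())
        ours = lda_classify(model, X)
        assert (ours.to_numpy() == ref.predict(X.to_numpy())).all()

    def test_axes_invariant_under_affine_recoding(self, toy_lda):
        """Scores from the generalized eigenproblem are invariant (up to sign
        and scale) under invertible affine re-coding of the traits."""
        X, labels = toy_lda
        rng = np.random.default_rng(3)
        A = rng.normal(size=(2, 2)) + 2 * np.eye(2)
        Xr = pd.DataFrame(X.to_numpy() @ A + [10.0, -3.0], columns=X.columns)
        s1 = lda_scores(lda_fit(X, labels), X).to_numpy()
        s2 = lda_scores(lda_fit(Xr, labels), Xr).to_numpy()
        for j in range(2):
            r = np.corrcoef(s1[:, j], s2[:, j])[0, 1]
            assert abs(r) == pytest.approx(1.0, abs=1e-8)

    def test_small_group_rejected(self):
        X = pd.DataFrame({"t": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            lda_fit(X, ["a", "a", "b"])


class TestJackknife:
    def test_perfectly_separable_toy_is_diagonal(self):
        X = pd.DataFrame(
            {"t": [1.0, 1.1, 1.2, 0.9, 9.0, 9.1, 9.2, 8.9]},
        )
        labels = ["a"] * 4 + ["b"] * 4
        cm = jackknife_confusion(X, labels)
        assert cm.loc["a", "a"] == 100.0
        assert cm.loc["b", "b"] == 100.0

    def test_columns_sum_to_100(self, toy_lda):
        X, labels = toy_lda
        cm = jackknife_confusion(X, labels)
        assert cm.shape == (3, 3)
        assert np.allclose(cm.sum(axis=0), 100.0, atol=0.1)

    def test_equals_brute_force_reference_loop(self):
        """Refitting with the reference implementation once per held-out
        record must give the identical confusion matrix (n = 18)."""
        sklearn = pytest.importorskip("sklearn.discriminant_analysis")
        rng = np.random.default_rng(8)
        X = pd.DataFrame(
            np.vstack([rng.normal((0, 0), 1.2, (9, 2)), rng.normal((3, 2), 1.2, (9, 2))]),
            columns=["t1", "t2"],
        )
        labels = pd.Series(["a"] * 9 + ["b"] * 9)
        ours = jackknife_confusion(X, labels)
        groups = ["a", "b"]
        counts = pd.DataFrame(0.0, index=groups, columns=groups)
        for i in range(len(X)):
            keep = np.arange(len(X)) != i
            ref = sklearn.LinearDiscriminantAnalysis(solver="svd")
            ref.fit(X.to_numpy()[keep], labels.to_numpy()[keep])
            pred = ref.predict(X.to_numpy()[[i]])[0]
            counts.loc[pred, labels.iloc[i]] += 1
        ref_cm = 100.0 * counts / counts.sum(axis=0)
        assert np.allclose(ours.to_numpy(), ref_cm.to_numpy(), atol=1e-9)

    def test_too_small_group_rejected(self):
        X = pd.DataFrame({"t": [1.0, 2.0, 9.0, 10.0, 11.0]})
        with pytest.raises(ValueError):
            jackknife_confusion(X, ["a", "a", "b", "b", "b"])


@pytest.fixture(scope="module")
def small_matrix():
    return simulate_study_traits(
        seed=101,
        populations={"P1": ("T_scardica", 12), "P2": ("T_undulatifolia", 15)},
        traits=["plant_length", "stem_width", "length_anther"],
    )


class TestTraitWorkflow:
    def test_summaries_recover_generator_parameters(self):
        tm = simulate_study_traits(
            seed=55,
            populations={"P1": ("T_scardica", 400)},
            traits=["plant_length"],
        )
        summ = summarize_traits(tm, by="species").iloc[0]
        # within 2 standard errors of the published mean 13.00, sd 5.41
        assert summ["mean"] == pytest.approx(13.00, abs=2 * 5.41 / np.sqrt(400))

    def test_single_value_group_reports_missing_sd(self):
        tm = TraitMatrix(
            pd.DataFrame(
                {
                    "individual_id": ["i1"],
                    "population": ["p"],
                    "species": ["s"],
                    "plant_length": [5.0],
                }
            ),
            {"plant_length": "cm"},
        )
        assert np.isnan(summarize_traits(tm, by="species")["sd"].iloc[0])

    def test_comparison_table_letters_separate_species(self, small_matrix):
        table = trait_comparison_table(small_matrix, by="species")
        pl = table[table["trait"] == "plant_length"].set_index("group")
        assert pl.loc["T_scardica", "letters"] != pl.loc["T_undulatifolia", "letters"]

    def test_ellipse_parameters_positive(self, small_matrix):
        X = standardize(small_matrix.values(["plant_length", "stem_width", "length_anther"]))
        model = lda_fit(X, small_matrix.data["species"])
        scores = lda_scores(model, X)
        # with 2 groups there is one axis; pad for the ellipse helper
        scores["LD2"] = 0.0
        ell = confidence_ellipses(scores, small_matrix.data["species"])
        assert (ell["radius_major"] >= 0).all()

    def test_wilks_lambda_small_for_separated_species(self, small_matrix):
        X = standardize(small_matrix.values(["plant_length", "stem_width", "length_anther"]))
        res = wilks_lambda(X, small_matrix.data["species"])
        assert 0 < res["wilks_lambda"] < 0.5
        assert res["p"] < 0.01
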