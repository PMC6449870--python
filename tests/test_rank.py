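"""Hit ranking: control correlations, score combination, the ML ensemble."""

import numpy as np
import pandas as pd
import pytest

from reprophen.rank import (build_ranking_table, combine_control_scores,
                            correlate_to_controls, permutation_null_auc,
                            select_hits, train_facilitator_predictor)


def profile_frame(rows, index=None, columns=None):
    rows = np.asarray(rows, dtype=float)
    return pd.DataFrame(
        rows, index=index or [f"t{i}" for i in range(len(rows))],
        columns=columns or [f"f{i}" for i in range(rows.shape[1])])


class TestControlCorrelation:
    def test_identical_and_negated_profiles(self):
        ctrl = profile_frame([[1.0, 2.0, 3.0, 1.0]], index=["Oct4"])
        prof = profile_frame([[1.0, 2.0, 3.0, 1.0],
                              [-1.0, -2.0, -3.0, -1.0]])
        r = correlate_to_controls(prof, ctrl)
        assert r.loc["t0", "r_Oct4"] == pytest.approx(1.0)
        assert r.loc["t1", "r_Oct4"] == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        # r((1,2,3),(1,2,4)) = 3 / sqrt(2 * 14/3)
        ctrl = profile_frame([[1.0, 2.0, 4.0]], index=["Myc"])
        prof = profile_frame([[1.0, 2.0, 3.0]])
        r = correlate_to_controls(prof, ctrl)
        assert r.loc["t0", "r_Myc"] == pytest.approx(0.9819805060619659,
                                                     abs=1e-12)

    def test_constant_profile_nan_with_warning(self):
        ctrl = profile_frame([[1.0, 2.0, 3.0]], index=["Trp53"])
        prof = profile_frame([[5.0, 5.0, 5.0]])
        with pytest.warns(RuntimeWarning, match="constant"):
            r = correlate_to_controls(prof, ctrl)
        assert np.isnan(r.loc["t0", "r_Trp53"])

    def test_too_few_shared_features_raises(self):
        ctrl = profile_frame([[1.0, 2.0]], index=["Myc"],
                             columns=["f0", "f1"])
        prof = profile_frame([[1.0, 2.0]], columns=["f0", "f1"])
        with pytest.raises(ValueError, match="shared features"):
            correlate_to_controls(prof, ctrl)


class TestCombineScores:
    @pytest.mark.parametrize("values,expected", [
        ((0.6, 0.3, 0.0), 0.3),
        ((1.0, 1.0, 1.0), 1.0),
        ((0.4, np.nan, 0.8), 0.6),
    ])
    def test_mean_combination(self, values, expected):
        corr = pd.DataFrame([values], index=["t0"],
                            columns=["r_a", "r_b", "r_c"])
        assert combine_control_scores(corr)["t0"] == pytest.approx(expected)

    def test_all_missing_gives_missing(self):
        corr = pd.DataFrame([[np.nan, np.nan]], index=["t0"],
                            columns=["r_a", "r_b"])
        assert np.isnan(combine_control_scores(corr)["t0"])

    def test_max_combination(self):
        corr = pd.DataFrame([[0.2, 0.9]], index=["t0"],
                            columns=["r_a", "r_b"])
        assert combine_control_scores(corr, method="max")["t0"] == 0.9

    def test_bounded(self, small_profiles):
        ps, _ = small_profiles
        ctrl = ps.profiles.loc[["Trp53", "Myc", "Oct4"]]
        score = combine_control_scores(
            correlate_to_controls(ps.profiles, ctrl))
        assert score.between(-1.0, 1.0).all()


def separable_data(n_pos=15, n_neg=60, nf=10, gap=4.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_pos + n_neg, nf))
    X[:n_pos, :3] += gap
    names = [f"fac{i}" for i in range(n_pos)] + \
        [f"t{i}" for i in range(n_neg)]
    return profile_frame(X, index=names), [f"fac{i}" for i in range(n_pos)]


class TestFacilitatorPredictor:
    def test_separable_signature_high_auc(self):
        profiles, fac = separable_data()
        pred = train_facilitator_predictor(profiles, fac, seed=0)
        assert pred.cv_auc >= 0.95
        assert pred.scores.between(0, 1).all()

    def test_duplicate_positive_scores_above_median(self):
        profiles, fac = separable_data()
        profiles.loc["dup"] = profiles.loc["fac0"]
        pred = train_facilitator_predictor(profiles, fac, seed=0)
        assert pred.scores["dup"] >= pred.scores.median()

    def test_single_class_raises(self):
        profiles, fac = separable_data()
        with pytest.raises(ValueError, match="single class"):
            train_facilitator_predictor(profiles, list(profiles.index))

    def test_too_few_positives_raises(self):
        profiles, _ = separable_data()
        with pytest.raises(ValueError, match="at least 3"):
            train_facilitator_predictor(profiles, ["fac0", "fac1"])

    def test_permuted_labels_near_chance(self):
        profiles, fac = separable_data()
        aucs = permutation_null_auc(profiles, fac, n_permutations=20,
                                    seed=0, n_estimators=25)
        assert 0.3 < aucs.mean() < 0.7


class TestSelectHits:
    def make_ranking(self, n=50, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "combined_score": rng.uniform(-1, 1, n),
            "facilitator_score": rng.uniform(0, 1, n),
        }, index=[f"t{i}" for i in range(n)])

    def test_exact_top_n_by_correlation(self):
        ranking = self.make_ranking()
        out = select_hits(ranking, n_corr_top=20, ml_quantile=1.0)
        assert out["selected_corr"].sum() == 20
        top = ranking["combined_score"].nlargest(20).index
        assert set(out.index[out["selected_corr"]]) == set(top)

    def test_union_deduplicated(self):
        ranking = self.make_ranking()
        out = select_hits(ranking, n_corr_top=10, ml_quantile=0.8)
        both = out["selected_corr"] & out["selected_ml"]
        union = out["selected_corr"] | out["selected_ml"]
        assert out["selected"].sum() == union.sum()
        assert (out.loc[both, "selected"]).all()

    def test_manual_inclusion(self):
        ranking = self.make_ranking()
        out = select_hits(ranking, n_corr_top=5, ml_quantile=1.0,
                          include=("t49",))
        assert out.loc["t49", "selected"]

    def test_n_top_too_large_raises(self):
        with pytest.raises(ValueError):
            select_hits(self.make_ranking(), n_corr_top=51)


class TestRankingInvariance:
    def test_redundant_feature_does_not_change_order(self, small_profiles):
        """Adding an exact copy of a feature (which the redundancy filter
        removes) leaves the combined-score ranking unchanged."""
        from reprophen.normalize import select_features
        ps, truth = small_profiles
        base = ps.profiles
        dup = base.copy()
        dup["f_dup"] = dup[dup.columns[0]]
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, red_base = select_features(base, 0.8)
            _, red_dup = select_features(dup, 0.8)
        ctrl = ["Trp53", "Myc", "Oct4"]
        lib = truth.index[truth["role"].isin(
            ["facilitator", "blocker", "neutral"])]
        for red in (red_base, red_dup):
            assert "f_dup" not in red.columns
        s1 = combine_control_scores(correlate_to_controls(
            red_base.loc[lib], red_base.loc[ctrl]))
        s2 = combine_control_scores(correlate_to_controls(
            red_dup.loc[lib], red_dup.loc[ctrl]))
        assert list(s1.sort_values().index) == list(s2.sort_values().index)
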