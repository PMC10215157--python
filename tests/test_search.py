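"""Exhaustive subset search with pooled-covariance linear discriminants."""

import numpy as np
import pandas as pd
import pytest

import vacuoquant as vq
from vacuoquant.descriptors import PREDICTOR_COLUMNS
from vacuoquant.search import (
    MEAN_PREDICTORS,
    accuracy,
    best_subsets,
    enumerate_subsets,
    fit_linear,
    loocv_accuracy,
    pareto_front,
    subset_flag_table,
    subset_search,
)


def make_predictor_table(rng, n_per_group=8, separated_col="mean_mal", gap=10.0):
    """Random predictor table where only ``separated_col`` separates
    CONTROL from TMG (by ``gap`` SDs); all other columns are shared noise."""
    rows = []
    for g in ("CONTROL", "TMG"):
        for i in range(n_per_group):
            row = {"image_id": f"{g}_{i:03d}", "group": g, "vd_present": True,
                   "n_regions": 5}
            for c in PREDICTOR_COLUMNS:
                row[c] = rng.normal(0.0, 1.0)
            if g == "TMG":
                row[separated_col] += gap
            rows.append(row)
    return pd.DataFrame(rows)


class TestEnumerateSubsets:
    def test_counts(self):
        assert len(enumerate_subsets(3)) == 7
        assert len(enumerate_subsets(10)) == 1023
        assert enumerate_subsets(1) == [1]

    def test_complete_and_sorted(self):
        s = enumerate_subsets(4)
        assert s == sorted(set(s))
        assert s[0] == 1 and s[-1] == 15

    def test_range_validation(self):
        with pytest.raises(ValueError):
            enumerate_subsets(0)
        with pytest.raises(ValueError):
            enumerate_subsets(21)


class TestFitLinear:
    def test_1d_separable(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        y = ["A", "A", "B", "B"]
        m = fit_linear(X, y, ("A", "B"))
        assert accuracy(m, X, y) == 1.0

    def test_2d_boundary_at_midpoint(self):
        # pooled-covariance LDA by hand: equal priors, boundary at x = 2.5
        X = np.array([[0.0, 0.0], [1.0, 0.0], [4.0, 0.0], [5.0, 0.0]])
        y = ["A", "A", "B", "B"]
        m = fit_linear(X, y, ("A", "B"))
        assert -m.intercept / m.weights[0] == pytest.approx(2.5, abs=1e-6)

    def test_xor_not_linearly_separable(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        y = ["A", "A", "B", "B"]
        m = fit_linear(X, y, ("A", "B"))
        assert accuracy(m, X, y) <= 0.75

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="no rows"):
            fit_linear(np.zeros((2, 1)), ["A", "A"], ("A", "B"))

    def test_majority_prediction_on_uninformative_features(self):
        X = np.zeros((32, 1))
        y = ["M"] * 26 + ["m"] * 6
        m = fit_linear(X, y, ("M", "m"))
        assert accuracy(m, X, y) == pytest.approx(26 / 32)

    def test_dimension_mismatch_raises(self):
        m = fit_linear(np.array([[0.0], [1.0]]), ["A", "B"], ("A", "B"))
        with pytest.raises(ValueError, match="dimension"):
            m.predict(np.zeros((3, 2)))

    def test_sklearn_oracle_agreement(self):
        """Independent cross-check: predictions and resubstitution accuracy
        match scikit-learn's LDA on small well-conditioned problems."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(23)
        for _ in range(25):
            n = int(rng.integers(6, 9))
            X = rng.normal(size=(n, 2))
            y = np.array(["A"] * (n // 2) + ["B"] * (n - n // 2))
            X[y == "B"] += rng.normal(1.0, 0.5, size=2)
            ours = fit_linear(X, y, ("A", "B"))
            ref = LinearDiscriminantAnalysis().fit(X, y)
            assert (ours.predict(X) == ref.predict(X)).all()
            assert accuracy(ours, X, y) == pytest.approx(ref.score(X, y), abs=1e-9)

    def test_loocv_on_far_separated_data(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(0, 1, (10, 2)), rng.normal(30, 1, (10, 2))])
        y = ["A"] * 10 + ["B"] * 10
        assert loocv_accuracy(X, y, ("A", "B")) == 1.0


class TestSubsetSearch:
    def test_three_predictor_toy_gives_seven_results_per_problem(self):
        rng = np.random.default_rng(1)
        table = make_predictor_table(rng)
        res = subset_search(table, "PAIRED", feature_columns=["mean_area", "sd_area", "mean_mal"])
        assert len(res) == 7

    def test_exhaustiveness_over_all_ten(self):
        rng = np.random.default_rng(2)
        table = make_predictor_table(rng)
        res = subset_search(table, "PAIRED")
        assert len(res) == 1023
        assert res.n_predictors.equals(res.bitmask.map(lambda b: bin(b).count("1")))

    def test_planted_separation_found_and_best_singleton_is_mal(self):
        rng = np.random.default_rng(3)
        table = make_predictor_table(rng, gap=10.0)
        res = subset_search(table, "PAIRED")
        assert res.accuracy.max() == 1.0
        singles = res[res.n_predictors == 1]
        mal_mask = 1 << PREDICTOR_COLUMNS.index("mean_mal")
        best_single = singles.loc[singles.accuracy.idxmax()]
        assert best_single.bitmask == mal_mask
        assert best_single.accuracy == 1.0

    def test_best_subset_at_least_best_singleton(self):
        rng = np.random.default_rng(4)
        table = make_predictor_table(rng, gap=1.0)
        for scheme in ("PAIRED", "VD_PRESENCE", "ONE_VS_REST"):
            if scheme == "VD_PRESENCE":
                table2 = table.copy()
                table2.loc[::3, "vd_present"] = False
            else:
                table2 = table
            res = subset_search(table2, scheme)
            if len(res) == 0:
                continue
            for _, sub in res.groupby("problem"):
                best = sub.accuracy.max()
                best_single = sub[sub.n_predictors == 1].accuracy.max()
                assert best >= best_single

    def test_determinism(self):
        rng = np.random.default_rng(6)
        table = make_predictor_table(rng)
        a = subset_search(table, "PAIRED").to_csv()
        b = subset_search(table, "PAIRED").to_csv()
        assert a == b

    def test_mean_restricted_search(self):
        rng = np.random.default_rng(7)
        table = make_predictor_table(rng)
        res = subset_search(table, "PAIRED", feature_columns=MEAN_PREDICTORS)
        assert len(res) == 2**5 - 1
        flags = subset_flag_table(best_subsets(res), MEAN_PREDICTORS)
        # SD columns are marked not-applicable
        assert (flags["sd_area"] == "-").all()


class TestSchemes:
    def _four_group_table(self, rng, n=4):
        rows = []
        for gi, g in enumerate(vq.GROUPS):
            for i in range(n):
                row = {"image_id": f"{g}_{i}", "group": g,
                       "vd_present": not (g == "CONTROL" and i < 2), "n_regions": 3}
                for ci, c in enumerate(PREDICTOR_COLUMNS):
                    row[c] = rng.normal(gi * 2.0 if ci == 0 else 0.0, 1.0)
                rows.append(row)
        return pd.DataFrame(rows)

    def test_one_vs_rest_has_four_problems(self):
        table = self._four_group_table(np.random.default_rng(8))
        res = subset_search(table, "ONE_VS_REST", feature_columns=["mean_area", "sd_area"])
        assert set(res.problem) == set(vq.GROUPS)
        assert len(res) == 4 * 3

    def test_common_predictors_average_of_one_vs_rest(self):
        feats = ["mean_area", "sd_area", "mean_mal"]
        table = self._four_group_table(np.random.default_rng(9))
        ovr = subset_search(table, "ONE_VS_REST", feature_columns=feats)
        common = subset_search(table, "COMMON_PREDICTORS", feature_columns=feats)
        for _, row in common.iterrows():
            per_class = ovr[ovr.bitmask == row.bitmask].accuracy
            assert row.accuracy == pytest.approx(per_class.mean())
            assert row.accuracy <= per_class.max() + 1e-12

    def test_control_vs_merged_filters_to_vd_present(self):
        table = self._four_group_table(np.random.default_rng(10))
        from vacuoquant.search import _problems_for_scheme

        problems = _problems_for_scheme(table, "CONTROL_VS_MERGED", PREDICTOR_COLUMNS)
        assert len(problems) == 1
        expected_rows = int(table.vd_present.sum())
        assert problems[0].X.shape[0] == expected_rows
        assert (problems[0].y == "CONTROL").sum() == 2

    def test_run_all_schemes_emits_five_reports(self):
        table = self._four_group_table(np.random.default_rng(12), n=5)
        reports = vq.run_all_schemes(
            table, feature_columns=["mean_area", "sd_area"],
            subset_3d=("mean_area", "sd_area", "mean_mal"),
        )
        for scheme in vq.SCHEMES:
            assert f"best_subsets_{scheme.lower()}" in reports
            assert f"pareto_{scheme.lower()}" in reports
        assert "common_histogram" in reports
        assert len(reports["common_histogram"]) == 3
        assert "separation3d" in reports


class TestParetoFront:
    def test_documented_example(self):
        res = pd.DataFrame(
            [
                {"scheme": "s", "problem": "p", "bitmask": 3, "n_predictors": 2, "accuracy": 0.9},
                {"scheme": "s", "problem": "p", "bitmask": 7, "n_predictors": 3, "accuracy": 0.9},
                {"scheme": "s", "problem": "p", "bitmask": 31, "n_predictors": 5, "accuracy": 0.95},
            ]
        )
        front = pareto_front(res)
        assert set(zip(front.n_predictors, front.accuracy)) == {(2, 0.9), (5, 0.95)}

    def test_single_result_is_its_own_front(self):
        res = pd.DataFrame(
            [{"scheme": "s", "problem": "p", "bitmask": 1, "n_predictors": 1, "accuracy": 0.5}]
        )
        assert len(pareto_front(res)) == 1

    def test_front_accuracies_strictly_increase_with_size(self):
        rng = np.random.default_rng(13)
        table = make_predictor_table(rng, gap=2.0)
        res = subset_search(table, "PAIRED")
        front = pareto_front(res)
        by_k = front.groupby("n_predictors").accuracy.first()
        assert (np.diff(by_k.to_numpy()) > 0).all()

    def test_ties_all_reported_in_best_subsets(self):
        res = pd.DataFrame(
            [
                {"scheme": "s", "problem": "p", "bitmask": 1, "n_predictors": 1, "accuracy": 0.9},
                {"scheme": "s", "problem": "p", "bitmask": 2, "n_predictors": 1, "accuracy": 0.9},
                {"scheme": "s", "problem": "p", "bitmask": 3, "n_predictors": 2, "accuracy": 0.9},
            ]
        )
        best = best_subsets(res)
        assert set(best.bitmask) == {1, 2}
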