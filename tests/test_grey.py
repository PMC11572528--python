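import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from resilgrey import (
    CohortSpec,
    GreyEvaluationModel,
    GreyScheme,
    WhiteningFunction,
    cluster_tree,
    default_scheme,
    grey_coefficients,
    grey_relational_score,
    simulate_cohort,
)
from resilgrey.scale import global_leaf_weights
from conftest import make_table


class TestWhiteningFunctions:
    @pytest.mark.parametrize(
        "form,breaks,x,expected",
        [
            ("upper_limit", (4, 5), 5.0, 1.0),
            ("upper_limit", (4, 5), 4.5, 0.5),
            ("upper_limit", (4, 5), 3.0, 0.0),
            ("lower_limit", (1, 2), 1.0, 1.0),
            ("lower_limit", (1, 2), 2.0, 0.0),
            ("triangular", (2, 3, 4), 3.0, 1.0),
            ("triangular", (2, 3, 4), 2.5, 0.5),
            ("moderate", (2, 3), 3.0, 1.0),
            ("moderate", (2, 3), 4.0, 0.0),
        ],
    )
    def test_piecewise_values(self, form, breaks, x, expected):
        assert WhiteningFunction(form, breaks)(x) == pytest.approx(expected)

    def test_out_of_axis_rating_rejected(self):
        from resilgrey.grey import whitening_value

        f = WhiteningFunction("upper_limit", (4, 5))
        with pytest.raises(ValueError, match="axis"):
            whitening_value(f, 9.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_range_and_monotone_form(self, seed):
        rng = np.random.default_rng(seed)
        a, b = np.sort(rng.uniform(0, 10, size=2))
        if b - a < 1e-3:
            b = a + 1e-3
        xs = np.linspace(a - 1, b + 1, 101)
        up = WhiteningFunction("upper_limit", (a, b))(xs)
        lo = WhiteningFunction("lower_limit", (a, b))(xs)
        for vals in (up, lo):
            assert np.all(vals >= 0) and np.all(vals <= 1)
        assert np.all(np.diff(up) >= -1e-12)   # non-decreasing
        assert np.all(np.diff(lo) <= 1e-12)    # non-increasing

    def test_breakpoints_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            WhiteningFunction("upper_limit", (5, 4))


class TestGreyCoefficients:
    def test_top_ratings_concentrate_on_excellent(self, chain_tree):
        table = make_table(chain_tree, np.full((20, 1), 5.0))
        out = grey_coefficients(table, default_scheme(), "a111")
        r = out["r_e"]
        assert r[0] == max(r)
        assert r.sum() == pytest.approx(1.0)

    def test_split_membership_point(self, chain_tree):
        # at 2.5 exactly two class functions are 0.5 under the default scheme
        table = make_table(chain_tree, [[2.5]])
        out = grey_coefficients(table, default_scheme(), "a111")
        np.testing.assert_allclose(out["r_e"], [0.0, 0.0, 0.5, 0.5], atol=1e-12)

    def test_matches_brute_force_summation(self, toy_tree):
        rng = np.random.default_rng(12)
        scheme = default_scheme()
        ratings = rng.integers(1, 6, size=(100, 4)).astype(float)
        table = make_table(toy_tree, ratings)
        for leaf_idx, leaf in enumerate(toy_tree.leaf_ids):
            out = grey_coefficients(table, scheme, leaf)
            n_e = np.zeros(4)
            for x in ratings[:, leaf_idx]:
                for e, cls in enumerate(scheme.classes):
                    n_e[e] += scheme.functions[cls](x)
            np.testing.assert_allclose(out["n_e"], n_e, atol=1e-12)
            np.testing.assert_allclose(out["r_e"], n_e / n_e.sum(), atol=1e-12)

    def test_degenerate_leaf_flagged_not_fatal(self, chain_tree):
        scheme = GreyScheme(
            classes=("excellent", "poor"),
            functions={
                "excellent": WhiteningFunction("upper_limit", (4, 5)),
                "poor": WhiteningFunction("lower_limit", (1, 2)),
            },
            grade_values={"excellent": 1.0, "poor": 0.4},
        )
        table = make_table(chain_tree, [[3.0]])  # both functions vanish at 3
        out = grey_coefficients(table, scheme, "a111")
        assert out["degenerate"]


class TestClusterTree:
    def test_all_top_ratings_attain_max_grade(self, tree):
        table = make_table(tree, np.full((25, 46), 5.0))
        report = cluster_tree(table, tree)
        assert report.composite("overall") == pytest.approx(1.0, abs=1e-12)
        assert report.nodes["composite"].max() == pytest.approx(1.0)
        assert report.respondent_scores["overall"].min() == pytest.approx(1.0)

    def test_chain_tree_scores_equal_leaf_score(self, chain_tree):
        table = make_table(chain_tree, [[4.0], [3.0], [5.0]])
        report = cluster_tree(table, chain_tree)
        leaf = report.composite("a111")
        for node in ("a1", "a11", "overall"):
            assert report.composite(node) == pytest.approx(leaf, abs=1e-12)

    def test_membership_vectors_normalised_everywhere(self, tree, cohort_347):
        from resilgrey.survey import filter_valid

        report = cluster_tree(filter_valid(cohort_347).valid, tree)
        for node_id in report.nodes.index:
            assert report.membership(node_id).sum() == pytest.approx(1.0, abs=1e-9)

    def test_identical_leaf_vectors_pass_through_weights(self, toy_tree):
        # all leaves rated identically => every node's membership is the
        # common leaf vector, whatever the weights
        table = make_table(toy_tree, np.full((10, 4), 4.0))
        report = cluster_tree(table, toy_tree)
        base = report.membership(toy_tree.leaf_ids[0])
        for node_id in report.nodes.index:
            np.testing.assert_allclose(report.membership(node_id), base, atol=1e-12)

    def test_composite_monotone_in_any_single_rating(self, toy_tree):
        rng = np.random.default_rng(6)
        ratings = rng.integers(1, 5, size=(15, 4)).astype(float)
        table = make_table(toy_tree, ratings)
        before = cluster_tree(table, toy_tree).nodes["composite"]
        bumped = ratings.copy()
        bumped[3, 2] += 1.0  # raise one respondent's rating on one leaf
        after = cluster_tree(make_table(toy_tree, bumped), toy_tree).nodes["composite"]
        assert np.all(after.to_numpy() >= before.to_numpy() - 1e-12)

    def test_planted_high_trait_group_scores_higher(self, tree):
        spec = CohortSpec(
            n_respondents=300,
            seed=77,
            group_effects={"exercise_habit": {"stable": 1.0}},
        )
        table = simulate_cohort(spec, tree)
        report = cluster_tree(table, tree)
        scores = report.respondent_scores["overall"]
        habit = table.covariates["exercise_habit"]
        assert scores[habit == "stable"].median() > scores[habit == "none"].median()


class TestGreyRelational:
    def test_reference_respondent_scores_one(self, toy_tree):
        ratings = np.array([[5, 5, 5, 5], [3, 2, 4, 1], [1, 1, 1, 1]], dtype=float)
        grades = grey_relational_score(make_table(toy_tree, ratings), toy_tree)
        assert grades.iloc[0] == pytest.approx(1.0, abs=1e-12)
        assert grades.iloc[1] > grades.iloc[2]

    def test_constant_table_grades_all_one(self, toy_tree):
        grades = grey_relational_score(
            make_table(toy_tree, np.full((5, 4), 3.0)), toy_tree
        )
        np.testing.assert_allclose(grades, 1.0)

    def test_matches_direct_implementation(self, toy_tree):
        rng = np.random.default_rng(15)
        ratings = rng.integers(1, 6, size=(50, 4)).astype(float)
        rho = 0.5
        grades = grey_relational_score(make_table(toy_tree, ratings), toy_tree, rho=rho)
        # independent direct computation
        ref = ratings.max(axis=0)
        delta = np.abs(ratings - ref)
        dmin, dmax = delta.min(), delta.max()
        gw = global_leaf_weights(toy_tree)
        w = np.array([gw[l] for l in toy_tree.leaf_ids])
        w = w / w.sum()
        expected = [
            sum(w[k] * (dmin + rho * dmax) / (delta[i, k] + rho * dmax)
                for k in range(4))
            for i in range(50)
        ]
        np.testing.assert_allclose(grades, expected, atol=1e-12)

    def test_permuting_leaves_with_weights_preserves_grades(self, toy_tree):
        rng = np.random.default_rng(19)
        ratings = rng.integers(1, 6, size=(20, 4)).astype(float)
        base = grey_relational_score(make_table(toy_tree, ratings), toy_tree)
        perm = [2, 3, 0, 1]
        permuted = make_table(toy_tree, ratings)
        permuted.ratings = permuted.ratings.iloc[:, perm]
        again = grey_relational_score(permuted, toy_tree)
        np.testing.assert_allclose(again, base, atol=1e-12)

    def test_rho_must_be_in_unit_interval(self, toy_tree):
        with pytest.raises(ValueError, match="rho"):
            grey_relational_score(
                make_table(toy_tree, np.ones((2, 4))), toy_tree, rho=0.0
            )


class TestModelResults:
    def test_fit_returns_scores_and_summary(self, tree, cohort_347):
        from resilgrey.survey import filter_valid

        table = filter_valid(cohort_347).valid
        results = GreyEvaluationModel(table, tree).fit()
        assert 0.4 <= results.overall_score <= 1.0
        text = results.summary()
        assert "overall" in text and "x2" in text
        assert results.respondent_scores.shape == (table.n_respondents, 63)

    def test_scheme_yaml_round_trip(self, tmp_path):
        scheme = default_scheme()
        path = tmp_path / "scheme.yaml"
        import yaml

        path.write_text(yaml.safe_dump(scheme.to_yaml_dict()))
        again = GreyScheme.from_yaml(path)
        assert again.classes == scheme.classes
        assert again.grade_values == scheme.grade_values
        for c in scheme.classes:
            assert again.functions[c] == scheme.functions[c]

    def test_compare_by_delegates_to_rank_tests(self, tree):
        spec = CohortSpec(n_respondents=200, seed=5,
                          group_effects={"training": {"yes": 0.8}})
        table = simulate_cohort(spec, tree)
        results = GreyEvaluationModel(table, tree).fit()
        res = results.compare_by("training")
        assert res.test == "mann-whitney"
        assert 0 <= res.p_value <= 1
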