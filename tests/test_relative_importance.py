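"""Relative weights and dominance analysis against independent algebra."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from affectvar.relative_importance import (
    RegressionProblem,
    all_subsets_r2,
    conditional_dominance,
    dominance_analysis,
    flag_importance,
    general_dominance,
    pairwise_dominance,
    r_squared_from_correlations,
    relative_weights,
    run_relative_importance,
    standardize,
)

from conftest import random_problem


def problem_from_corr(Rxx, rxy, labels=None, n=1000):
    """Build a RegressionProblem directly from population correlations."""
    Rxx = np.asarray(Rxx, dtype=float)
    rxy = np.asarray(rxy, dtype=float)
    p = len(rxy)
    labels = labels or [f"x{i}" for i in range(p)]
    return RegressionProblem(
        labels=labels, X=np.empty((n, p)), y=np.empty(n), Rxx=Rxx, rxy=rxy, n=n
    )


def brute_force_r2(X, y, idx):
    """Independent oracle: R^2 by direct least squares on raw data."""
    if not idx:
        return 0.0
    design = np.column_stack([np.ones(len(y)), X[:, list(idx)]])
    resid = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    return 1.0 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))


class TestRSquaredFromCorrelations:
    def test_single_predictor_is_squared_correlation(self):
        assert r_squared_from_correlations([[1.0]], [0.5]) == pytest.approx(0.25)

    def test_orthogonal_predictors_add(self):
        assert r_squared_from_correlations(np.eye(2), [0.3, 0.4]) == pytest.approx(0.25)

    def test_correlated_pair_hand_inverted(self):
        # Rxx=[[1,.5],[.5,1]], rxy=[.4,.4] -> beta=[4/15,4/15], R^2=0.2133...
        r2 = r_squared_from_correlations([[1, 0.5], [0.5, 1]], [0.4, 0.4])
        assert r2 == pytest.approx(0.4 * (4 / 15) * 2)

    def test_singular_subset_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            r_squared_from_correlations([[1, 1], [1, 1]], [0.3, 0.3])

    def test_matches_least_squares_on_data(self):
        rng = np.random.default_rng(21)
        problem, data = random_problem(rng, n=200, p=4)
        X = standardize(data[[f"x{i}" for i in range(4)]].to_numpy())
        y = standardize(data["y"].to_numpy())
        for idx in [(0,), (1, 3), (0, 1, 2, 3)]:
            expected = brute_force_r2(X, y, idx)
            got = r_squared_from_correlations(
                problem.Rxx[np.ix_(idx, idx)], problem.rxy[list(idx)]
            )
            assert got == pytest.approx(expected, abs=1e-10)


class TestAllSubsets:
    def test_counts(self):
        rng = np.random.default_rng(22)
        p2, _ = random_problem(rng, p=2)
        assert len(all_subsets_r2(p2)) == 4
        p10, _ = random_problem(rng, n=300, p=10)
        assert len(all_subsets_r2(p10)) == 1024

    def test_monotone_under_superset(self):
        rng = np.random.default_rng(23)
        problem, _ = random_problem(rng, p=5)
        subsets = all_subsets_r2(problem)
        full = frozenset(range(5))
        for s, r2 in subsets.items():
            assert r2 <= subsets[full] + 1e-12
            for i in range(5):
                assert subsets[s | {i}] >= r2 - 1e-12

    def test_enumeration_guard(self):
        problem = problem_from_corr(np.eye(21), np.zeros(21))
        with pytest.raises(ValueError, match="pre-select"):
            all_subsets_r2(problem)


class TestDominance:
    def test_size_zero_is_squared_zero_order_correlation(self):
        rng = np.random.default_rng(24)
        problem, _ = random_problem(rng, p=4)
        cond = conditional_dominance(all_subsets_r2(problem), 4)
        assert cond[:, 0] == pytest.approx(problem.rxy**2)

    def test_orthogonal_predictors_flat_conditional(self):
        problem = problem_from_corr(np.eye(3), [0.5, 0.3, 0.1])
        cond = conditional_dominance(all_subsets_r2(problem), 3)
        for i in range(3):
            assert cond[i] == pytest.approx(np.full(3, problem.rxy[i] ** 2))

    def test_against_brute_force_enumeration_p3(self):
        rng = np.random.default_rng(25)
        _, data = random_problem(rng, n=150, p=3)
        X = standardize(data[["x0", "x1", "x2"]].to_numpy())
        y = standardize(data["y"].to_numpy())
        problem = RegressionProblem.from_dataframe(data, "y", ["x0", "x1", "x2"])
        cond = conditional_dominance(all_subsets_r2(problem), 3)
        # independent oracle: direct least squares over explicit subset lists
        for i in range(3):
            others = [k for k in range(3) if k != i]
            for size in range(3):
                incs = [
                    brute_force_r2(X, y, list(s) + [i]) - brute_force_r2(X, y, list(s))
                    for s in combinations(others, size)
                ]
                assert cond[i, size] == pytest.approx(np.mean(incs), abs=1e-9)
        gen = general_dominance(cond)
        assert gen.sum() == pytest.approx(brute_force_r2(X, y, [0, 1, 2]), abs=1e-9)

    def test_general_dominance_sums_to_full_r2(self):
        rng = np.random.default_rng(26)
        for _ in range(10):
            problem, _ = random_problem(rng, p=5)
            subsets = all_subsets_r2(problem)
            gen = general_dominance(conditional_dominance(subsets, 5))
            assert (gen >= -1e-12).all()
            assert gen.sum() == pytest.approx(subsets[frozenset(range(5))], abs=1e-10)

    def test_p2_general_is_average_of_hand_algebra(self):
        # for p=2: general_i = (r_i^2 + R^2 - r_j^2) / 2
        problem = problem_from_corr([[1, 0.4], [0.4, 1]], [0.5, 0.2])
        subsets = all_subsets_r2(problem)
        gen = general_dominance(conditional_dominance(subsets, 2))
        r2 = subsets[frozenset({0, 1})]
        assert gen[0] == pytest.approx((0.5**2 + r2 - 0.2**2) / 2)
        assert gen[1] == pytest.approx((0.2**2 + r2 - 0.5**2) / 2)


class TestPairwiseDominance:
    def test_p2_orthogonal_complete_dominance(self):
        problem = problem_from_corr(np.eye(2), [0.5, 0.3])
        dom = dominance_analysis(problem)
        for level in ("complete", "conditional", "general"):
            mat = dom.matrices[level]
            assert mat.iloc[0, 1] == 1.0
            assert mat.iloc[1, 0] == 0.0

    def test_exact_ties_coded_half(self):
        # hand-built subset map for an exactly duplicated predictor pair
        subsets = {
            frozenset(): 0.0,
            frozenset({0}): 0.25,
            frozenset({1}): 0.25,
            frozenset({0, 1}): 0.25,
        }
        cond = conditional_dominance(subsets, 2)
        gen = general_dominance(cond)
        mats = pairwise_dominance(subsets, cond, gen)
        for level in ("complete", "conditional", "general"):
            assert mats[level][0, 1] == 0.5
            assert mats[level][1, 0] == 0.5

    def test_hierarchy_complete_implies_conditional_implies_general(self):
        rng = np.random.default_rng(27)
        for _ in range(20):
            problem, _ = random_problem(rng, n=120, p=4)
            dom = dominance_analysis(problem)
            comp = dom.matrices["complete"].to_numpy()
            cond = dom.matrices["conditional"].to_numpy()
            gen = dom.matrices["general"].to_numpy()
            decided = comp == 1.0
            assert (cond[decided] == 1.0).all()
            decided_cond = cond == 1.0
            assert (gen[decided_cond] == 1.0).all()

    def test_pairwise_table_layout(self):
        rng = np.random.default_rng(28)
        problem, _ = random_problem(rng, p=3)
        table = dominance_analysis(problem).pairwise_table()
        assert len(table) == 3
        assert set(table.columns) == {"pair", "complete", "conditional", "general"}


class TestRelativeWeights:
    def test_orthogonal_weights_equal_squared_correlations(self):
        problem = problem_from_corr(np.eye(3), [0.5, 0.3, 0.1])
        rw = relative_weights(problem)
        assert rw.table["rwi"].to_numpy() == pytest.approx(problem.rxy**2)
        assert rw.table["beta"].to_numpy() == pytest.approx(problem.rxy)

    def test_weights_sum_to_r2_and_percent_to_100(self):
        rng = np.random.default_rng(29)
        for _ in range(10):
            problem, _ = random_problem(rng, p=5)
            rw = relative_weights(problem)
            assert rw.table["rwi"].sum() == pytest.approx(rw.total_r2, abs=1e-10)
            assert rw.table["rwi_percent"].sum() == pytest.approx(100.0)
            assert (rw.table["rwi"] >= 0).all()

    def test_against_stepwise_matrix_algebra_oracle(self):
        # independently recompute Johnson's algebra with scipy's sqrtm
        from scipy.linalg import sqrtm

        rng = np.random.default_rng(30)
        problem, _ = random_problem(rng, p=3)
        lam = np.real(sqrtm(problem.Rxx))
        beta_star = np.linalg.inv(lam) @ problem.rxy
        expected = (lam**2) @ beta_star**2
        rw = relative_weights(problem)
        assert rw.table["rwi"].to_numpy() == pytest.approx(expected, abs=1e-10)

    def test_predictor_reordering_permutes_weights(self):
        rng = np.random.default_rng(31)
        _, data = random_problem(rng, p=4)
        labels = ["x0", "x1", "x2", "x3"]
        rw1 = relative_weights(RegressionProblem.from_dataframe(data, "y", labels))
        perm = ["x2", "x0", "x3", "x1"]
        rw2 = relative_weights(RegressionProblem.from_dataframe(data, "y", perm))
        a = rw1.table.set_index("label")["rwi"]
        b = rw2.table.set_index("label")["rwi"]
        assert a.sort_index().to_numpy() == pytest.approx(b.sort_index().to_numpy())

    def test_collinear_predictors_rejected_with_advice(self):
        data = pd.DataFrame(
            {"x0": np.arange(20.0), "y": np.arange(20.0) ** 2}
        )
        data["x1"] = 2 * data["x0"]
        with pytest.raises(ValueError, match="collinear"):
            RegressionProblem.from_dataframe(data, "y", ["x0", "x1"])


class TestFlagging:
    @pytest.mark.parametrize("rwi,important", [(0.021, True), (0.019, False), (0.02, True)])
    def test_threshold_is_inclusive(self, rwi, important):
        from affectvar.relative_importance import RelativeWeights

        rw = RelativeWeights(
            table=pd.DataFrame(
                {"label": ["x"], "beta": [0.1], "rwi": [rwi], "rwi_percent": [100.0]}
            ),
            total_r2=rwi,
        )
        flags = flag_importance(rw)
        assert bool(flags["important"].iloc[0]) is important
        assert flags.attrs["threshold"] == 0.02


class TestRunRelativeImportance:
    def test_deterministic_and_complete(self, small_study):
        from affectvar.cli import run_analysis

        report = run_analysis(small_study.ratings, small_study.attention, small_study.games)
        b1 = report.bundles["pre_ota"]
        b2 = run_relative_importance(report.dataset, "pre_ota")
        pd.testing.assert_frame_equal(b1.weights.table, b2.weights.table)
        assert set(report.bundles) == {
            "pre_ota",
            "post_ota",
            "pre_performance",
            "post_performance",
        }

    def test_unknown_outcome_rejected(self, small_study):
        from affectvar.cli import run_analysis

        report = run_analysis(small_study.ratings, small_study.attention, small_study.games)
        with pytest.raises(ValueError, match="unknown outcome"):
            run_relative_importance(report.dataset, "mid_change_ota")
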