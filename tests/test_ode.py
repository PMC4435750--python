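import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netrecon import InferenceParams, WeightedAdjacency, quantile_prune
from netrecon.ode import (
    bartlett_count,
    broken_stick_count,
    fit_pls,
    infer_projection,
    infer_stepwise,
    infer_tsni_integral,
    stepwise_select,
)
from netrecon.preprocess import RegressionData, build_regression_data
from .conftest import linear_courses


def orthonormal_design(n_rows, n_cols, seed):
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.normal(size=(n_rows, n_cols)))
    return q


def best_subset(X, y, tol=1e-8):
    """Exhaustive minimal-support exact-fit search (oracle for stepwise)."""
    p = X.shape[1]
    best = None
    for r in range(p + 1):
        for support in itertools.combinations(range(p), r):
            rss = float(y @ y) if not support else float(
                np.sum((y - X[:, support] @ np.linalg.lstsq(
                    X[:, support], y, rcond=None)[0]) ** 2))
            if rss < tol:
                return list(support)
        if best is not None:
            break
    return best


class TestStepwiseSelect:
    def test_matches_best_subset_on_orthonormal_design(self):
        """Noise-free sparse response: selection = exhaustive best subset."""
        X = orthonormal_design(40, 5, seed=0)
        y = 2.0 * X[:, 1] - 3.0 * X[:, 4]
        support, coefs = stepwise_select(X, y)
        assert support == best_subset(X, y) == [1, 4]
        assert np.allclose(coefs, [2.0, -3.0], atol=1e-10)

    def test_null_response_stays_empty(self):
        """Pure-noise responses should almost never recruit terms at tiny p_enter."""
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(50):
            X = rng.normal(size=(100, 5))
            y = rng.normal(size=100)
            support, _ = stepwise_select(X, y, p_enter=1e-6, p_remove=1e-5)
            hits += bool(support)
        assert hits <= 1

    def test_threshold_order_enforced(self):
        X = orthonormal_design(20, 3, seed=2)
        with pytest.raises(ValueError):
            stepwise_select(X, X[:, 0], p_enter=0.10, p_remove=0.05)

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            stepwise_select(np.zeros((2, 3)), np.zeros(2))

    def test_max_terms_cap(self):
        X = orthonormal_design(30, 4, seed=3)
        y = X[:, 0] + X[:, 1] + X[:, 2]
        support, _ = stepwise_select(X, y, max_terms=2, forward_only=True)
        assert len(support) == 2


class TestBrokenStick:
    def test_spectrum_with_one_dominant_fraction(self):
        # expectations for p=3: (0.6111, 0.2778, 0.1111)
        assert broken_stick_count(np.array([0.70, 0.20, 0.10])) == 1

    def test_dominant_component(self):
        assert broken_stick_count(np.array([0.99, 0.005, 0.005])) == 1

    def test_two_components_retained(self):
        # both leading fractions exceed their broken-stick expectations
        assert broken_stick_count(np.array([0.65, 0.30, 0.05])) == 2

    def test_uniform_floor(self):
        assert broken_stick_count(np.full(4, 0.25)) == 1

    def test_matches_direct_summation(self):
        """Frozen against the defining sum b_i = (1/p) * sum_{j>=i} 1/j."""
        p = 6
        b = [(1.0 / p) * sum(1.0 / j for j in range(i, p + 1))
             for i in range(1, p + 1)]
        fracs = np.array([0.45, 0.25, 0.12, 0.08, 0.06, 0.04])
        expected = 0
        for i in range(p):
            if fracs[i] > b[i]:
                expected += 1
            else:
                break
        assert broken_stick_count(fracs) == max(expected, 1)

    def test_empty_error(self):
        with pytest.raises(ValueError):
            broken_stick_count(np.array([]))


class TestBartlett:
    def test_equal_eigenvalues_floor(self):
        assert bartlett_count(np.ones(4), n_samples=100) == 1

    def test_one_dominant_eigenvalue(self):
        """Hand-evaluated: k=0 rejected (huge statistic), k=1 retained (0)."""
        eigs = np.array([100.0, 1.0, 1.0, 1.0, 1.0])
        assert bartlett_count(eigs, n_samples=500) == 1

    def test_two_dominant(self):
        eigs = np.array([50.0, 20.0, 1.0, 1.0, 1.0])
        assert bartlett_count(eigs, n_samples=500) == 2

    def test_sample_size_error(self):
        with pytest.raises(ValueError):
            bartlett_count(np.ones(5), n_samples=5)


class TestFitPLS:
    def test_vip_normalization_identity(self):
        """sum_j VIP_j^2 = p for any fit."""
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 6))
        y = X @ rng.normal(size=6) + 0.1 * rng.normal(size=30)
        for k in (1, 2, 4):
            fit = fit_pls(X, y, k)
            assert np.sum(fit.vip_scores ** 2) == pytest.approx(6.0, abs=1e-8)

    def test_single_predictor_vip_is_one(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 1))
        fit = fit_pls(X, 2.0 * X[:, 0], 1)
        assert fit.vip_scores[0] == pytest.approx(1.0)

    def test_relevant_predictor_has_largest_vip(self):
        """On an orthonormal design VIP ranking matches correlation ranking."""
        X = orthonormal_design(40, 4, seed=6)
        y = X[:, 0].copy()
        fit = fit_pls(X, y, 1)
        assert np.argmax(fit.vip_scores) == 0
        corr = np.abs([np.corrcoef(X[:, j], y)[0, 1] for j in range(4)])
        assert np.argmax(corr) == 0

    def test_rank_limit(self):
        X = orthonormal_design(10, 3, seed=7)
        with pytest.raises(ValueError):
            fit_pls(X, X[:, 0], 4)


class TestInferenceRoutes:
    def test_stepwise_recovers_linear_system(self, two_node_system):
        A = two_node_system
        courses = linear_courses(A, 5, seed=1)
        X = np.vstack([tc.states for tc in courses])
        data = RegressionData(response=X @ A.T, design=X,
                              times=np.zeros(len(X)), mode="gradient")
        w = infer_stepwise(data, InferenceParams())
        assert np.array_equal(np.sign(w.weights), np.sign(A))
        assert np.allclose(w.weights, A, atol=1e-8)

    def test_constant_states_give_empty_network(self):
        data = RegressionData(response=np.zeros((10, 3)),
                              design=np.ones((10, 3)),
                              times=np.arange(10.0), mode="gradient")
        w = infer_stepwise(data, InferenceParams())
        assert np.count_nonzero(w.weights) == 0

    def test_include_self_false_masks_diagonal(self, two_node_system):
        courses = linear_courses(two_node_system, 3, seed=2)
        data = build_regression_data(courses, mode="gradient")
        w = infer_stepwise(data, InferenceParams(include_self=False))
        assert np.all(np.diag(w.weights) == 0)

    def test_projection_rules_agree_on_well_conditioned_data(self, three_node_cascade):
        """Both latent-count rules should recover the dominant edge set."""
        A = three_node_cascade
        courses = linear_courses(A, 20, seed=3)
        X = np.vstack([tc.states for tc in courses])
        data = RegressionData(response=X @ A.T, design=X,
                              times=np.zeros(len(X)), mode="gradient")
        supports = {}
        for rule in ("broken_stick", "bartlett"):
            w = infer_projection(data, InferenceParams(lv_rule=rule,
                                                       vip_threshold=0.0))
            supports[rule] = set(map(tuple, np.argwhere(
                quantile_prune(w, 0.0).adjacency != 0)))
        overlap = len(supports["broken_stick"] & supports["bartlett"])
        assert overlap / max(len(supports["broken_stick"]), 1) >= 0.8

    def test_vip_screening_recovers_cascade(self, three_node_cascade):
        """A moderate VIP cut keeps true regulators on conditioned data."""
        A = three_node_cascade
        courses = linear_courses(A, 20, seed=4)
        X = np.vstack([tc.states for tc in courses])
        data = RegressionData(response=X @ A.T, design=X,
                              times=np.zeros(len(X)), mode="gradient")
        w = infer_projection(data, InferenceParams(vip_threshold=0.5))
        assert np.array_equal(quantile_prune(w, 0.0).adjacency, np.sign(A))

    def test_tsni_requires_integral_mode(self, two_node_system):
        courses = linear_courses(two_node_system, 2, seed=5)
        data = build_regression_data(courses, mode="gradient")
        with pytest.raises(ValueError):
            infer_tsni_integral(data, InferenceParams())

    def test_tsni_recovers_elementwise(self, two_node_system):
        A = two_node_system
        courses = linear_courses(A, 3, T=3.0, m=50, seed=6)
        data = build_regression_data(courses, mode="integral")
        w = infer_tsni_integral(data, InferenceParams())
        assert np.allclose(w.weights, A, atol=1e-2)

    def test_tsni_sparsity_cap_zero(self, two_node_system):
        courses = linear_courses(two_node_system, 2, seed=7)
        data = build_regression_data(courses, mode="integral")
        w = infer_tsni_integral(data, InferenceParams(max_regressors=0))
        assert np.count_nonzero(w.weights) == 0

    def test_no_perturbation_no_gains(self, two_node_system):
        courses = linear_courses(two_node_system, 2, seed=8)
        data = build_regression_data(courses, mode="integral")
        w = infer_tsni_integral(data, InferenceParams())
        assert w.perturbation_gains is None


class TestQuantilePrune:
    def test_zero_quantile_keeps_all(self):
        w = WeightedAdjacency(np.array([[0.0, 1.0], [-2.0, 0.0]]))
        assert quantile_prune(w, 0.0).n_edges == 2

    def test_top_quantile_keeps_largest(self):
        rng = np.random.default_rng(9)
        vals = rng.permutation(np.arange(1.0, 11.0))
        weights = np.zeros((4, 4))
        weights.flat[[1, 2, 3, 6, 7, 8, 9, 11, 12, 13]] = vals
        net = quantile_prune(WeightedAdjacency(weights), 0.95)
        assert net.n_edges == 1
        assert weights.flat[np.flatnonzero(net.adjacency.flat)] == 10.0

    def test_all_zero_matrix(self):
        assert quantile_prune(WeightedAdjacency(np.zeros((3, 3))), 0.5).n_edges == 0

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1), st.floats(0, 1), st.floats(0, 1))
    def test_monotone_in_quantile(self, seed, q1, q2):
        """Edges at the larger quantile are a subset of the smaller's."""
        q1, q2 = sorted((q1, q2))
        rng = np.random.default_rng(seed)
        weights = rng.normal(size=(5, 5)) * rng.integers(0, 2, size=(5, 5))
        w = WeightedAdjacency(weights)
        lo = quantile_prune(w, q1).adjacency != 0
        hi = quantile_prune(w, q2).adjacency != 0
        assert np.all(~hi | lo)


class TestParams:
    def test_threshold_ordering_invariant(self):
        with pytest.raises(ValueError):
            InferenceParams(p_enter=0.2, p_remove=0.1)

    def test_quantile_bounds(self):
        with pytest.raises(ValueError):
            InferenceParams(quantile_q=1.5)
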