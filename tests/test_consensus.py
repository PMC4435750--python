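import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netrecon import SignedNetwork, evaluate, optimize_quorum, quorum_consensus
from .conftest import network_with_edges


def random_networks(n_nodes, n_nets, seed, p_edge=0.3):
    rng = np.random.default_rng(seed)
    nets = []
    for _ in range(n_nets):
        adj = (rng.random((n_nodes, n_nodes)) < p_edge).astype(int)
        adj *= rng.choice([-1, 1], size=adj.shape)
        np.fill_diagonal(adj, 0)
        nets.append(SignedNetwork(adj))
    return nets


class TestEvaluate:
    @pytest.mark.parametrize("n_pred,n_true,n_ref,ppv,recall,f", [
        (14, 8, 19, 0.571, 0.421, 0.48),
        (12, 3, 19, 0.25, 0.158, 0.19),
    ])
    def test_counts_to_metrics(self, n_pred, n_true, n_ref, ppv, recall, f):
        n = 10
        ref_edges = [(i % n, (i + 1 + i // n) % n) for i in range(n_ref)]
        # build a reference with exactly n_ref edges and an inferred network
        # sharing exactly n_true of them
        ref = np.zeros((n, n), dtype=int)
        slots = [(i, j) for i in range(n) for j in range(n) if i != j]
        for (s, t) in slots[:n_ref]:
            ref[t, s] = 1
        pred = np.zeros((n, n), dtype=int)
        for (s, t) in slots[:n_true]:
            pred[t, s] = 1
        for (s, t) in slots[n_ref:n_ref + (n_pred - n_true)]:
            pred[t, s] = 1
        res = evaluate(SignedNetwork(pred), SignedNetwork(ref))
        assert (res.tp, res.fp, res.fn) == (n_true, n_pred - n_true, n_ref - n_true)
        assert res.ppv == pytest.approx(ppv, abs=5e-3)
        assert res.recall == pytest.approx(recall, abs=5e-3)
        assert res.f_score == pytest.approx(f, abs=5e-3)

    def test_perfect_and_empty_extremes(self, small_reference):
        perfect = evaluate(small_reference, small_reference)
        assert (perfect.ppv, perfect.recall, perfect.f_score) == (1.0, 1.0, 1.0)
        empty = evaluate(SignedNetwork(np.zeros((4, 4), dtype=int)), small_reference)
        assert (empty.ppv, empty.recall, empty.f_score) == (0.0, 0.0, 0.0)

    def test_sign_is_ignored(self, small_reference):
        flipped = SignedNetwork(-small_reference.adjacency)
        res = evaluate(flipped, small_reference)
        assert res.f_score == 1.0

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(0)
        ref = random_networks(6, 1, seed=1)[0]
        inf = random_networks(6, 1, seed=2)[0]
        perm = rng.permutation(6)
        ref_p = SignedNetwork(ref.adjacency[np.ix_(perm, perm)])
        inf_p = SignedNetwork(inf.adjacency[np.ix_(perm, perm)])
        a = evaluate(inf, ref)
        b = evaluate(inf_p, ref_p)
        assert (a.tp, a.fp, a.fn) == (b.tp, b.fp, b.fn)

    def test_harmonic_mean_identity(self):
        res = evaluate(*random_networks(8, 2, seed=3))
        if res.ppv == res.recall and res.ppv > 0:
            assert res.f_score == pytest.approx(res.ppv)
        # and in general F is the harmonic mean
        if res.ppv + res.recall > 0:
            assert res.f_score == pytest.approx(
                2 * res.ppv * res.recall / (res.ppv + res.recall))

    def test_diagonal_toggle(self):
        adj = np.eye(3, dtype=int)
        net = SignedNetwork(adj)
        assert evaluate(net, net, ignore_diagonal=True).tp == 0
        assert evaluate(net, net, ignore_diagonal=False).tp == 3

    def test_size_mismatch(self):
        with pytest.raises(ValueError):
            evaluate(SignedNetwork(np.zeros((3, 3), dtype=int)),
                     SignedNetwork(np.zeros((4, 4), dtype=int)))


class TestQuorum:
    def test_union_and_intersection(self):
        nets = random_networks(5, 4, seed=5)
        union = quorum_consensus(nets, 1)
        inter = quorum_consensus(nets, len(nets))
        stack = np.stack([n.adjacency != 0 for n in nets])
        assert np.array_equal(union.adjacency != 0, stack.any(axis=0))
        assert np.array_equal(inter.adjacency != 0, stack.all(axis=0))

    def test_quorum_three_of_fifteen(self):
        nets = random_networks(6, 15, seed=6, p_edge=0.15)
        cons = quorum_consensus(nets, 3)
        counts = np.stack([n.adjacency != 0 for n in nets]).sum(axis=0)
        assert np.array_equal(cons.adjacency != 0, counts >= 3)

    def test_majority_sign_tie_positive(self):
        a = network_with_edges(3, [(0, 1, 1)])
        b = network_with_edges(3, [(0, 1, -1)])
        cons = quorum_consensus([a, b], 1)
        assert cons.adjacency[1, 0] == 1

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(1, 6), st.integers(1, 6))
    def test_monotone_in_quorum(self, seed, k1, k2):
        k1, k2 = sorted((k1, k2))
        nets = random_networks(5, 6, seed=seed)
        lo = quorum_consensus(nets, k1).adjacency != 0
        hi = quorum_consensus(nets, k2).adjacency != 0
        assert np.all(~hi | lo)

    def test_size_mismatch(self):
        with pytest.raises(ValueError):
            quorum_consensus(random_networks(4, 1, 0) + random_networks(5, 1, 0), 1)


class TestOptimizeQuorum:
    def test_matches_brute_force(self):
        """The exhaustive-scan definition, cross-checked edge for edge."""
        for seed in range(5):
            nets = random_networks(5, 5, seed=100 + seed)
            ref = random_networks(5, 1, seed=200 + seed)[0]
            k_star, cons, res = optimize_quorum(nets, ref)
            brute = max(
                ((k, evaluate(quorum_consensus(nets, k), ref).f_score)
                 for k in range(1, 6)),
                key=lambda kv: kv[1],
            )
            assert res.f_score == pytest.approx(brute[1])
            # smallest k attaining the max
            for k in range(1, k_star):
                assert evaluate(quorum_consensus(nets, k), ref).f_score < res.f_score

    def test_perfect_match_returns_f_one(self, small_reference):
        nets = [small_reference.copy() for _ in range(3)]
        k_star, cons, res = optimize_quorum(nets, small_reference)
        assert res.f_score == 1.0 and k_star == 1

    def test_identical_networks_tie_break(self):
        nets = [network_with_edges(4, [(0, 1, 1), (1, 2, 1)]) for _ in range(4)]
        ref = network_with_edges(4, [(0, 1, 1), (2, 3, 1)])
        k_star, _, _ = optimize_quorum(nets, ref)
        assert k_star == 1
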