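import math

import numpy as np
import pytest

from traitrates import mklik, synthdata
from traitrates.mklik import (LikelihoodError, NEG_INF, PruningEngine, QMatrix,
                              RootPrior, brute_force_log_likelihood,
                              brute_force_node_marginals, log_likelihood,
                              node_marginals, series_expm,
                              transition_probabilities)
from traitrates.treeio import TraitData, parse_newick

from conftest import random_instance


class TestQMatrix:
    def test_rows_sum_zero(self):
        Q = QMatrix.equal_rates(5, 0.3)
        assert np.allclose(Q.q.sum(axis=1), 0.0, atol=1e-12)

    def test_negative_off_diagonal_rejected(self):
        off = np.full((5, 5), 0.1)
        off[0, 1] = -0.1
        with pytest.raises(LikelihoodError):
            QMatrix.from_off_diagonal(off)

    def test_bad_row_sums_rejected(self):
        q = np.full((5, 5), 0.1)
        with pytest.raises(LikelihoodError):
            QMatrix(q)

    def test_stationary_uniform_for_equal_rates(self):
        Q = QMatrix.equal_rates(5, 0.7)
        assert np.allclose(Q.stationary_distribution(), 0.2, atol=1e-10)


class TestRootPrior:
    def test_uniform(self):
        pi = RootPrior.uniform(5)
        assert np.allclose(pi.pi, 0.2)

    def test_rejects_unnormalized(self):
        with pytest.raises(LikelihoodError):
            RootPrior(np.array([0.5, 0.5, 0.1, 0.0, 0.0]))

    def test_rejects_negative(self):
        with pytest.raises(LikelihoodError):
            RootPrior(np.array([1.2, -0.2, 0.0, 0.0, 0.0]))


class TestTransitionProbabilities:
    def test_t_zero_is_identity(self):
        Q = QMatrix.equal_rates(5, 0.3)
        assert np.allclose(transition_probabilities(Q, 0.0), np.eye(5), atol=1e-12)

    def test_equal_rates_closed_form(self):
        # P_ii(t) = 1/k + (1 - 1/k) exp(-k r t)
        r, t = 0.1, 2.0
        Q = QMatrix.equal_rates(5, r)
        P = transition_probabilities(Q, t)
        expected = 1 / 5 + (4 / 5) * math.exp(-5 * r * t)
        assert P[0, 0] == pytest.approx(expected, abs=1e-12)
        assert P[0, 0] == pytest.approx(0.494304, abs=5e-7)

    def test_negative_t_rejected(self):
        with pytest.raises(LikelihoodError):
            transition_probabilities(QMatrix.equal_rates(5, 0.1), -0.5)

    def test_rows_stochastic(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            Q = QMatrix.from_off_diagonal(rng.uniform(0, 3, (5, 5)))
            P = transition_probabilities(Q, float(rng.uniform(0, 5)))
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-9)
            assert P.min() >= 0.0 and P.max() <= 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_series_oracle(self, seed):
        rng = np.random.default_rng(seed)
        Q = QMatrix.from_off_diagonal(rng.uniform(0, 1.5, (5, 5)))
        P = transition_probabilities(Q, 0.7)
        P_series = series_expm(Q.q, 0.7)
        assert np.abs(P - P_series).max() < 1e-8

    def test_structural_zeros(self):
        off = np.zeros((5, 5))
        off[0, 1] = 2.0  # only one allowed transition: defective Q
        Q = QMatrix.from_off_diagonal(off)
        P = transition_probabilities(Q, 1.0)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-9)
        assert P[0, 1] == pytest.approx(1 - math.exp(-2.0), abs=1e-9)


class TestLogLikelihood:
    def test_zero_length_identical_tips(self, zero_cherry, uniform_pi):
        traits = TraitData.from_labels({"a": "CI", "b": "CI"})
        Q = QMatrix.equal_rates(5, 0.5)
        lnl = log_likelihood(zero_cherry, traits, Q, uniform_pi)
        assert lnl == pytest.approx(math.log(0.2), abs=1e-12)

    def test_zero_q_different_tips_impossible(self, zero_cherry, uniform_pi):
        tree = parse_newick("(a:1,b:1);")
        traits = TraitData.from_labels({"a": "CI", "b": "MK"})
        Q = QMatrix(np.zeros((5, 5)))
        assert mklik.log_likelihood(tree, traits, Q, uniform_pi) == NEG_INF

    def test_dimension_mismatch(self, zero_cherry, uniform_pi):
        traits = TraitData.from_labels({"a": "CI", "b": "CI"})
        with pytest.raises(LikelihoodError):
            log_likelihood(zero_cherry, traits, QMatrix.equal_rates(3, 0.1), uniform_pi)

    def test_matches_brute_force_bulk(self, uniform_pi):
        # the central oracle property: 200 random small instances
        rng = np.random.default_rng(11)
        for _ in range(200):
            tree, Q, traits = random_instance(rng)
            a = log_likelihood(tree, traits, Q, uniform_pi)
            b = brute_force_log_likelihood(tree, traits, Q, uniform_pi)
            if b == NEG_INF:
                assert a == NEG_INF
            else:
                assert a == pytest.approx(b, abs=1e-9)

    def test_child_order_invariance(self, uniform_pi):
        rng = np.random.default_rng(5)
        tree, Q, traits = random_instance(rng, n_min=5, n_max=6)
        a = log_likelihood(tree, traits, Q, uniform_pi)
        for node in tree.internal_nodes():
            node.children.reverse()
        b = log_likelihood(tree, traits, Q, uniform_pi)
        assert a == pytest.approx(b, abs=1e-12)

    def test_star_closed_form(self, uniform_pi):
        # star likelihood = sum_s pi_s prod_tips P_{s, state}(b_tip)
        rng = np.random.default_rng(8)
        star = parse_newick("(a:0.5,b:1.5,c:1.0,d:0.2);")
        labels = {"a": "CI", "b": "MK", "c": "CI", "d": "PI"}
        traits = TraitData.from_labels(labels)
        Q = QMatrix.from_off_diagonal(rng.uniform(0, 2, (5, 5)))
        total = 0.0
        for s in range(5):
            prod = 0.2
            for leaf in star.leaves():
                P = transition_probabilities(Q, leaf.length)
                prod *= P[s, traits.states[leaf.name]]
            total += prod
        assert log_likelihood(star, traits, Q, uniform_pi) == pytest.approx(
            math.log(total), abs=1e-10)

    def test_no_underflow_500_leaves(self, uniform_pi):
        tree = synthdata.simulate_yule_tree(500, 1.0, seed=0)
        Q = QMatrix.equal_rates(5, 0.1)
        traits, _ = synthdata.simulate_trait(tree, Q, uniform_pi, seed=1)
        lnl = log_likelihood(tree, traits, Q, uniform_pi)
        assert math.isfinite(lnl)

    def test_single_leaf(self, uniform_pi):
        tree = parse_newick("(a:1);")
        traits = TraitData.from_labels({"a": "MK"})
        Q = QMatrix.equal_rates(5, 0.1)
        assert brute_force_log_likelihood(tree, traits, Q, uniform_pi) == \
            pytest.approx(math.log(0.2), abs=1e-12)


class TestBruteForceGuard:
    def test_too_many_internal_nodes(self, uniform_pi):
        tree = synthdata.simulate_yule_tree(12, 1.0, seed=0)
        Q = QMatrix.equal_rates(5, 0.1)
        traits, _ = synthdata.simulate_trait(tree, Q, uniform_pi, seed=0)
        with pytest.raises(LikelihoodError):
            brute_force_log_likelihood(tree, traits, Q, uniform_pi)


class TestNodeMarginals:
    def test_zero_length_cherry_forced(self, uniform_pi):
        tree = parse_newick("(a:0,b:0);")
        traits = TraitData.from_labels({"a": "MK", "b": "MK"})
        Q = QMatrix.equal_rates(5, 0.4)
        probs = node_marginals(tree, traits, Q, uniform_pi, tree.root)
        mk = traits.alphabet.index("MK")
        assert probs[mk] == pytest.approx(1.0, abs=1e-12)

    def test_long_branch_stationary_limit(self, uniform_pi):
        tree = parse_newick("(a:10000,b:10000,c:10000);")
        traits = TraitData.from_labels({"a": "CI", "b": "CI", "c": "CI"})
        Q = QMatrix.equal_rates(5, 1.0)
        probs = node_marginals(tree, traits, Q, uniform_pi, tree.root)
        assert np.abs(probs - 0.2).max() < 1e-3

    def test_matches_brute_force(self, uniform_pi):
        rng = np.random.default_rng(21)
        for _ in range(30):
            tree, Q, traits = random_instance(rng, n_min=3, n_max=3)
            for node in tree.internal_nodes():
                a = node_marginals(tree, traits, Q, uniform_pi, node)
                b = brute_force_node_marginals(tree, traits, Q, uniform_pi, node)
                assert np.abs(a - b).max() < 1e-9
                assert a.sum() == pytest.approx(1.0, abs=1e-9)

    def test_impossible_data_raises(self, uniform_pi):
        tree = parse_newick("(a:1,b:1);")
        traits = TraitData.from_labels({"a": "CI", "b": "MK"})
        Q = QMatrix(np.zeros((5, 5)))
        with pytest.raises(LikelihoodError):
            node_marginals(tree, traits, Q, uniform_pi, tree.root)


class TestEngineReuse:
    def test_set_tip_states_changes_result(self, uniform_pi):
        tree = parse_newick("((a:1,b:1):1,c:2);")
        traits = TraitData.from_labels({"a": "CI", "b": "CI", "c": "CI"})
        engine = PruningEngine(tree, traits)
        Q = QMatrix.equal_rates(5, 0.2)
        l1 = engine.log_likelihood(Q, uniform_pi)
        engine.set_tip_states([0, 0, 1])
        l2 = engine.log_likelihood(Q, uniform_pi)
        assert l1 != l2

    def test_engine_matches_oneshot(self, uniform_pi):
        rng = np.random.default_rng(2)
        tree, Q, traits = random_instance(rng)
        engine = PruningEngine(tree, traits)
        assert engine.log_likelihood(Q, uniform_pi) == \
            log_likelihood(tree, traits, Q, uniform_pi)
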