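import math
from collections import Counter

import numpy as np
import pytest

from traitrates import rjmcmc, synthdata
from traitrates.mklik import QMatrix, RootPrior
from traitrates.mlfit import PAIRS
from traitrates.rjmcmc import (BFTable, ChainTrace, MCMCError, PriorSpec,
                               ancestral_at_mrca, bayes_factors,
                               classify_models, geweke_diagnostic,
                               posterior_rate_means, run_chain)
from traitrates.treeio import TraitData, parse_newick


@pytest.fixture(scope="module")
def tiny_data():
    tree = parse_newick("((a:0.5,b:0.5):0.5,(c:0.5,d:0.5):0.5);")
    traits = TraitData.from_labels({"a": "CI", "b": "CI", "c": "MK", "d": "MK"})
    return tree, traits


@pytest.fixture(scope="module")
def prior_trace(tiny_data):
    tree, traits = tiny_data
    return run_chain([tree], traits, PriorSpec(100.0), n_generations=60000,
                     sample_freq=3, seed=11, prior_only=True)


class TestRunChain:
    def test_sample_count(self, tiny_data):
        tree, traits = tiny_data
        trace = run_chain([tree], traits, PriorSpec(1.0), n_generations=1000,
                          sample_freq=100, seed=0, prior_only=True)
        assert trace.n_samples == 10

    def test_leafset_mismatch(self, tiny_data):
        tree, traits = tiny_data
        other = parse_newick("((a:1,b:1):1,(c:1,e:1):1);")
        with pytest.raises(MCMCError):
            run_chain([tree, other], traits, PriorSpec(1.0), 1000, 100, seed=0)

    def test_prior_recovery(self, prior_trace):
        sub = prior_trace.post_burn()
        nz = sub.pair_rates[sub.pair_rates > 0]
        assert nz.mean() == pytest.approx(100.0, rel=0.05)

    def test_seed_determinism(self, tiny_data):
        tree, traits = tiny_data
        kw = dict(n_generations=3000, sample_freq=10, seed=42)
        t1 = run_chain([tree], traits, PriorSpec(10.0), **kw)
        t2 = run_chain([tree], traits, PriorSpec(10.0), **kw)
        assert t1.signatures == t2.signatures
        assert np.array_equal(t1.pair_rates, t2.pair_rates)
        assert np.array_equal(t1.lnl, t2.lnl)

    def test_monomorphic_tips_shrink_rates(self, uniform_pi):
        # likelihood penalises change when all tips agree
        tree = synthdata.simulate_yule_tree(12, 1.0, seed=0)
        traits = TraitData.from_labels({n: "CI" for n in tree.leaf_names()})
        post = run_chain([tree], traits, PriorSpec(100.0), n_generations=20000,
                         sample_freq=10, seed=1, pi=uniform_pi)
        sub = post.post_burn()
        nz = sub.pair_rates[sub.pair_rates > 0]
        assert nz.mean() < 100.0

    def test_two_prior_chains_agree_on_k(self, tiny_data, prior_trace):
        tree, traits = tiny_data
        other = run_chain([tree], traits, PriorSpec(100.0), n_generations=60000,
                          sample_freq=3, seed=99, prior_only=True)
        c1 = Counter(prior_trace.post_burn().k.tolist())
        c2 = Counter(other.post_burn().k.tolist())
        n1, n2 = sum(c1.values()), sum(c2.values())
        tv = 0.5 * sum(abs(c1.get(k, 0) / n1 - c2.get(k, 0) / n2)
                       for k in set(c1) | set(c2))
        assert tv < 0.05

    def test_tree_switching(self, tiny_data):
        tree, traits = tiny_data
        tree2 = parse_newick("((a:0.5,c:0.5):0.5,(b:0.5,d:0.5):0.5);")
        trace = run_chain([tree, tree2], traits, PriorSpec(10.0),
                          n_generations=5000, sample_freq=5, seed=3)
        assert set(np.unique(trace.tree_index)) == {0, 1}


class TestFixedModelPosterior:
    def test_uninformative_data_posterior_equals_prior(self, uniform_pi):
        # two identical tips on zero branches: likelihood is constant, so
        # the fixed-model posterior rate equals the Exp(mu) prior
        tree = parse_newick("(a:0,b:0);")
        traits = TraitData.from_labels({"a": "CI", "b": "CI"})
        mu = 5.0
        weights = {"rate_update": 0.9, "prior_redraw": 0.1, "reassign": 0.0,
                   "split": 0.0, "merge": 0.0, "tree_switch": 0.0}
        trace = run_chain([tree], traits, PriorSpec(mu), n_generations=40000,
                          sample_freq=4, seed=2, pi=uniform_pi,
                          move_weights=weights)
        sub = trace.post_burn()
        rates = sub.pair_rates[:, 0]
        n_eff = len(rates) / 20  # crude autocorrelation allowance
        mc_se = rates.std(ddof=1) / math.sqrt(n_eff)
        assert abs(rates.mean() - mu) < 3 * mc_se


class TestClassify:
    def test_counts(self):
        trace = _fake_trace(["m1", "m1", "m2"], [2, 2, 3])
        counts = classify_models(trace, burn_frac=0.0)
        assert counts.by_signature == {"m1": 2, "m2": 1}
        assert counts.by_k == {2: 2, 3: 1}
        assert sum(counts.by_k.values()) == counts.total

    def test_one_class_no_zero_is_k1(self, tiny_data):
        tree, traits = tiny_data
        trace = run_chain([tree], traits, PriorSpec(1.0), 500, 50, seed=0,
                          prior_only=True)
        # initial model: all 20 pairs in one class
        state_sig = ",".join(["C1"] * 20)
        assert trace.signatures[0].count("C") >= 1  # canonical labels
        counts = classify_models(trace, burn_frac=0.0)
        assert all(k >= 0 for k in counts.by_k)

    def test_empty_trace_raises(self):
        with pytest.raises(MCMCError):
            classify_models(_fake_trace([], []))

    def test_classification_is_pure(self, prior_trace):
        a = classify_models(prior_trace)
        b = classify_models(prior_trace)
        assert a.by_signature == b.by_signature and a.by_k == b.by_k


class TestBayesFactors:
    def test_odds_ratio_arithmetic(self):
        # post fraction 0.9, prior fraction 0.5 -> BF 9 (up to smoothing)
        post = _fake_counts({"m": 9000, "x": 1000}, mu=1.0, prior_only=False)
        prior = _fake_counts({"m": 5000, "x": 5000}, mu=1.0, prior_only=True)
        table = bayes_factors(post, prior)
        row = [r for r in table.models if r.item == "m"][0]
        assert row.bf == pytest.approx(9.0, rel=0.01)
        assert row.ln_bf == pytest.approx(math.log(9.0), abs=0.01)

    def test_equal_fractions_bf_one(self):
        post = _fake_counts({"m": 600, "x": 400}, mu=1.0, prior_only=False)
        prior = _fake_counts({"m": 600, "x": 400}, mu=1.0, prior_only=True)
        row = bayes_factors(post, prior).models[0]
        assert row.bf == pytest.approx(1.0, abs=1e-9)
        assert row.ln_bf == pytest.approx(0.0, abs=1e-9)

    def test_decisive_label(self):
        post = _fake_counts({"m": 9990, "x": 10}, mu=1.0, prior_only=False)
        prior = _fake_counts({"m": 100, "x": 9900}, mu=1.0, prior_only=True)
        row = [r for r in bayes_factors(post, prior).models if r.item == "m"][0]
        assert row.ln_bf > 5
        assert row.label == "decisive"

    def test_mismatched_mu_rejected(self):
        post = _fake_counts({"m": 1}, mu=1.0, prior_only=False)
        prior = _fake_counts({"m": 1}, mu=10.0, prior_only=True)
        with pytest.raises(MCMCError):
            bayes_factors(post, prior)

    def test_prior_must_be_prior_only(self):
        post = _fake_counts({"m": 1}, mu=1.0, prior_only=False)
        with pytest.raises(MCMCError):
            bayes_factors(post, post)


class TestGeweke:
    def test_iid_normal_mostly_small_z(self):
        rng = np.random.default_rng(0)
        bad = sum(
            abs(geweke_diagnostic(rng.normal(size=10000)).z) >= 4
            for _ in range(100)
        )
        assert bad <= 1

    def test_shifted_series_detected(self):
        series = np.concatenate([np.zeros(5000), np.ones(5000)])
        series += np.random.default_rng(1).normal(0, 1e-3, 10000)
        res = geweke_diagnostic(series)
        assert abs(res.z) > 1.96 and not res.converged

    def test_constant_series_undefined(self):
        res = geweke_diagnostic(np.ones(1000))
        assert res.undefined

    def test_short_series_rejected(self):
        with pytest.raises(MCMCError):
            geweke_diagnostic(np.arange(50))

    def test_bad_windows_rejected(self):
        with pytest.raises(MCMCError):
            geweke_diagnostic(np.arange(1000), frac_first=0.6, frac_last=0.6)


class TestAncestral:
    def test_zero_length_cherry_forced(self, uniform_pi):
        tree = parse_newick("((a:0,b:0):1,c:1);")
        traits = TraitData.from_labels({"a": "FI", "b": "FI", "c": "CI"})
        trace = run_chain([tree], traits, PriorSpec(1.0), 2000, 10, seed=0,
                          pi=uniform_pi)
        est = ancestral_at_mrca(trace, [tree], traits, {"a", "b"}, uniform_pi)
        fi = traits.alphabet.index("FI")
        assert est.probabilities[fi] == pytest.approx(1.0, abs=1e-9)
        assert est.probabilities.sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_fixed_q_marginals(self, uniform_pi):
        # chain restricted to a single model: jump moves disabled
        from traitrates import mklik
        tree = parse_newick("((a:0.6,b:0.9):0.4,c:1.2);")
        traits = TraitData.from_labels({"a": "CI", "b": "MK", "c": "CI"})
        weights = {"rate_update": 1.0, "prior_redraw": 0.0, "reassign": 0.0,
                   "split": 0.0, "merge": 0.0, "tree_switch": 0.0}
        trace = run_chain([tree], traits, PriorSpec(0.5), 30000, 10, seed=4,
                          pi=uniform_pi, move_weights=weights)
        est = ancestral_at_mrca(trace, [tree], traits, {"a", "b"}, uniform_pi)
        # average the per-sample marginals directly as an oracle
        node = [n for n in tree.internal_nodes() if n.parent is not None][0]
        engine = mklik.PruningEngine(tree, traits)
        sub = trace.post_burn()
        ref = np.mean([
            engine.node_marginals(
                QMatrix.from_off_diagonal(_off(sub.pair_rates[i])), uniform_pi, node)
            for i in range(sub.n_samples)
        ], axis=0)
        assert np.abs(est.probabilities - ref / ref.sum()).max() < 1e-9


class TestRateMeans:
    def test_fixed_class_rate(self):
        trace = _fake_trace(["s"] * 120, [1] * 120)
        trace.pair_rates[:, 0] = 2.0
        res = posterior_rate_means(trace, burn_frac=0.0)
        assert res.means[0] == 2.0

    def test_always_zero_pair(self):
        trace = _fake_trace(["s"] * 120, [1] * 120)
        res = posterior_rate_means(trace, burn_frac=0.0)
        assert res.means[1] == 0.0


class TestTracePersistence:
    def test_round_trip(self, tmp_path, tiny_data):
        tree, traits = tiny_data
        trace = run_chain([tree], traits, PriorSpec(5.0), 2000, 20, seed=9)
        trace.to_tsv(tmp_path / "trace.tsv", tmp_path / "trace.json")
        again = ChainTrace.from_tsv(tmp_path / "trace.tsv", tmp_path / "trace.json")
        assert again.signatures == trace.signatures
        assert np.array_equal(again.k, trace.k)
        assert np.array_equal(again.pair_rates, trace.pair_rates)
        assert again.meta["mu"] == trace.meta["mu"]


def _off(pair_rates):
    off = np.zeros((5, 5))
    for idx, (i, j) in enumerate(PAIRS):
        off[i, j] = pair_rates[idx]
    return off


def _fake_trace(signatures, ks):
    n = len(signatures)
    return ChainTrace(
        iterations=np.arange(n),
        signatures=list(signatures),
        k=np.array(ks, dtype=int),
        pair_rates=np.zeros((n, 20)),
        lnl=np.zeros(n),
        tree_index=np.zeros(n, dtype=int),
        meta={"burn_in_frac": 0.0, "mu": 1.0, "prior_only": False,
              "move_weights": {}},
    )


def _fake_counts(by_sig, mu, prior_only):
    total = sum(by_sig.values())
    from traitrates.rjmcmc import ModelCounts
    return ModelCounts(dict(by_sig), {1: total}, total,
                       {"mu": mu, "prior_only": prior_only, "move_weights": {}})
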