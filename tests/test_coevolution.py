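"""Paired binary-trait CTMC models: likelihood, MCMC, marginal likelihood."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import expm

from eggnest._ctmc import prune, transition_matrices, tree_arrays
from eggnest.coevolution import (DEPENDENT_PARAMS, INDEPENDENT_PARAMS,
                                 CoevolutionModel, McmcConfig, bayes_factor,
                                 binarize_c, interpret_bayes_factor,
                                 rate_matrix)
from eggnest.simulate import paired_trait_q, simulate_discrete, simulate_tree
from eggnest.trees import Phylogeny


def brute_force_loglik(phylo, tip_states, Q, root="likelihood-weighted"):
    """Sum over all internal-node state assignments (oracle for <= 4 tips)."""
    nodes = list(phylo.tree.postorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    Ls = np.zeros(4)
    for rs in range(4):
        total = 0.0
        for assign in itertools.product(range(4), repeat=len(internal) - 1):
            state = {id(internal[-1]): rs}
            for n, s in zip(internal[:-1], assign):
                state[id(n)] = s
            p = 1.0
            for n in nodes:
                if n.parent_node is None:
                    continue
                sp = state[id(n.parent_node)]
                sc = (state[id(n)] if not n.is_leaf()
                      else tip_states[n.taxon.label])
                p *= expm(Q * (n.edge.length or 0.0))[sp, sc]
            total += p
        Ls[rs] = total
    if root == "likelihood-weighted":
        return np.log((Ls ** 2).sum() / Ls.sum())
    return np.log(Ls.mean())


def tip_frame(states: dict) -> pd.DataFrame:
    return pd.DataFrame({"x": {k: v // 2 for k, v in states.items()},
                         "y": {k: v % 2 for k, v in states.items()}})


class TestRateMatrix:
    def test_dependent_structure(self):
        Q = rate_matrix(dict(zip(DEPENDENT_PARAMS, range(1, 9))), "dependent")
        assert np.allclose(Q.sum(axis=1), 0.0)
        assert Q[0, 3] == Q[3, 0] == Q[1, 2] == Q[2, 1] == 0.0  # no doubles
        assert Q[0, 1] == 1 and Q[0, 2] == 2 and Q[3, 2] == 8

    def test_independent_ties(self):
        Q = rate_matrix({"alpha1": 3, "beta1": 4, "alpha2": 5, "beta2": 6},
                        "independent")
        assert Q[0, 2] == Q[1, 3] == 3   # trait-1 gain ignores trait 2
        assert Q[2, 0] == Q[3, 1] == 4
        assert Q[0, 1] == Q[2, 3] == 5
        assert Q[1, 0] == Q[3, 2] == 6

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            rate_matrix([-1, 1, 1, 1], "independent")


class TestBinarize:
    def test_median_split(self):
        out = binarize_c(pd.Series([1.0, 2.0, 3.0, 4.0]))
        assert list(out) == ["low", "low", "high", "high"]

    def test_all_equal_goes_low(self):
        assert (binarize_c(pd.Series([2.0] * 5)) == "low").all()

    def test_odd_count_strict_greater(self):
        out = binarize_c(pd.Series(np.arange(1001, dtype=float)))
        assert (out == "high").sum() == 500


class TestLikelihood:
    def test_zero_rates_identical_tips(self, quartet_tree):
        data = tip_frame({k: 2 for k in "abcd"})   # all (1, 0)
        m = CoevolutionModel(quartet_tree, data, "dependent",
                             branch_scale=1.0)
        ll, _ = m.loglik(np.zeros(8))
        assert ll == pytest.approx(0.0, abs=1e-12)   # likelihood 1

    def test_zero_rates_discordant_tips(self, quartet_tree):
        states = {"a": 2, "b": 1, "c": 2, "d": 2}
        m = CoevolutionModel(quartet_tree, tip_frame(states), "dependent",
                             branch_scale=1.0)
        ll, _ = m.loglik(np.zeros(8))
        assert ll == -np.inf

    def test_pruning_matches_enumeration(self, quartet_tree):
        rng = np.random.default_rng(17)
        for _ in range(20):
            theta = rng.exponential(2.0, 8)
            states = {lab: int(rng.integers(4)) for lab in "abcd"}
            m = CoevolutionModel(quartet_tree, tip_frame(states),
                                 "dependent", branch_scale=1.0)
            ll, _ = m.loglik(theta)
            oracle = brute_force_loglik(quartet_tree, states,
                                        rate_matrix(theta, "dependent"))
            assert ll == pytest.approx(oracle, abs=1e-10)

    def test_rate_time_rescaling_identity(self, quartet_tree):
        rng = np.random.default_rng(23)
        theta = rng.exponential(1.0, 8)
        states = {lab: int(rng.integers(4)) for lab in "abcd"}
        m1 = CoevolutionModel(quartet_tree, tip_frame(states), "dependent",
                              branch_scale=1.0)
        m2 = CoevolutionModel(quartet_tree, tip_frame(states), "dependent",
                              branch_scale=1.0 / 3.0)
        assert m1.loglik(theta)[0] == pytest.approx(
            m2.loglik(theta * 3.0)[0], abs=1e-10)

    def test_independent_equals_product_of_marginals(self):
        tree = simulate_tree(30, seed=4, scale_depth=2.0)
        rng = np.random.default_rng(8)
        states, _ = simulate_discrete(tree, paired_trait_q(0.8), 0, rng)
        data = pd.DataFrame({"x": states // 2, "y": states % 2})
        theta = rng.exponential(1.0, 4)
        m = CoevolutionModel(tree, data, "independent", branch_scale=1.0)
        ll4, _ = m.loglik(theta)
        ll2 = sum(_marginal_2state_loglik(tree, data[c], g, l)
                  for c, (g, l) in zip(["x", "y"],
                                       [(theta[0], theta[1]),
                                        (theta[2], theta[3])]))
        assert ll4 == pytest.approx(ll2, abs=1e-10)

    def test_bad_states_rejected(self, quartet_tree):
        data = pd.DataFrame({"x": [0, 1, 2, 0], "y": [0] * 4},
                            index=list("abcd"))
        with pytest.raises(ValueError):
            CoevolutionModel(quartet_tree, data)


def _marginal_2state_loglik(tree, states, gain, loss):
    Q2 = np.array([[-gain, gain], [loss, -loss]])
    arr = tree_arrays(tree)
    P = transition_matrices(Q2, arr["blen"])
    tp = np.zeros((len(arr["blen"]), 2))
    for i, lab in zip(np.where(arr["is_leaf"])[0], arr["leaf_labels"]):
        tp[i, int(states[lab])] = 1.0
    partial, ls = prune(arr["child_ptr"], arr["child_idx"], arr["is_leaf"],
                        tp, P)
    return float(np.log(partial @ (partial / partial.sum())) + ls)


class TestMcmc:
    def test_same_seed_identical_trace(self):
        tree = simulate_tree(20, seed=6, scale_depth=100.0)
        rng = np.random.default_rng(2)
        states, _ = simulate_discrete(tree, paired_trait_q(10.0) * 0.001,
                                      0, rng)
        data = pd.DataFrame({"x": states // 2, "y": states % 2})
        cfg = McmcConfig(iterations=2000, burn_in=500, seed=99)
        r1 = CoevolutionModel(tree, data).fit(cfg)
        r2 = CoevolutionModel(tree, data).fit(cfg)
        assert r1.samples.equals(r2.samples)

    def test_rate_asymmetry_recovered(self):
        # q13 >> q24: posterior mean of q13 above q24 in most replicates
        hits = 0
        reps = 8
        for r in range(reps):
            rng = np.random.default_rng(4000 + r)
            tree = simulate_tree(300, rng, scale_depth=100.0)
            Q = paired_trait_q(10.0, elevated="q13")
            states, _ = simulate_discrete(tree, Q * 0.001,
                                          int(rng.integers(4)), rng)
            data = pd.DataFrame({"x": states // 2, "y": states % 2})
            cfg = McmcConfig(iterations=6000, burn_in=1500,
                             seed=int(rng.integers(2**31)))
            res = CoevolutionModel(tree, data).fit(cfg)
            hits += (res.posterior_mean["q13"] > res.posterior_mean["q24"])
        assert hits / reps >= 0.8


class TestMarginalLikelihood:
    def test_constant_likelihood_gives_zero_logml(self):
        tree = simulate_tree(10, seed=3)
        cfg = McmcConfig(iterations=100, burn_in=10, seed=5, n_stones=10,
                         stone_iterations=300, stone_burn_in=50)
        m = CoevolutionModel(tree, None, "dependent")
        assert m.marginal_likelihood(cfg) == pytest.approx(0.0, abs=1e-12)

    def test_nested_models_agree_on_tied_rates(self):
        # dependent model whose data came from an independent process:
        # both marginal likelihoods must agree within Monte-Carlo error
        tree = simulate_tree(60, seed=11, scale_depth=100.0)
        rng = np.random.default_rng(13)
        states, _ = simulate_discrete(tree, paired_trait_q(10.0) * 0.001,
                                      0, rng)
        data = pd.DataFrame({"x": states // 2, "y": states % 2})
        mk = lambda s: McmcConfig(iterations=100, burn_in=10, seed=s,
                                  n_stones=10, stone_iterations=1500,
                                  stone_burn_in=300)
        lmls_d = [CoevolutionModel(tree, data, "dependent")
                  .marginal_likelihood(mk(s)) for s in (21, 22)]
        lmls_i = [CoevolutionModel(tree, data, "independent")
                  .marginal_likelihood(mk(s)) for s in (23, 24)]
        mc_sd = max(np.std(lmls_d), np.std(lmls_i), 0.5)
        assert abs(np.mean(lmls_d) - np.mean(lmls_i)) < 2 + 4 * mc_sd

    def test_doubling_stones_is_stable(self):
        tree = simulate_tree(40, seed=19, scale_depth=100.0)
        rng = np.random.default_rng(29)
        states, _ = simulate_discrete(tree, paired_trait_q(10.0) * 0.001,
                                      0, rng)
        data = pd.DataFrame({"x": states // 2, "y": states % 2})
        m = CoevolutionModel(tree, data, "independent")
        mk = lambda ns: McmcConfig(iterations=100, burn_in=10, seed=31,
                                   n_stones=ns, stone_iterations=1500,
                                   stone_burn_in=300)
        a = m.marginal_likelihood(mk(10))
        b = m.marginal_likelihood(mk(20))
        assert abs(a - b) < 0.5


class TestBayesFactor:
    def test_arithmetic(self):
        assert bayes_factor(-100.0, -100.0) == 0.0
        assert bayes_factor(-100.0, -104.65) == pytest.approx(9.3)

    def test_interpretation_scale(self):
        assert "strong" in interpret_bayes_factor(15.6)
        assert "positive" in interpret_bayes_factor(9.3)
        assert "no clear" in interpret_bayes_factor(0.5)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            bayes_factor(-np.inf, -3.0)
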