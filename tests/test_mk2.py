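import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import expm

from eyespot_origins import mk2, trees
from eyespot_origins.mk2 import Mk2Rates, transition_matrix

from conftest import brute_force_lnL, random_character, random_tree


class TestTransitionMatrix:
    def test_zero_time_is_identity(self):
        P = transition_matrix(Mk2Rates(0.3, 0.7), 0.0)
        assert np.allclose(P, np.eye(2), atol=1e-15)

    def test_symmetric_rates_converge_to_half(self):
        q = 0.25
        P = transition_matrix(Mk2Rates(q, q), 1e6 / q)
        assert np.allclose(P, 0.5, atol=1e-12)

    def test_matches_matrix_exponential(self):
        g, l, t = 0.2, 0.1, 3.0
        Q = np.array([[-g, g], [l, -l]])
        assert np.allclose(transition_matrix(Mk2Rates(g, l), t), expm(Q * t), atol=1e-10)

    def test_rows_sum_to_one_over_random_draws(self, rng):
        for _ in range(500):
            g, l = np.exp(rng.uniform(-8, 3, size=2))
            t = np.exp(rng.uniform(-3, 5))
            P = transition_matrix(Mk2Rates(g, l), t)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
            assert (P >= 0).all()

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            transition_matrix(Mk2Rates(1, 1), -0.5)

    @settings(derandomize=True, max_examples=200)
    @given(
        gain=st.floats(1e-6, 50.0), loss=st.floats(1e-6, 50.0),
        s=st.floats(0.0, 20.0), t=st.floats(0.0, 20.0),
    )
    def test_chapman_kolmogorov(self, gain, loss, s, t):
        # P(s+t) = P(s) P(t) for any division of the elapsed time
        r = Mk2Rates(gain, loss)
        lhs = transition_matrix(r, s + t)
        rhs = transition_matrix(r, s) @ transition_matrix(r, t)
        assert np.allclose(lhs, rhs, atol=1e-12)


class TestLogLikelihood:
    def test_two_tip_closed_form(self):
        # Cherry with both branches t, both tips 0, symmetric rate q and an
        # equal root prior: lnL = log(0.5 P00^2 + 0.5 P10^2).
        t, q = 1.7, 0.4
        tree = trees.read_newick(f"(A:{t},B:{t});")
        P = transition_matrix(Mk2Rates(q, q), t)
        expected = math.log(0.5 * P[0, 0] ** 2 + 0.5 * P[1, 0] ** 2)
        got = mk2.log_likelihood(tree, {"A": 0, "B": 0}, Mk2Rates(q, q), root_prior="equal")
        assert got == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_tree(int(rng.integers(3, 7)), seed=seed)
        char = random_character(tree, seed + 100)
        rates = Mk2Rates(*np.exp(rng.uniform(-3, 0.5, size=2)))
        lnL = mk2.log_likelihood(tree, char, rates)
        assert lnL == pytest.approx(brute_force_lnL(tree, char, rates), abs=1e-10)

    def test_missing_tips_marginalized(self):
        tree = random_tree(5, seed=2)
        char = random_character(tree, 9)
        char.pop(tree.tip_labels[0])
        rates = Mk2Rates(0.3, 0.6)
        assert mk2.log_likelihood(tree, char, rates) == pytest.approx(
            brute_force_lnL(tree, char, rates), abs=1e-10
        )

    def test_all_missing_is_error(self, three_tip_tree):
        with pytest.raises(ValueError, match="missing"):
            mk2.log_likelihood(three_tip_tree, {}, Mk2Rates(1, 1))

    def test_constraint_restriction_inequality(self):
        tree = random_tree(8, seed=4)
        char = random_character(tree, 5)
        rates = Mk2Rates(0.2, 0.4)
        free = mk2.log_likelihood(tree, char, rates)
        l0 = mk2.log_likelihood(tree, char, rates, {tree.root: 0})
        l1 = mk2.log_likelihood(tree, char, rates, {tree.root: 1})
        assert l0 <= free + 1e-6
        assert l1 <= free + 1e-6
        # the two restricted likelihoods partition the full one
        assert math.exp(l0) + math.exp(l1) == pytest.approx(math.exp(free), rel=1e-9)

    def test_constrained_matches_enumeration(self):
        tree = random_tree(5, seed=8)
        char = random_character(tree, 3)
        rates = Mk2Rates(0.5, 0.3)
        internal = [v for v in range(tree.n_nodes) if not tree.is_tip(v)]
        cons = {internal[0]: 1}
        assert mk2.log_likelihood(tree, char, rates, cons) == pytest.approx(
            brute_force_lnL(tree, char, rates, cons), abs=1e-10
        )

    def test_tip_constraint_contradiction_is_error(self, three_tip_tree):
        char = {"A": 0, "B": 1, "C": 0}
        tip_a = three_tip_tree.tip_id("A")
        with pytest.raises(ValueError, match="contradicts"):
            mk2.log_likelihood(three_tip_tree, char, Mk2Rates(1, 1), {tip_a: 1})

    def test_probability_normalization_over_tip_configs(self):
        tree = random_tree(5, seed=21)
        rates = Mk2Rates(0.37, 0.81)
        total = sum(
            math.exp(mk2.log_likelihood(tree, dict(zip(tree.tip_labels, cfg)), rates))
            for cfg in itertools.product((0, 1), repeat=5)
        )
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_rerooting_invariance_under_stationary_prior(self):
        for seed in range(4):
            tree = random_tree(7, seed=seed)
            char = random_character(tree, seed + 50)
            rates = Mk2Rates(0.15, 0.45)
            ref = mk2.log_likelihood(tree, char, rates, root_prior="stationary")
            for v in range(tree.n_nodes - 1):
                if tree.is_tip(v):
                    continue
                rerooted = trees.reroot_at_node(tree, v)
                assert mk2.log_likelihood(rerooted, char, rates) == pytest.approx(
                    ref, abs=1e-9
                )


class TestFitRates:
    def test_uniform_character_pins_gain_at_bound(self):
        tree = random_tree(20, seed=6)
        char = {lbl: 0 for lbl in tree.tip_labels}
        fit = mk2.fit_rates(tree, char, n_restarts=3, seed=0)
        # surface is flat near the bound; the fitted gain is negligible
        assert fit.rates.gain <= 1e-4
        assert fit.lnL < 0  # likelihood of discrete data is < 1
        assert fit.lnL == pytest.approx(0.0, abs=0.05)  # ~ all prior mass on 0

    def test_fit_beats_generating_rates(self):
        from eyespot_origins import synthetic_data as syn

        tree = random_tree(60, seed=13, depth=100.0)
        truth = Mk2Rates(0.01, 0.03)
        char, _ = syn.simulate_character(tree, truth, root_state=0, seed=17)
        if len(set(char.values())) < 2:
            pytest.skip("degenerate draw")
        fit = mk2.fit_rates(tree, char, n_restarts=3, seed=1)
        assert fit.lnL >= mk2.log_likelihood(tree, char, truth) - 1e-6

    def test_deterministic_for_fixed_seed(self):
        tree = random_tree(15, seed=9)
        char = random_character(tree, 2)
        f1 = mk2.fit_rates(tree, char, seed=42)
        f2 = mk2.fit_rates(tree, char, seed=42)
        assert (f1.rates, f1.lnL) == (f2.rates, f2.lnL)


class TestMarginalAncestralStates:
    def test_all_one_tips_low_loss_gives_confident_ones(self):
        tree = random_tree(10, seed=14)
        char = {lbl: 1 for lbl in tree.tip_labels}
        anc = mk2.marginal_ancestral_states(tree, char, Mk2Rates(0.1, 1e-6))
        for p0, p1 in anc.values():
            assert p1 > 0.99

    @pytest.mark.parametrize("seed", range(6))
    def test_equals_node_fixing_ratio(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_tree(int(rng.integers(3, 7)), seed=seed + 30)
        char = random_character(tree, seed + 60)
        rates = Mk2Rates(*np.exp(rng.uniform(-2.5, 0.5, size=2)))
        anc = mk2.marginal_ancestral_states(tree, char, rates)
        for v, (p0, p1) in anc.items():
            l0 = mk2.log_likelihood(tree, char, rates, {v: 0})
            l1 = mk2.log_likelihood(tree, char, rates, {v: 1})
            expected = math.exp(l1) / (math.exp(l0) + math.exp(l1))
            assert p1 == pytest.approx(expected, abs=1e-9)
            assert p0 + p1 == pytest.approx(1.0, abs=1e-9)
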