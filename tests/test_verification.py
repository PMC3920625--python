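"""Bounded maximum reachability: exact value iteration vs independent
oracles, simulator consistency, monotonicity and limit behaviors."""

import itertools
import math

import numpy as np
import pytest

from cspbn import (CandidateFunction, CapacityError, CSPBN, GeneSpec,
                   GeneratorConfig, Not, ReachabilitySpec, Var,
                   apoptosis_network, max_reachability,
                   max_reachability_bruteforce, max_reachability_open_loop,
                   open_loop_reachability, parse_expr, random_cspbn,
                   simulate_paths, wnt5a_network)

WNT5A_SPEC = ReachabilitySpec((1,), (0,), 5, "both")


def _toggle_gene():
    """Single gene x1' = !x1, no inputs, deterministic."""
    return CSPBN(
        genes=(GeneSpec("x1", (CandidateFunction(Not(Var("x1")), 1.0),)),),
        inputs=(), q=0.0, x0=(1,), j0=(1,))


class TestExactValueIteration:
    def test_deterministic_one_step_reach(self):
        spec = ReachabilitySpec((1,), (0,), 1, "both")
        assert max_reachability(_toggle_gene(), spec).pmax == 1.0

    def test_horizon_zero_checks_initial_state(self):
        net = _toggle_gene()
        assert max_reachability(
            net, ReachabilitySpec((1,), (1,), 0)).pmax == 1.0
        assert max_reachability(
            net, ReachabilitySpec((1,), (0,), 0)).pmax == 0.0

    def test_wnt5a_reported_probabilities(self):
        for q, expected in ((0.3, 0.7215), (0.5, 0.6587), (0.7, 0.6489)):
            net = wnt5a_network(0.5, 0.5, q)
            result = max_reachability(net, WNT5A_SPEC)
            assert round(result.pmax, 4) == expected

    def test_pmax_is_max_of_per_u0(self, wnt5a_verif):
        result = max_reachability(wnt5a_verif, WNT5A_SPEC)
        assert result.pmax == max(result.per_u0.values())
        assert set(result.per_u0) == {(0,), (1,)}

    def test_u0_modes_match_both(self, wnt5a_verif):
        both = max_reachability(wnt5a_verif, WNT5A_SPEC)
        lo = max_reachability(wnt5a_verif,
                              ReachabilitySpec((1,), (0,), 5, "0"))
        hi = max_reachability(wnt5a_verif,
                              ReachabilitySpec((1,), (0,), 5, "1"))
        assert lo.pmax == pytest.approx(both.per_u0[(0,)], abs=1e-15)
        assert hi.pmax == pytest.approx(both.per_u0[(1,)], abs=1e-15)

    def test_monotone_in_horizon(self, wnt5a_verif, apoptosis):
        for net, target in ((wnt5a_verif, (1,)), (apoptosis, (2,))):
            prev = -1.0
            for N in range(6):
                spec = ReachabilitySpec(target, (0,), N, "both")
                p = max_reachability(net, spec).pmax
                assert p >= prev - 1e-15
                assert 0.0 <= p <= 1.0
                prev = p

    def test_q_zero_single_candidate_is_zero_or_one(self):
        """Frozen selection with one candidate per gene: a deterministic
        system with input choice, so pmax is 0 or 1."""
        vocab = ("a", "b", "u1")
        net = CSPBN(
            genes=(GeneSpec("a", (CandidateFunction(
                       parse_expr("!b & u1", vocab), 1.0),)),
                   GeneSpec("b", (CandidateFunction(
                       parse_expr("a | b", vocab), 1.0),))),
            inputs=("u1",), q=0.0, x0=(0, 0), j0=(1, 1))
        for target in itertools.product((0, 1), repeat=2):
            spec = ReachabilitySpec((1, 2), target, 3, "both")
            assert max_reachability(net, spec).pmax in (0.0, 1.0)

    def test_capacity_error(self, wnt5a_verif):
        with pytest.raises(CapacityError):
            max_reachability(wnt5a_verif, WNT5A_SPEC, state_cap=100)


class TestOracleEquivalence:
    def test_value_iteration_equals_path_enumeration(self):
        """On 50 random instances with at most 64 joint states and
        horizon <= 3, dense value iteration matches depth-first
        path-summation over all history-dependent strategies."""
        checked = 0
        seed = 0
        while checked < 50:
            seed += 1
            cfg = GeneratorConfig(n=2, m=1, max_candidates=2,
                                  max_literals=3, q=0.4 + 0.01 * (seed % 20),
                                  seed=seed)
            net = random_cspbn(cfg)
            if net.joint_state_count() > 64:
                continue
            N = 1 + seed % 3
            spec = ReachabilitySpec((1,), (seed % 2,), N, "both")
            vi = max_reachability(net, spec).pmax
            bf = max_reachability_bruteforce(net, spec)
            assert vi == pytest.approx(bf, abs=1e-12)
            checked += 1

    def test_closed_loop_dominates_open_loop(self, apoptosis):
        spec = ReachabilitySpec((2,), (0,), 3, "both")
        closed = max_reachability(apoptosis, spec).pmax
        open_p, seq = max_reachability_open_loop(apoptosis, spec)
        assert open_p <= closed + 1e-12
        assert open_p == pytest.approx(
            open_loop_reachability(apoptosis, spec, seq), abs=1e-12)

    def test_memoryless_limit_matches_direct_pbn(self):
        """At q = 1 the joint-chain value equals an independently coded
        memoryless-PBN recursion (controller observes x, functions
        re-drawn from c every step; first step deterministic from j0)."""
        for seed in range(1, 9):
            cfg = GeneratorConfig(n=2, m=1, max_candidates=2,
                                  max_literals=3, q=1.0, seed=seed)
            net = random_cspbn(cfg)
            N = 2 + seed % 2
            spec = ReachabilitySpec((1,), (seed % 2,), N, "both")
            vi = max_reachability(net, spec).pmax
            assert vi == pytest.approx(_pbn_pmax(net, spec), abs=1e-12)


def _pbn_pmax(net, spec):
    """Direct memoryless-PBN maximum reachability (independent of the
    joint-chain code path): G(x, u, k) checks the target, then sums over
    candidate combinations freshly drawn from c; the controller picks
    the next input after observing the state."""
    names = net.names
    all_u = list(itertools.product((0, 1), repeat=net.m))

    def apply(x, u, combo):
        env = dict(zip(names, x + u))
        return tuple(g.candidates[j - 1].expr.evaluate(env)
                     for g, j in zip(net.genes, combo))

    def is_target(x):
        return all(x[j - 1] == v
                   for j, v in zip(spec.output_indices, spec.target))

    combos = list(itertools.product(
        *[range(1, g.l + 1) for g in net.genes]))

    def weight(combo):
        w = 1.0
        for g, j in zip(net.genes, combo):
            w *= g.candidates[j - 1].prob
        return w

    def G(x, u, k):
        """Value with k transitions left; the controller observes the
        state reached by each stochastic branch before choosing the
        next input (max inside the expectation)."""
        if is_target(x):
            return 1.0
        if k == 0:
            return 0.0
        total = 0.0
        for combo in combos:
            w = weight(combo)
            if w == 0.0:
                continue
            x2 = apply(x, u, combo)
            total += w * max(G(x2, u2, k - 1) for u2 in all_u)
        return total

    x0 = tuple(net.x0)

    def from_u0(u0):
        # the first transition uses the given initial functions j0
        if is_target(x0):
            return 1.0
        if spec.horizon == 0:
            return 0.0
        x1 = apply(x0, u0, tuple(net.j0))
        return max(G(x1, u1, spec.horizon - 1) for u1 in all_u)

    return max(from_u0(u0) for u0 in all_u)


class TestSimulation:
    def test_first_step_deterministic(self, apoptosis):
        """With the initial functions given, every sampled path makes
        the same first transition."""
        sim = simulate_paths(apoptosis, [(0,), (1,)], 2, runs=200, seed=3)
        assert np.all(sim.x_paths[:, 1, :] == [0, 0, 1])

    def test_q_zero_paths_are_the_frozen_bn(self, apoptosis):
        net = apoptosis.replace(q=0.0)
        sim = simulate_paths(net, [(0,), (1,), (1,)], 3, runs=100, seed=5)
        assert np.all(sim.x_paths == sim.x_paths[0])
        assert np.all(sim.sel_paths == 1)

    def test_reproducible_given_seed(self, apoptosis):
        a = simulate_paths(apoptosis, [(1,)] * 4, 4, runs=64, seed=11)
        b = simulate_paths(apoptosis, [(1,)] * 4, 4, runs=64, seed=11)
        assert np.array_equal(a.x_paths, b.x_paths)
        assert np.array_equal(a.sel_paths, b.sel_paths)

    def test_monte_carlo_matches_exact_pmax(self, wnt5a_verif):
        """100,000 paths under the extracted optimal strategy land
        within three binomial standard errors of the exact value."""
        result = max_reachability(wnt5a_verif, WNT5A_SPEC)
        sim = simulate_paths(wnt5a_verif, result, 5, runs=100_000,
                             seed=20240917, spec=WNT5A_SPEC)
        se = math.sqrt(result.pmax * (1 - result.pmax) / 100_000)
        assert abs(sim.reach_frequency - result.pmax) <= 3 * se

    def test_open_loop_frequency_matches_exact(self, apoptosis):
        spec = ReachabilitySpec((2,), (0,), 3, "both")
        seq = [(1,), (0,), (1,)]
        exact = open_loop_reachability(apoptosis, spec, seq)
        sim = simulate_paths(apoptosis, seq, 3, runs=100_000, seed=2,
                             spec=spec)
        se = math.sqrt(max(exact * (1 - exact), 1e-12) / 100_000)
        assert abs(sim.reach_frequency - exact) <= 4 * se
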