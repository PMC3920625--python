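"""Expected-state recursion, cost evaluation, exhaustive optimization
and the polynomial-program export."""

import itertools

import numpy as np
import pytest

from cspbn import (CandidateFunction, CapacityError, ControlSpec, CSPBN,
                   GeneSpec, GeneratorConfig, Var, apoptosis_network,
                   emit_polynomial_program, evaluate_cost, expected_update,
                   optimize_exhaustive, parse_expr, random_cspbn, rollout,
                   rollout_pbn, wnt5a_network)
from cspbn.control import candidate_polynomials

Q_GRID = (0.0, 0.25, 0.5, 0.75, 1.0)

STUDY_U = [(1,), (1,), (0,), (0,), (0,)]
WNT5A_WEIGHTS = dict(Q=(1, 0, 0, 0, 0, 0), R=(1,), Qf=(1, 0, 0, 0, 0, 0))


def _copy_gene():
    """Single gene x1' = u, one candidate."""
    return CSPBN(genes=(GeneSpec("x1", (CandidateFunction(
                     Var("u"), 1.0),)),),
                 inputs=("u",), q=0.5, x0=(1,), j0=(1,))


class TestExpectedUpdate:
    @pytest.mark.parametrize("q", Q_GRID)
    def test_apoptosis_worked_example(self, q):
        """From x(1) = (0,0,1) with u(1) = 1 and the selection
        distributions advanced one step: E[x3(2)] = 1 for any q, and
        E[x1(2)], E[x2(2)] follow their closed forms."""
        net = apoptosis_network(q)
        traj = rollout(net, [(0,), (1,)])
        assert np.array_equal(traj.ex[1], [0, 0, 1])
        assert traj.ex[2][2] == pytest.approx(1.0, abs=1e-12)
        assert traj.ex[2][0] == pytest.approx(0.6 * q + (1 - q), abs=1e-12)
        assert traj.ex[2][1] == pytest.approx(0.7 * q + (1 - q), abs=1e-12)

    def test_single_candidate_binary_state_stays_binary(self):
        vocab = ("a", "b")
        net = CSPBN(
            genes=(GeneSpec("a", (CandidateFunction(
                       parse_expr("!b", vocab), 1.0),)),
                   GeneSpec("b", (CandidateFunction(
                       parse_expr("a & b", vocab), 1.0),))),
            inputs=(), q=0.7, x0=(1, 1), j0=(1, 1))
        traj = rollout(net, [()] * 4)
        assert set(np.unique(traj.ex)) <= {0.0, 1.0}

    def test_dimension_mismatch(self, apoptosis):
        polys = candidate_polynomials(apoptosis)
        with pytest.raises(ValueError):
            expected_update(polys, apoptosis.names, [0.5, 0.5],
                            [np.array([1.0, 0.0])] * 3, [1])


class TestRollout:
    def test_wnt5a_first_step(self, wnt5a_control):
        traj = rollout(wnt5a_control, STUDY_U)
        assert np.array_equal(traj.ex[1], [1, 1, 0, 1, 1, 0])

    def test_wnt5a_reported_trajectory_values(self, wnt5a_control):
        traj = rollout(wnt5a_control, STUDY_U)
        assert traj.ex[2][0] == pytest.approx(0.06, abs=5e-5)
        assert traj.ex[4][0] == pytest.approx(0.0008, abs=5e-5)
        assert traj.ex[4][5] == pytest.approx(0.9866, abs=5e-5)
        assert traj.ex[5][4] == pytest.approx(0.3385, abs=5e-5)

    def test_horizon_zero(self, wnt5a_control):
        traj = rollout(wnt5a_control, [])
        assert traj.ex.shape == (1, 6)
        assert np.array_equal(traj.ex[0], wnt5a_control.x0)

    def test_q_zero_equals_frozen_bn(self, apoptosis):
        """With no switching the recursion is the deterministic Boolean
        trajectory of the initial functions."""
        net = apoptosis.replace(q=0.0)
        u_seq = [(1,), (0,), (1,), (1,)]
        traj = rollout(net, u_seq)
        x = list(net.x0)
        names = net.names
        for k, u in enumerate(u_seq):
            env = dict(zip(names, x + list(u)))
            x = [g.candidates[net.j0[i] - 1].expr.evaluate(env)
                 for i, g in enumerate(net.genes)]
            assert np.array_equal(traj.ex[k + 1], x)

    def test_range_preserved_on_random_networks(self):
        rng = np.random.default_rng(4)
        for seed in range(12):
            net = random_cspbn(GeneratorConfig(
                n=3, m=1, max_candidates=3, max_literals=4,
                q=float(rng.random()), seed=100 + seed))
            u_seq = [(int(b),) for b in rng.integers(0, 2, size=6)]
            traj = rollout(net, u_seq)
            assert np.all(traj.ex >= -1e-12) and np.all(traj.ex <= 1 + 1e-12)
            for d in traj.d:
                assert np.allclose(d.sum(axis=1), 1.0, atol=1e-9)

    def test_step_one_is_exact_for_binary_x0(self, wnt5a_verif):
        """j0 is given, so E[x(1)] is the deterministic evaluation."""
        for u0 in ((0,), (1,)):
            traj = rollout(wnt5a_verif, [u0])
            assert set(np.unique(traj.ex[1])) <= {0.0, 1.0}

    def test_memoryless_limit_matches_pbn_recursion(self, apoptosis):
        """At q = 1 with the candidate distribution as d(0), the
        switching recursion coincides with the memoryless-PBN form."""
        net = apoptosis.replace(q=1.0)
        u_seq = [(1,), (0,), (1,)]
        a = rollout(net, u_seq, d0="candidate")
        b = rollout_pbn(apoptosis, u_seq)
        assert np.allclose(a.ex, b.ex, atol=1e-12)


class TestCost:
    def test_zero_trajectory_zero_cost(self):
        net = _copy_gene().replace(x0=(0,))
        spec = ControlSpec(Q=(1,), R=(1,), Qf=(1,), horizon=2)
        traj = rollout(net, [(0,), (0,)])
        assert evaluate_cost(traj, spec) == 0.0

    def test_wnt5a_printed_trajectory_cost(self, wnt5a_control):
        """Cost of the literature's printed input sequence under its
        stated weights (about 4.067, not the separately printed 5.23)."""
        spec = ControlSpec(horizon=5, **WNT5A_WEIGHTS)
        traj = rollout(wnt5a_control, STUDY_U)
        assert evaluate_cost(traj, spec) == pytest.approx(4.067, abs=2e-3)

    def test_state_cost_linear_in_Q(self, wnt5a_control):
        traj = rollout(wnt5a_control, STUDY_U)
        base = ControlSpec(horizon=5, **WNT5A_WEIGHTS)
        no_input = ControlSpec(Q=WNT5A_WEIGHTS["Q"], R=(0,),
                               Qf=WNT5A_WEIGHTS["Qf"], horizon=5)
        doubled = ControlSpec(Q=(2, 0, 0, 0, 0, 0), R=(0,),
                              Qf=(2, 0, 0, 0, 0, 0), horizon=5)
        assert evaluate_cost(traj, doubled) == pytest.approx(
            2 * evaluate_cost(traj, no_input), abs=1e-12)
        # input part is additive on top
        assert evaluate_cost(traj, base) == pytest.approx(
            evaluate_cost(traj, no_input) + 2.0, abs=1e-12)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            ControlSpec(Q=(-1,), R=(0,), Qf=(0,), horizon=1)


class TestOptimizer:
    def test_single_gene_copy_input(self):
        net = _copy_gene()
        spec = ControlSpec(Q=(1,), R=(0,), Qf=(1,), horizon=2)
        result = optimize_exhaustive(net, spec)
        assert np.array_equal(result.u_star, [[0], [0]])
        assert result.J_star == pytest.approx(1.0, abs=1e-15)

    def test_large_input_cost_forces_zero_input(self, wnt5a_control):
        spec = ControlSpec(Q=(1, 0, 0, 0, 0, 0), R=(100,),
                           Qf=(1, 0, 0, 0, 0, 0), horizon=3)
        result = optimize_exhaustive(wnt5a_control, spec)
        assert not result.u_star.any()

    def test_optimum_dominates_all_sequences(self, wnt5a_control):
        """J* is a lower bound over all 32 enumerated sequences and is
        consistent with its own trajectory."""
        spec = ControlSpec(horizon=5, **WNT5A_WEIGHTS)
        result = optimize_exhaustive(wnt5a_control, spec)
        assert evaluate_cost(result.trajectory, spec) == pytest.approx(
            result.J_star, abs=1e-12)
        for bits in itertools.product((0, 1), repeat=5):
            traj = rollout(wnt5a_control, [(b,) for b in bits])
            assert evaluate_cost(traj, spec) >= result.J_star - 1e-12

    def test_tie_break_lexicographic(self):
        # all costs equal when all weights are zero
        net = _copy_gene()
        spec = ControlSpec(Q=(0,), R=(0,), Qf=(0,), horizon=3)
        result = optimize_exhaustive(net, spec)
        assert not result.u_star.any()

    def test_capacity_cap(self, wnt5a_control):
        spec = ControlSpec(horizon=5, **WNT5A_WEIGHTS)
        with pytest.raises(CapacityError):
            optimize_exhaustive(wnt5a_control, spec, enum_cap=4)


class TestPolynomialProgram:
    def test_wnt5a_program_shape(self, wnt5a_control):
        spec = ControlSpec(horizon=5, **WNT5A_WEIGHTS)
        prog = emit_polynomial_program(wnt5a_control, spec)
        assert len(prog.state_vars) == 30
        assert len(prog.input_vars) == 5
        assert len(prog.equality_constraints) == 30
        assert len(prog.binary_constraints) == 5

    def test_minimal_program(self):
        net = _copy_gene()
        spec = ControlSpec(Q=(1,), R=(0,), Qf=(1,), horizon=1)
        prog = emit_polynomial_program(net, spec)
        assert len(prog.equality_constraints) == 1
        assert len(prog.binary_constraints) == 1
        text = str(prog)
        assert "minimize" in text and "u_1_0*(u_1_0 - 1) = 0" in text

    def test_round_trip_satisfies_constraints(self, wnt5a_control):
        """The enumerated optimum satisfies every emitted equality and
        reproduces the objective value."""
        spec = ControlSpec(horizon=5, **WNT5A_WEIGHTS)
        prog = emit_polynomial_program(wnt5a_control, spec)
        result = optimize_exhaustive(wnt5a_control, spec)
        res = prog.residuals(result.trajectory.ex, result.u_star)
        assert np.max(np.abs(res)) < 1e-9
        assert prog.objective_value(result.trajectory.ex,
                                    result.u_star) == pytest.approx(
            result.J_star, abs=1e-9)
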