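"""Open-loop optimal control of CS-PBNs via the expected-state recursion.

The expected state propagates through the multilinear extensions of the
candidate functions weighted by the selection distributions:

    E[x_i(k+1)] = sum_j d_j^(i)(k) fhat_j^(i)(E[x(k)], u(k)),
    d^(i)(k+1)  = P^(i) d^(i)(k),

with ``d^(i)(0)`` the indicator of the given initial function index, so
the first transition is the deterministic evaluation of the initial
functions.  The finite-horizon cost

    J = sum_{k=0}^{N-1} (Q x(k) + R u(k)) + Q_f x(N)

is linear, so under the recursion it is evaluated directly on the
expected trajectory.  Because the inputs are binary, the resulting
polynomial program has a finite feasible set of 2^(mN) input sequences
and is solved exactly by enumeration; the program itself can also be
emitted as text for hand-off to a polynomial-optimization solver.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import CSPBN, CapacityError
from .polynomial import MultilinearPoly, evaluate_poly, to_polynomial
from .selection import indicator_distribution, selection_matrix

__all__ = [
    "ControlSpec",
    "Trajectory",
    "ControlResult",
    "PolynomialProgram",
    "expected_update",
    "rollout",
    "rollout_pbn",
    "evaluate_cost",
    "optimize_exhaustive",
    "emit_polynomial_program",
]

#: Default cap on ``m * N`` for exhaustive enumeration (2^24 sequences).
DEFAULT_ENUM_CAP = 24


def _as_weights(w, size: int, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(w, dtype=float))
    if arr.size != size:
        raise ValueError(f"{name} has length {arr.size}, expected {size}")
    if np.any(arr < 0):
        raise ValueError(f"{name} entries must be nonnegative")
    return arr


@dataclass(frozen=True)
class ControlSpec:
    """Linear finite-horizon cost: state weights ``Q`` (length n),
    input weights ``R`` (length m), terminal weights ``Qf`` (length n),
    horizon ``N >= 1``.  All weights are nonnegative."""

    Q: tuple[float, ...]
    R: tuple[float, ...]
    Qf: tuple[float, ...]
    horizon: int

    def __post_init__(self):
        object.__setattr__(self, "Q", tuple(float(v) for v in np.atleast_1d(self.Q)))
        object.__setattr__(self, "R", tuple(float(v) for v in np.atleast_1d(self.R)))
        object.__setattr__(self, "Qf", tuple(float(v) for v in np.atleast_1d(self.Qf)))
        if any(v < 0 for v in self.Q + self.R + self.Qf):
            raise ValueError("weights must be nonnegative")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")

    def validate_against(self, net: CSPBN) -> None:
        _as_weights(self.Q, net.n, "Q")
        _as_weights(self.R, net.m, "R")
        _as_weights(self.Qf, net.n, "Qf")


@dataclass
class Trajectory:
    """Expected-state rollout: ``ex`` has shape ``(N+1, n)`` with
    ``ex[0] = x0``; ``d`` is the per-gene selection-distribution
    sequence (each ``(N+1, l(i))``); ``u`` is the applied binary input
    sequence, shape ``(N, m)``."""

    ex: np.ndarray
    d: list[np.ndarray]
    u: np.ndarray


@dataclass
class ControlResult:
    u_star: np.ndarray
    J_star: float
    trajectory: Trajectory


def candidate_polynomials(net: CSPBN) -> list[list[MultilinearPoly]]:
    """Multilinear extensions of every candidate, per gene."""
    return [[to_polynomial(c.expr) for c in g.candidates] for g in net.genes]


def expected_update(polys: list[list[MultilinearPoly]],
                    names: Sequence[str],
                    ex_k: Sequence[float],
                    d_k: Sequence[np.ndarray],
                    u_k: Sequence[float]) -> np.ndarray:
    """One step of the expected-state recursion.

    Component ``i`` is the ``d_k[i]``-weighted sum of gene ``i``'s
    candidate polynomials evaluated at the point ``(ex_k, u_k)``;
    ``names`` lists gene names followed by input names.  Output entries
    stay in ``[0, 1]`` for inputs in the unit hypercube.
    """
    n = len(polys)
    ex_k = np.asarray(ex_k, dtype=float)
    if ex_k.size != n:
        raise ValueError(f"state vector length {ex_k.size}, expected {n}")
    env = dict(zip(names, list(ex_k) + [float(v) for v in u_k]))
    out = np.empty(n)
    for i, gene_polys in enumerate(polys):
        d = np.asarray(d_k[i], dtype=float)
        if d.size != len(gene_polys):
            raise ValueError(
                f"gene {i + 1}: distribution length {d.size} != "
                f"{len(gene_polys)} candidates")
        out[i] = sum(w * evaluate_poly(p, env)
                     for w, p in zip(d, gene_polys))
    return out


def rollout(net: CSPBN, u_seq: Sequence[Sequence[int]],
            d0: Sequence[np.ndarray] | str | None = None) -> Trajectory:
    """Roll the expected-state recursion forward under an input sequence.

    By default ``d^(i)(0)`` is the indicator of the given initial
    function index ``j0(i)`` (the first transition is deterministic for
    a binary ``x0``).  ``d0="candidate"`` starts every gene from its
    candidate distribution ``c`` instead — the memoryless-PBN reading
    with no distinguished initial function — and an explicit list of
    distributions is also accepted.
    """
    u_arr = np.atleast_2d(np.asarray(u_seq, dtype=float))
    if u_arr.size == 0:
        u_arr = u_arr.reshape(0, net.m)
    if u_arr.shape[0] and u_arr.shape[1] != net.m:
        raise ValueError(
            f"input vectors have length {u_arr.shape[1]}, expected m={net.m}")
    N = u_arr.shape[0]

    polys = candidate_polynomials(net)
    names = net.names
    Ps = [selection_matrix(g, net.q) for g in net.genes]
    if d0 is None:
        dists = [indicator_distribution(net.j0[i], g.l)
                 for i, g in enumerate(net.genes)]
    elif d0 == "candidate":
        dists = [np.asarray(g.probs, dtype=float) for g in net.genes]
    else:
        dists = [np.asarray(d, dtype=float) for d in d0]

    ex = np.empty((N + 1, net.n))
    ex[0] = np.asarray(net.x0, dtype=float)
    d_hist = [np.empty((N + 1, g.l)) for g in net.genes]
    for i in range(net.n):
        d_hist[i][0] = dists[i]
    for k in range(N):
        ex[k + 1] = expected_update(polys, names, ex[k], dists, u_arr[k])
        dists = [Ps[i] @ dists[i] for i in range(net.n)]
        for i in range(net.n):
            d_hist[i][k + 1] = dists[i]
    return Trajectory(ex=ex, d=d_hist, u=u_arr.astype(int))


def rollout_pbn(net: CSPBN, u_seq: Sequence[Sequence[int]]) -> Trajectory:
    """Memoryless-PBN expected-state recursion: every step weights the
    candidates by the fixed probabilities ``c`` (independent re-selection
    each step, no selection memory)."""
    memoryless = net.replace(q=1.0)
    return rollout(memoryless, u_seq, d0="candidate")


def evaluate_cost(traj: Trajectory, spec: ControlSpec) -> float:
    """Evaluate the linear cost on an expected trajectory."""
    N = traj.u.shape[0]
    if spec.horizon != N:
        raise ValueError(
            f"trajectory horizon {N} does not match spec horizon {spec.horizon}")
    n = traj.ex.shape[1]
    Q = _as_weights(spec.Q, n, "Q")
    Qf = _as_weights(spec.Qf, n, "Qf")
    R = _as_weights(spec.R, traj.u.shape[1] if N else len(spec.R), "R")
    total = 0.0
    for k in range(N):
        total += float(Q @ traj.ex[k]) + float(R @ traj.u[k])
    return total + float(Qf @ traj.ex[N])


def optimize_exhaustive(net: CSPBN, spec: ControlSpec,
                        enum_cap: int = DEFAULT_ENUM_CAP) -> ControlResult:
    """Exact open-loop optimum by enumerating all binary input sequences.

    Since ``u(u-1)=0`` forces binary inputs and the recursion determines
    the expected trajectory from the sequence, scanning all ``2^(mN)``
    sequences solves the polynomial program exactly.  Sequences are
    visited in lexicographic order and ties keep the first minimizer, so
    the reported optimum is the lexicographically smallest.  Raises
    :class:`CapacityError` when ``m*N`` exceeds ``enum_cap``.
    """
    spec.validate_against(net)
    N, m = spec.horizon, net.m
    if m * N > enum_cap:
        raise CapacityError(
            f"m*N = {m * N} exceeds the enumeration cap {enum_cap}; "
            "export the polynomial program instead")
    best: ControlResult | None = None
    for bits in itertools.product((0, 1), repeat=m * N):
        u_seq = np.asarray(bits, dtype=int).reshape(N, m)
        traj = rollout(net, u_seq)
        cost = evaluate_cost(traj, spec)
        if best is None or cost < best.J_star:
            best = ControlResult(u_star=u_seq, J_star=cost, trajectory=traj)
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# Polynomial-program export
# ---------------------------------------------------------------------------

@dataclass
class PolynomialProgram:
    """The finite-horizon control problem as an explicit polynomial
    program over the expected-state and input decision variables.

    ``state_vars`` name ``E[x_i(k)]`` for ``k = 1..N``; ``input_vars``
    name ``u_i(k)`` for ``k = 0..N-1``.  Each equality constraint is a
    multilinear polynomial that must vanish; ``binary_constraints``
    carry the ``u(u-1) = 0`` conditions.  ``objective`` is the cost as a
    polynomial over the same variables (initial state folded in as
    constants)."""

    state_vars: list[str]
    input_vars: list[str]
    objective: MultilinearPoly
    equality_constraints: list[MultilinearPoly]
    binary_constraints: list[str]
    x0: tuple[float, ...]

    def residuals(self, ex: np.ndarray, u: np.ndarray) -> np.ndarray:
        """Evaluate the equality constraints at a rollout
        (``ex`` shape ``(N+1, n)``, ``u`` shape ``(N, m)``)."""
        env = self._env(ex, u)
        return np.asarray([evaluate_poly(c, env)
                           for c in self.equality_constraints])

    def objective_value(self, ex: np.ndarray, u: np.ndarray) -> float:
        return evaluate_poly(self.objective, self._env(ex, u))

    def _env(self, ex: np.ndarray, u: np.ndarray) -> dict[str, float]:
        env: dict[str, float] = {}
        N = u.shape[0]
        for k in range(1, N + 1):
            for i in range(ex.shape[1]):
                env[f"E_{i + 1}_{k}"] = float(ex[k, i])
        for k in range(N):
            for j in range(u.shape[1]):
                env[f"u_{j + 1}_{k}"] = float(u[k, j])
        return env

    def __str__(self) -> str:
        lines = ["# polynomial program: open-loop CS-PBN optimal control",
                 f"# initial state x(0) = {list(self.x0)}",
                 "minimize",
                 f"  {self.objective}",
                 "subject to"]
        for c in self.equality_constraints:
            lines.append(f"  {c} = 0")
        for b in self.binary_constraints:
            lines.append(f"  {b}")
        lines.append("variables")
        lines.append("  " + ", ".join(self.state_vars + self.input_vars))
        return "\n".join(lines)


def emit_polynomial_program(net: CSPBN,
                            spec: ControlSpec) -> PolynomialProgram:
    """Build the explicit polynomial program equivalent to the control
    problem: ``n*N`` state variables, ``m*N`` input variables, ``n*N``
    equality constraints from the recursion (initial state substituted
    into the ``k = 0`` constraints) and ``m*N`` binary constraints.

    The selection distributions do not depend on the inputs, so their
    trajectory is precomputed and enters the constraints as numeric
    weights.
    """
    spec.validate_against(net)
    N, n, m = spec.horizon, net.n, net.m
    polys = candidate_polynomials(net)
    names = net.names

    # selection-distribution trajectory (input-independent)
    Ps = [selection_matrix(g, net.q) for g in net.genes]
    dists = [indicator_distribution(net.j0[i], g.l)
             for i, g in enumerate(net.genes)]
    d_traj = [dists]
    for _ in range(N - 1):
        dists = [Ps[i] @ dists[i] for i in range(n)]
        d_traj.append(dists)

    def sub(poly: MultilinearPoly, k: int) -> MultilinearPoly:
        """Rename model variables to decision variables at time k; at
        k = 0 states are substituted by the numeric initial state."""
        out = MultilinearPoly()
        for mono, coef in poly.terms.items():
            term = MultilinearPoly.constant(coef)
            for v in mono:
                idx = names.index(v)
                if idx < n:  # gene
                    if k == 0:
                        term = term.scale(float(net.x0[idx]))
                    else:
                        term = term * MultilinearPoly.variable(
                            f"E_{idx + 1}_{k}")
                else:  # input
                    term = term * MultilinearPoly.variable(
                        f"u_{idx - n + 1}_{k}")
            out = out + term
        return out

    eqs: list[MultilinearPoly] = []
    for k in range(N):
        for i in range(n):
            rhs = MultilinearPoly()
            for w, p in zip(d_traj[k][i], polys[i]):
                rhs = rhs + sub(p, k).scale(float(w))
            lhs = MultilinearPoly.variable(f"E_{i + 1}_{k + 1}")
            eqs.append(lhs - rhs)

    Q = _as_weights(spec.Q, n, "Q")
    R = _as_weights(spec.R, m, "R")
    Qf = _as_weights(spec.Qf, n, "Qf")
    obj = MultilinearPoly.constant(float(Q @ np.asarray(net.x0, dtype=float)))
    for k in range(1, N):
        for i in range(n):
            obj = obj + MultilinearPoly.variable(f"E_{i + 1}_{k}").scale(Q[i])
    for k in range(N):
        for j in range(m):
            obj = obj + MultilinearPoly.variable(f"u_{j + 1}_{k}").scale(R[j])
    for i in range(n):
        obj = obj + MultilinearPoly.variable(f"E_{i + 1}_{N}").scale(Qf[i])

    state_vars = [f"E_{i + 1}_{k}" for k in range(1, N + 1) for i in range(n)]
    input_vars = [f"u_{j + 1}_{k}" for k in range(N) for j in range(m)]
    binary = [f"{v}*({v} - 1) = 0" for v in input_vars]
    return PolynomialProgram(
        state_vars=state_vars,
        input_vars=input_vars,
        objective=obj,
        equality_constraints=eqs,
        binary_constraints=binary,
        x0=tuple(float(v) for v in net.x0),
    )
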