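"""Bounded maximum reachability for CS-PBNs.

The network, its per-gene function-selection chains and the binary
control inputs form a finite Markov decision process on the joint space

    (x, sel, u)  with  2^n * prod l(i) * 2^m  states,

where per synchronized step the next state bit ``x_i'`` is the
deterministic evaluation of gene ``i``'s currently selected candidate at
``(x, u)``, the selection indices are re-drawn independently from the
column of each gene's switching matrix, and the controller picks the
next input nondeterministically after observing the full joint state.

``max_reachability`` computes the exact finite-horizon maximum
probability that the designated output genes hit a target value at some
time ``0..N`` (target states absorbing) by dense backward value
iteration.  A depth-first path-summation oracle and a vectorized
Monte-Carlo simulator provide independent cross-checks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence, Union

import numpy as np

from .model import CSPBN, CapacityError
from .selection import selection_matrix

__all__ = [
    "ReachabilitySpec",
    "VerificationResult",
    "SimulationResult",
    "max_reachability",
    "max_reachability_bruteforce",
    "open_loop_reachability",
    "max_reachability_open_loop",
    "simulate_paths",
]

#: Default cap on the explicit joint-state count.
DEFAULT_STATE_CAP = 10**7


@dataclass(frozen=True)
class ReachabilitySpec:
    """A bounded-reachability query ``Pmax=?[F<=N y = y_f]``.

    ``output_indices`` are 1-based gene indices defining the output
    ``y`` (``y_i = x_j``); ``target`` is the wanted binary value of
    ``y``; ``horizon`` is the step bound ``N``; ``u0_mode`` fixes the
    initial input to all-zeros (``"0"``), all-ones (``"1"``) or
    maximizes over every initial input (``"both"``), matching one model
    run per ``u(0)``.
    """

    output_indices: tuple[int, ...]
    target: tuple[int, ...]
    horizon: int
    u0_mode: str = "both"

    def __post_init__(self):
        object.__setattr__(self, "output_indices",
                           tuple(int(i) for i in self.output_indices))
        object.__setattr__(self, "target",
                           tuple(int(v) for v in self.target))
        if not self.output_indices:
            raise ValueError("output gene set must be nonempty")
        if len(self.target) != len(self.output_indices):
            raise ValueError("target length must match output gene count")
        if any(v not in (0, 1) for v in self.target):
            raise ValueError("target values must be binary")
        if self.horizon < 0:
            raise ValueError("horizon must be >= 0")
        if self.u0_mode not in ("0", "1", "both"):
            raise ValueError(f"unknown u0_mode {self.u0_mode!r}")

    def validate_against(self, net: CSPBN) -> None:
        for j in self.output_indices:
            if not 1 <= j <= net.n:
                raise ValueError(f"output gene index {j} outside 1..{net.n}")


@dataclass
class VerificationResult:
    """Outcome of a bounded-reachability computation.

    ``pmax`` is the maximum over the considered initial inputs of the
    exact reachability probability; ``per_u0`` maps each initial input
    vector to its value.  When ``policy`` is kept, index ``s`` of the
    list holds the optimal next-input choice (encoded input index, shape
    ``(2^n, prod l)``) to apply when ``s`` steps remain after the
    current transition.
    """

    pmax: float
    per_u0: dict[tuple[int, ...], float]
    policy: list[np.ndarray] | None = None
    u0_star: tuple[int, ...] | None = None


# ---------------------------------------------------------------------------
# Joint-space enumeration
# ---------------------------------------------------------------------------

class _JointSpace:
    """Precomputed explicit representation of the joint MDP."""

    def __init__(self, net: CSPBN, state_cap: int = DEFAULT_STATE_CAP):
        total = net.joint_state_count()
        if total > state_cap:
            raise CapacityError(
                f"joint state space has {total} states, above the cap "
                f"{state_cap}; raise state_cap to proceed")
        self.net = net
        self.n = net.n
        self.m = net.m
        self.nx = 2 ** net.n
        self.nu = 2 ** net.m
        self.ls = [g.l for g in net.genes]
        self.L = int(np.prod(self.ls)) if self.ls else 1

        # mixed-radix strides for sel encoding, gene 0 most significant
        # (matches the kron order used for the joint switching matrix)
        strides = []
        acc = 1
        for l in reversed(self.ls):
            strides.append(acc)
            acc *= l
        self.sel_strides = list(reversed(strides))

        names = net.names
        self._truth_tables = []  # per gene: array (l_i, nx, nu) of 0/1
        envs = None
        for gene in net.genes:
            tabs = np.empty((gene.l, self.nx, self.nu), dtype=np.int8)
            for j, cand in enumerate(gene.candidates):
                for xi in range(self.nx):
                    for ui in range(self.nu):
                        env = self._env(xi, ui)
                        tabs[j, xi, ui] = cand.expr.evaluate(env)
            self._truth_tables.append(tabs)

        # deterministic x-update: next_x[x, sel, u]
        self.next_x = np.zeros((self.nx, self.L, self.nu), dtype=np.int64)
        for sel_idx in range(self.L):
            js = self.decode_sel(sel_idx)
            acc = np.zeros((self.nx, self.nu), dtype=np.int64)
            for i in range(self.n):
                acc += self._truth_tables[i][js[i] - 1].astype(np.int64) << i
            self.next_x[:, sel_idx, :] = acc

        # joint selection-switching matrix (column-stochastic), kron over
        # genes with gene 0 most significant
        P = np.ones((1, 1))
        for gene in net.genes:
            P = np.kron(P, selection_matrix(gene, net.q))
        self.P_joint = P

    # -- encodings --------------------------------------------------------
    def _env(self, x_idx: int, u_idx: int) -> dict[str, int]:
        net = self.net
        env = {g.name: (x_idx >> i) & 1 for i, g in enumerate(net.genes)}
        for j, name in enumerate(net.inputs):
            env[name] = (u_idx >> j) & 1
        return env

    def encode_x(self, x: Sequence[int]) -> int:
        return sum(int(v) << i for i, v in enumerate(x))

    def decode_x(self, x_idx: int) -> tuple[int, ...]:
        return tuple((x_idx >> i) & 1 for i in range(self.n))

    def encode_u(self, u: Sequence[int]) -> int:
        return sum(int(v) << j for j, v in enumerate(u))

    def decode_u(self, u_idx: int) -> tuple[int, ...]:
        return tuple((u_idx >> j) & 1 for j in range(self.m))

    def encode_sel(self, j0: Sequence[int]) -> int:
        return sum((int(j) - 1) * s for j, s in zip(j0, self.sel_strides))

    def decode_sel(self, sel_idx: int) -> tuple[int, ...]:
        out = []
        for l, s in zip(self.ls, self.sel_strides):
            out.append((sel_idx // s) % l + 1)
        return tuple(out)

    def target_mask(self, spec: ReachabilitySpec) -> np.ndarray:
        """Boolean mask over x indices where the output equals the target."""
        mask = np.ones(self.nx, dtype=bool)
        xs = np.arange(self.nx)
        for j, v in zip(spec.output_indices, spec.target):
            mask &= ((xs >> (j - 1)) & 1) == v
        return mask

    def u0_indices(self, mode: str) -> list[int]:
        if mode == "0":
            return [0]
        if mode == "1":
            return [self.nu - 1]
        return list(range(self.nu))


# ---------------------------------------------------------------------------
# Exact value iteration
# ---------------------------------------------------------------------------

def max_reachability(net: CSPBN, spec: ReachabilitySpec,
                     state_cap: int = DEFAULT_STATE_CAP,
                     keep_policy: bool = True) -> VerificationResult:
    """Exact finite-horizon maximum reachability on the joint MDP.

    Backward value iteration with the target made absorbing and checked
    at every time ``0..N``; the controller observes the full joint state
    and the maximization over the initial input follows
    ``spec.u0_mode``.  Raises :class:`CapacityError` above ``state_cap``
    joint states.
    """
    spec.validate_against(net)
    space = _JointSpace(net, state_cap)
    target_x = space.target_mask(spec)

    # V[x, sel, u]: probability of reaching the target within s steps
    V = np.broadcast_to(target_x.astype(float)[:, None, None],
                        (space.nx, space.L, space.nu)).copy()
    sel_ax = np.arange(space.L)[None, :, None]
    policy: list[np.ndarray] = []
    for _ in range(spec.horizon):
        # expected value after the stochastic sel re-draw, per next input:
        # M[x', sel, u'] = sum_{sel'} P_joint[sel', sel] V[x', sel', u']
        M = np.einsum("ba,xbu->xau", space.P_joint, V)
        best_u = np.argmax(M, axis=2)           # (x', sel)
        Mmax = np.max(M, axis=2)                # (x', sel)
        if keep_policy:
            policy.append(best_u.astype(np.int64))
        V = Mmax[space.next_x, sel_ax]          # (x, sel, u)
        V[target_x] = 1.0

    x0_idx = space.encode_x(net.x0)
    sel0 = space.encode_sel(net.j0)
    per_u0: dict[tuple[int, ...], float] = {}
    for u_idx in space.u0_indices(spec.u0_mode):
        # clamp float round-off at the probability boundaries
        per_u0[space.decode_u(u_idx)] = float(
            min(1.0, max(0.0, V[x0_idx, sel0, u_idx])))
    u0_star = max(per_u0, key=lambda u: (per_u0[u], tuple(-b for b in u)))
    return VerificationResult(
        pmax=per_u0[u0_star],
        per_u0=per_u0,
        policy=policy if keep_policy else None,
        u0_star=u0_star,
    )


# ---------------------------------------------------------------------------
# Independent brute-force oracle (tiny instances)
# ---------------------------------------------------------------------------

def max_reachability_bruteforce(net: CSPBN,
                                spec: ReachabilitySpec) -> float:
    """Depth-first path summation with maximization at every decision.

    Recursively enumerates every selection outcome and every input
    choice without memoization — exponential, intended only for tiny
    cross-check instances (tens of joint states, horizon <= 3).
    """
    spec.validate_against(net)
    names = net.names
    q = net.q

    def is_target(x: tuple[int, ...]) -> bool:
        return all(x[j - 1] == v
                   for j, v in zip(spec.output_indices, spec.target))

    def step_x(x, sel, u):
        env = dict(zip(names, x + u))
        return tuple(g.candidates[sel[i] - 1].expr.evaluate(env)
                     for i, g in enumerate(net.genes))

    def sel_branches(sel):
        per_gene = []
        for i, g in enumerate(net.genes):
            opts = []
            for j in range(1, g.l + 1):
                p = g.candidates[j - 1].prob * q + (1.0 - q) * (j == sel[i])
                if p > 0.0:
                    opts.append((j, p))
            per_gene.append(opts)
        for combo in itertools.product(*per_gene):
            yield (tuple(j for j, _ in combo),
                   float(np.prod([p for _, p in combo])))

    all_u = list(itertools.product((0, 1), repeat=net.m))

    def value(x, sel, u, steps_left) -> float:
        if is_target(x):
            return 1.0
        if steps_left == 0:
            return 0.0
        x2 = step_x(x, sel, u)
        best = 0.0
        for u2 in all_u:
            total = 0.0
            for sel2, p in sel_branches(sel):
                total += p * value(x2, sel2, u2, steps_left - 1)
            best = max(best, total)
        return best

    x0 = tuple(net.x0)
    sel0 = tuple(net.j0)
    if spec.u0_mode == "0":
        u0s = [tuple([0] * net.m)]
    elif spec.u0_mode == "1":
        u0s = [tuple([1] * net.m)]
    else:
        u0s = all_u
    return max(value(x0, sel0, u0, spec.horizon) for u0 in u0s)


# ---------------------------------------------------------------------------
# Open-loop comparison
# ---------------------------------------------------------------------------

def open_loop_reachability(net: CSPBN, spec: ReachabilitySpec,
                           u_seq: Sequence[Sequence[int]],
                           state_cap: int = DEFAULT_STATE_CAP) -> float:
    """Exact reach probability of one fixed input sequence ``u(0..N-1)``
    (target absorbing, checked at times ``0..N``)."""
    spec.validate_against(net)
    seq = [tuple(int(v) for v in u) for u in u_seq]
    if len(seq) < spec.horizon:
        raise ValueError("input sequence shorter than the horizon")
    space = _JointSpace(net, state_cap)
    target_x = space.target_mask(spec)

    D = np.zeros((space.nx, space.L))
    D[space.encode_x(net.x0), space.encode_sel(net.j0)] = 1.0
    reached = 0.0
    for t in range(spec.horizon):
        reached += D[target_x].sum()
        D[target_x] = 0.0
        u_idx = space.encode_u(seq[t])
        moved = np.zeros_like(D)
        dest = space.next_x[:, :, u_idx]        # (x, sel) -> x'
        np.add.at(moved, (dest, np.arange(space.L)[None, :]), D)
        D = moved @ space.P_joint.T             # simultaneous sel re-draw
    reached += D[target_x].sum()
    return float(reached)


def max_reachability_open_loop(net: CSPBN, spec: ReachabilitySpec,
                               enum_cap: int = 24,
                               state_cap: int = DEFAULT_STATE_CAP
                               ) -> tuple[float, list[tuple[int, ...]]]:
    """Best *fixed* input sequence by exhaustive enumeration, for
    comparison with the closed-loop (state-feedback) maximum; returns
    ``(probability, best sequence)``.  The closed-loop value is always
    at least as large."""
    if net.m * spec.horizon > enum_cap:
        raise CapacityError(
            f"m*N = {net.m * spec.horizon} exceeds the enumeration cap "
            f"{enum_cap}")
    best_p, best_seq = -1.0, None
    for bits in itertools.product((0, 1), repeat=net.m * spec.horizon):
        seq = [tuple(bits[t * net.m:(t + 1) * net.m])
               for t in range(spec.horizon)]
        # honor the initial-input mode
        if spec.horizon > 0 and net.m:
            if spec.u0_mode == "0" and any(seq[0]):
                continue
            if spec.u0_mode == "1" and not all(seq[0]):
                continue
        p = open_loop_reachability(net, spec, seq, state_cap)
        if p > best_p:
            best_p, best_seq = p, seq
    return best_p, (best_seq or [])


# ---------------------------------------------------------------------------
# Monte-Carlo simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Sampled trajectories: ``x_paths``/``sel_paths`` have shape
    ``(runs, horizon + 1, n)`` (selection indices 1-based); ``u_paths``
    has shape ``(runs, horizon, m)``.  ``reach_frequency`` is the
    fraction of paths whose output hit the target at some time
    ``0..horizon`` (None when no reachability spec was given)."""

    x_paths: np.ndarray
    sel_paths: np.ndarray
    u_paths: np.ndarray
    reach_frequency: float | None


Policy = Union[Sequence[Sequence[int]], VerificationResult,
               Callable[[tuple, int], Sequence[int]]]


def simulate_paths(net: CSPBN, input_policy: Policy, horizon: int,
                   runs: int = 1000, seed: int = 0,
                   spec: ReachabilitySpec | None = None,
                   state_cap: int = DEFAULT_STATE_CAP) -> SimulationResult:
    """Simulate joint trajectories under a fixed or state-feedback input.

    ``input_policy`` may be an open-loop sequence of input vectors
    ``u(0..horizon-1)``, a :class:`VerificationResult` carrying the
    optimal reachability strategy (its ``u0_star`` seeds ``u(0)``), or a
    callable ``(joint_state, step) -> input vector`` where the joint
    state is ``(x tuple, sel tuple, u tuple)``.  Given the same seed the
    sampled paths are reproducible.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    space = _JointSpace(net, state_cap)
    rng = np.random.default_rng(seed)
    n, m = net.n, net.m

    closed_loop = isinstance(input_policy, VerificationResult)
    callable_policy = callable(input_policy) and not closed_loop
    if closed_loop:
        if input_policy.policy is None:
            raise ValueError("VerificationResult has no stored policy")
        u0 = input_policy.u0_star
        pol = input_policy.policy
    elif callable_policy:
        u0 = None  # asked per state below
    else:
        seq = [tuple(int(v) for v in u) for u in input_policy]
        if len(seq) < horizon:
            raise ValueError(
                f"open-loop input sequence length {len(seq)} < horizon {horizon}")
        u0 = seq[0] if horizon > 0 else tuple([0] * m)

    x_idx = np.full(runs, space.encode_x(net.x0), dtype=np.int64)
    sel = np.tile(np.array(net.j0, dtype=np.int64), (runs, 1))  # 1-based
    if callable_policy:
        state0 = (tuple(net.x0), tuple(net.j0), tuple([0] * m))
        u0 = tuple(int(v) for v in input_policy(state0, 0))
    u_idx = np.full(runs, space.encode_u(u0) if m else 0, dtype=np.int64)

    target_x = space.target_mask(spec) if spec is not None else None
    reached = target_x[x_idx].copy() if spec is not None else None

    x_paths = np.empty((runs, horizon + 1, n), dtype=np.int8)
    sel_paths = np.empty((runs, horizon + 1, n), dtype=np.int64)
    u_paths = np.empty((runs, horizon, m), dtype=np.int8)
    probs = [np.asarray(g.probs, dtype=float) for g in net.genes]
    cum = [np.cumsum(p) for p in probs]

    def record(t):
        for i in range(n):
            x_paths[:, t, i] = (x_idx >> i) & 1
        sel_paths[:, t, :] = sel

    record(0)
    for t in range(horizon):
        for j in range(m):
            u_paths[:, t, j] = (u_idx >> j) & 1
        # deterministic state update given current selections and input
        sel_joint = (sel - 1) @ np.asarray(space.sel_strides, dtype=np.int64)
        x_next = space.next_x[x_idx, sel_joint, u_idx]
        # next input: chosen on observing (x', sel) before sel re-draw
        if t + 1 < horizon:
            if closed_loop:
                # policy[k-1] is the next-input choice computed with k
                # transitions remaining; here k = horizon - t
                u_idx = pol[horizon - t - 1][x_next, sel_joint]
            elif callable_policy:
                new_u = np.empty(runs, dtype=np.int64)
                for r in range(runs):
                    st = (space.decode_x(int(x_next[r])),
                          tuple(int(v) for v in sel[r]),
                          space.decode_u(int(u_idx[r])))
                    new_u[r] = space.encode_u(input_policy(st, t + 1))
                u_idx = new_u
            else:
                u_idx = np.full(runs, space.encode_u(seq[t + 1]),
                                dtype=np.int64)
        # selection re-draw: switch w.p. q, then sample from c
        for i in range(n):
            switch = rng.random(runs) < net.q
            if switch.any():
                draws = np.searchsorted(cum[i], rng.random(runs)) + 1
                np.minimum(draws, len(cum[i]), out=draws)
                sel[:, i] = np.where(switch, draws, sel[:, i])
        x_idx = x_next
        record(t + 1)
        if spec is not None:
            reached |= target_x[x_idx]

    freq = float(reached.mean()) if spec is not None else None
    return SimulationResult(x_paths=x_paths, sel_paths=sel_paths,
                            u_paths=u_paths, reach_frequency=freq)
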