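# Methods

## Model

A context-sensitive probabilistic Boolean network (CS-PBN) over genes
`x_1..x_n ∈ {0,1}` and control inputs `u_1..u_m ∈ {0,1}` gives each gene
an ordered list of candidate Boolean update functions
`f_j^(i)(x, u)`, `j = 1..l(i)`, with selection probabilities `c_j^(i)`
summing to one, plus a single switching probability `q ∈ [0,1]` shared
by all genes.  The hidden per-gene index `sel(i)` of the active
candidate evolves as a Markov chain: with probability `q` it is re-drawn
from `c^(i)` (independently across genes and of everything else), with
probability `1 − q` it is kept.  Writing the chain column-stochastically
(`P[a,b] = c_a q + (1−q)[a=b]`, distributions as column vectors,
`d(k+1) = P d(k)`) makes `q = 0` the frozen deterministic network and
`q = 1` the classical memoryless PBN; for `0 < q < 1` the selection
distribution contracts to `c` geometrically at rate `1 − q`.

Both the initial state `x0` and the initial function indices `j0` are
part of a problem instance: the function active at time 0 is known, so
the first transition is deterministic for binary `x0`.

Updates are synchronous.  One network step simultaneously (i) sets every
`x_i' = f_{sel(i)}^{(i)}(x, u)` using the *current* selections and input,
(ii) re-draws the selections, and (iii) lets the controller choose the
next input.  The input choice is made before the new selections are
revealed — the semantics of synchronized guarded-command modules, which
the PRISM export mirrors exactly.

## Boolean functions as multilinear polynomials

Every Boolean expression is converted to its multilinear extension by
the rewrite rules `¬a ↦ 1−a`, `a∨b ↦ a+b−ab`, `a∧b ↦ ab`, with
idempotent powers reduced via `a² = a`.  The internal representation is
a sparse map from monomials (sets of variable names, so idempotence is
structural) to real coefficients; zero coefficients are dropped, making
polynomial equality plain structural equality.  Coefficients of
Boolean-derived polynomials are integers, and all fixture arithmetic
involves only small integers and decimal probabilities, so double
precision is exact for the shipped networks and no rational backend is
used.  Evaluated at independent Bernoulli marginals the extension equals
the expectation of the Boolean function — the property the control
recursion relies on.

## Verification

Bounded maximum reachability is computed on the explicit joint space
`(x, sel, u)` (size `2^n · Π l(i) · 2^m`; 8192 states for the WNT5A
instance) by dense backward value iteration:

```
V_0 = [target],   V_{k+1}(x,sel,u) = 1 if target(x) else
      max_{u'} Σ_{sel'} P_joint(sel'|sel) V_k(x', sel', u'),
```

with `x'` the deterministic update and `P_joint` the Kronecker product
of the per-gene switching matrices.  The target is checked at every
time `0..N` and made absorbing, the standard bounded-eventually
reading.  The maximization is over state-feedback strategies (the
controller observes the full joint state), which is what a
model-checker's MDP engine computes; because the initial input must be
fixed in the encoding, the engine evaluates every `u(0)` and reports
each value plus their maximum.  An exhaustive open-loop search over
fixed input sequences is available separately for comparison; it can
only do worse.  Optimal choices are recorded per backward step, so the
extracted strategy can drive the Monte-Carlo simulator and be validated
against the exact value.

Numerical notes: values are clamped to `[0,1]` to absorb float
round-off at the boundaries; argmax ties resolve to the
lowest-encoded input; instances above a configurable cap (default 10^7
joint states) raise a capacity error rather than thrash.  Two
independent cross-checks guard the engine: a memoization-free
depth-first path-summation oracle for tiny instances, and a separately
coded memoryless-PBN recursion for the `q = 1` limit.

## PRISM export

The generator emits one selection-chain module and one state module per
gene and a four-command nondeterministic module per input — `2n + m`
modules, all synchronizing on a single shared action label so that one
product transition is one network step.  Branch probabilities are
written symbolically as `c*q` and `c*q + (1-q)`, with `q` a `const
double`, so each emitted file serves one `q`.  State updates are the
multilinear polynomials rendered in integer arithmetic (e.g.
`(x1'=u - u*x2)`), which PRISM evaluates to 0/1 on binary variables.
Identifiers colliding with PRISM keywords are renamed with a trailing
underscore and a warning.  The initial input value must be fixed in the
file, so verification against the package engine uses one file per
`u(0)`.

## Optimal control

The expected-state recursion propagates
`E[x_i(k+1)] = Σ_j d_j^(i)(k) f̂_j^(i)(E[x(k)], u(k))` together with
`d(k+1) = P d(k)`, starting from `d(0)` = the indicator of `j0`.  This
is the model's standard surrogate for the true expectation: it treats
gene levels as independent when plugging marginals into the
polynomials, so no claim of equality with the exact process expectation
is made (or tested) beyond the forced cases — step 1, `q = 0`, and
single-candidate genes.  With `q = 1` *and* `d(0) = c` the recursion
collapses to the memoryless-PBN form `E[x_i(k+1)] = Σ_j c_j f̂_j(·)`;
`rollout` therefore accepts an optional `d0` override (`"candidate"`),
which is how the equivalence of the two code paths is asserted.  With
the default indicator `d(0)` the two differ at step 0 by construction,
since the memoryless form has no distinguished initial function.

The cost `J = Σ_{k<N}(Q·E[x(k)] + R·u(k)) + Q_f·E[x(N)]` is linear with
nonnegative weights.  Because inputs are binary (`u(u−1) = 0`) and the
recursion determines the trajectory from the sequence, the polynomial
program has exactly `2^{mN}` feasible points; the optimizer enumerates
them (lexicographic order, first minimum kept, capacity error above a
configurable `m·N` cap, default 24) and is therefore exact.  The
program exporter preserves the general formulation for larger
instances: decision variables `E[x_i(k)]` (`k = 1..N`) and `u_j(k)`,
the recursion equalities with the input-independent selection weights
precomputed as numbers and `x0` substituted into the `k = 0`
constraints, and the binary constraints — `n·N` equalities plus `m·N`
binary conditions.  A round-trip check confirms the enumerated optimum
satisfies the emitted constraints to 1e−9.

For the shipped WNT5A control instance the enumerated optimum is the
sequence `(1,0,0,0,0)` (cost ≈ 3.689 under the stated weights), and the
commonly quoted sequence `(1,1,0,0,0)` costs ≈ 4.067 on the same
trajectory; the package reports whatever enumeration finds and exposes
all weights as parameters rather than asserting any particular
published optimum.

## Fixtures and the random generator

The apoptosis builder (3 genes, TNF input, candidate probabilities
0.6/0.4, 0.7/0.3, 0.8/0.2, defaults `x0 = (1,1,1)`, `j0` all 1) and the
WNT5A builder (6 genes after substituting pirin by the input, each gene
applying its regulatory update with probability `c1` or holding with
`c2`, verification default `x0 = (1,0,0,1,0,0)`, control default
`x0 = (1,1,0,1,0,0)`, `j0` all 1) encode the two study networks; the
original seven-gene autonomous Boolean form is included for
completeness.  Candidate probabilities of exactly 0 are permitted —
such a candidate can then only ever be active as the initial function.

The random generator draws candidate counts uniformly on
`1..max_candidates`, probabilities from a flat Dirichlet with the last
entry closed so sums are exactly one, and expressions as random
NOT/AND/OR trees over all declared names with a bounded leaf count.  It
emulates structural variety for property testing — arbitrary wiring,
fractional probabilities, degenerate single-candidate genes — but not
biological topology (no scale-free structure, no canalizing bias), so
passing property suites demonstrate algorithmic correctness, not
fidelity to real regulatory networks.

## Problem sizes and defaults

All shipped computations are desk-scale by design: the verification
engine runs the 8192-state WNT5A instance in well under a second; the
oracle-equivalence suite uses 50 random two-gene instances (≤ 64 joint
states, horizon ≤ 3); Monte-Carlo checks use 100,000 paths against a
three-standard-error band; the control study enumerates 32 sequences.
Probability-sum tolerance is 1e−9 everywhere and stored probabilities
are never silently renormalized; equality of exact quantities is
asserted to 1e−12 in the test suite.  The command-line interface prints
four decimals by default (`--precision` to change).

## Limitations

* Unbounded-horizon reachability, steady-state properties and general
  PCTL are out of scope; only bounded eventually is supported (the
  property emitter can print the unbounded variant for external
  checkers).
* Closed-loop (feedback) *optimal control* is not implemented; feedback
  appears only inside the verification MDP semantics.
* The expected-state recursion is a mean-field surrogate; it does not
  track correlations between genes.
* Network inference from expression data, and estimation of `c` or `q`,
  are out of scope.
* The explicit engines are meant for tens of genes' worth of joint
  states at most; capacity errors point to the PRISM and
  polynomial-program exporters for larger instances.
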