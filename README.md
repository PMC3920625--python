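# cspbn

Verification and open-loop optimal control of **context-sensitive
probabilistic Boolean networks** (CS-PBNs), a standard discrete model of
gene regulatory networks.

In a Boolean network each gene is ON/OFF and updates through a Boolean
function of the current gene levels and binary control inputs.  A
probabilistic Boolean network (PBN) gives each gene `x_i` several
candidate update functions `f_j^(i)(x, u)` with selection probabilities
`c_j^(i)` (`Σ_j c_j^(i) = 1`).  A *context-sensitive* PBN adds inertia:
per time step the active function is re-drawn only with switching
probability `q`, and kept with probability `1 − q`, so each gene carries
a hidden Markov chain over its candidate indices with column-stochastic
transition matrix

```
P^(i)[a, b] = c_a^(i) q + (1 − q)·[a = b],        d^(i)(k+1) = P^(i) d^(i)(k).
```

The package answers two questions about such networks:

* **Verification** — the maximum probability, over all input
  strategies, that a set of output genes reaches a target value within
  `N` steps (`Pmax=?[F<=N (x_j = v) & …]`).  The network, its selection
  chains and the inputs form a finite Markov decision process on the
  joint states `(x, sel, u)`; the engine solves it by exact backward
  value iteration with the target absorbing.  The same model can be
  exported as PRISM 4.x MDP code plus a PCTL property string for an
  external model checker.
* **Optimal control** — the fixed input sequence `u(0..N−1)` minimizing
  the expected linear cost
  `J = Σ_{k<N} (Q x(k) + R u(k)) + Q_f x(N)`.
  Each candidate function is replaced by its multilinear extension
  (`¬a ↦ 1−a`, `a∨b ↦ a+b−ab`, `a∧b ↦ ab`), giving the expected-state
  recursion `E[x_i(k+1)] = Σ_j d_j^(i)(k) f̂_j^(i)(E[x(k)], u(k))`.
  Binary inputs make the equivalent polynomial program finite, so it is
  solved exactly by enumeration; the program itself can be emitted as
  text for a polynomial-optimization solver.

Two literature networks ship as builders — a three-gene apoptosis module
(IAP / C3a / C8a with the TNF stimulus as input) and the six-gene WNT5A
melanoma network with pirin as the input — along with a seeded random
network generator, a plain-text YAML model format
(`docs/model-schema.json`), a Monte-Carlo simulator and a brute-force
verification oracle.

## Worked example

```python
import cspbn

# WNT5A network: keep the WNT5A level x1 low within 5 steps.
net = cspbn.wnt5a_network(c1=0.5, c2=0.5, q=0.3)   # x0=(1,0,0,1,0,0)
spec = cspbn.ReachabilitySpec(output_indices=(1,), target=(0,),
                              horizon=5, u0_mode="both")
result = cspbn.max_reachability(net, spec)
print(round(result.pmax, 4), {u: round(p, 4) for u, p in result.per_u0.items()})
```

prints

```
0.7215 {(0,): 0.6529, (1,): 0.7215}
```

i.e. the best strategy starts with pirin ON (`u(0) = 1`) and drives
WNT5A low within five steps with probability 0.7215; starting with
pirin OFF only achieves 0.6529.  Raising the switching probability
degrades the best achievable value (0.6587 at `q = 0.5`, 0.6489 at
`q = 0.7`).  For control:

```python
net = cspbn.wnt5a_network(0.8, 0.2, 0.3, x0=(1, 1, 0, 1, 0, 0))
traj = cspbn.rollout(net, [(1,), (1,), (0,), (0,), (0,)])
print(traj.ex[2][0], traj.ex[5][4])
```

prints `0.06 0.33845963...`: after two steps the expected WNT5A level
has dropped from 1 to 0.06, and the expected MART1 level at the final
time is 0.3385.

The same computations from the shell:

```sh
cspbn fixtures --name wnt5a --c1 0.5 --q 0.3 --out wnt5a.yaml
cspbn verify wnt5a.yaml --target "x1=0" --horizon 5 --u0 both
cspbn control wnt5a.yaml --x0 1,1,0,1,0,0 --Q 1,0,0,0,0,0 --R 1 \
      --Qf 1,0,0,0,0,0 --horizon 5
cspbn export-prism wnt5a.yaml --u0 1 --out wnt5a.nm \
      --property "x1=0" --horizon 5 --prop-out wnt5a.pctl
```

`cspbn validate`, `cspbn simulate` and `cspbn generate` cover model
checking-in, Monte-Carlo sampling and random test networks; see
`cspbn --help`.

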