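"""Built-in example networks and a random CS-PBN generator.

Two literature networks ship as programmatic builders: a three-gene
apoptosis module (IAP, C3a, C8a with the TNF stimulus as input) and the
six-gene WNT5A melanoma network with pirin as the control input (the
seven-gene autonomous Boolean form is also available).  A seeded random
generator produces arbitrary valid CS-PBNs for property testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (BoolExpr, CandidateFunction, Const, CSPBN, GeneSpec, Not,
                    Or, And, Var, parse_expr)

__all__ = [
    "GeneratorConfig",
    "apoptosis_network",
    "wnt5a_network",
    "wnt5a_autonomous_network",
    "random_cspbn",
]


def _gene(name: str, vocab, *cands: tuple[str, float]) -> GeneSpec:
    return GeneSpec(name, tuple(
        CandidateFunction(parse_expr(expr, vocab), prob)
        for expr, prob in cands))


def apoptosis_network(q: float,
                      x0=(1, 1, 1), j0=(1, 1, 1)) -> CSPBN:
    """Three-gene apoptosis CS-PBN.

    ``x1`` is the inhibitor-of-apoptosis protein level (IAP), ``x2``
    active caspase 3 (C3a), ``x3`` active caspase 8 (C8a); the tumor
    necrosis factor stimulus (TNF) is the input ``u``.  Each gene keeps
    its regulatory update with the stated probability or holds its value
    otherwise:

    ====  =======================  ====
    gene  candidate 1              c1
    ====  =======================  ====
    x1    ``!x2 & u``              0.6
    x2    ``!x1 & x3``             0.7
    x3    ``x2 | u``               0.8
    ====  =======================  ====

    (candidate 2 is the identity with the complementary probability).
    """
    vocab = ("x1", "x2", "x3", "u")
    return CSPBN(
        genes=(
            _gene("x1", vocab, ("!x2 & u", 0.6), ("x1", 0.4)),
            _gene("x2", vocab, ("!x1 & x3", 0.7), ("x2", 0.3)),
            _gene("x3", vocab, ("x2 | u", 0.8), ("x3", 0.2)),
        ),
        inputs=("u",),
        q=q,
        x0=tuple(x0),
        j0=tuple(j0),
    )


#: Regulatory update of each WNT5A-network gene once pirin is the input:
#: x1=WNT5A, x2=S100P, x3=RET1, x4=MART1, x5=HADHB, x6=STC2, u=pirin.
_WNT5A_UPDATES = ("!x5", "!x6", "x3", "!x6 | u", "x2 | x3", "x6 | !u")


def wnt5a_network(c1: float, c2: float, q: float,
                  x0=(1, 0, 0, 1, 0, 0),
                  j0=(1, 1, 1, 1, 1, 1)) -> CSPBN:
    """Six-gene WNT5A melanoma CS-PBN with pirin as the control input.

    Gene order after substituting pirin by ``u``: WNT5A, S100P, RET1,
    MART1, HADHB, STC2.  Every gene applies its regulatory update with
    probability ``c1`` and holds its current value with ``c2``
    (``c1 + c2 = 1``).  The usual intervention goal is to keep the WNT5A
    level ``x1`` low.
    """
    if abs(c1 + c2 - 1.0) > 1e-9:
        raise ValueError(f"c1 + c2 = {c1 + c2!r}, expected 1")
    vocab = tuple(f"x{i}" for i in range(1, 7)) + ("u",)
    genes = tuple(
        _gene(f"x{i + 1}", vocab, (upd, c1), (f"x{i + 1}", c2))
        for i, upd in enumerate(_WNT5A_UPDATES))
    return CSPBN(genes=genes, inputs=("u",), q=q,
                 x0=tuple(x0), j0=tuple(j0))


def wnt5a_autonomous_network(q: float = 0.0,
                             x0=(0, 1, 0, 0, 1, 0, 0),
                             j0=(1,) * 7) -> CSPBN:
    """Original seven-gene autonomous WNT5A Boolean network (one
    deterministic update per gene, no input): WNT5A, pirin, S100P, RET1,
    MART1, HADHB, STC2."""
    updates = (
        "!x6",
        "(!x2 & x4 & x6) | (x2 & (x4 | x6))",
        "!x7",
        "x4",
        "x2 | !x7",
        "x3 | x4",
        "!x2 | x7",
    )
    vocab = tuple(f"x{i}" for i in range(1, 8))
    genes = tuple(_gene(f"x{i + 1}", vocab, (upd, 1.0))
                  for i, upd in enumerate(updates))
    return CSPBN(genes=genes, inputs=(), q=q, x0=tuple(x0), j0=tuple(j0))


# ---------------------------------------------------------------------------
# Random generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the random-network generator: ``n`` genes, ``m``
    inputs, up to ``max_candidates`` update rules per gene, expression
    trees with at most ``max_literals`` leaves, switching probability
    ``q``, and a seed making the draw reproducible."""

    n: int = 3
    m: int = 1
    max_candidates: int = 2
    max_literals: int = 4
    q: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n < 1 or self.m < 0 or self.max_candidates < 1:
            raise ValueError("need n >= 1, m >= 0, max_candidates >= 1")
        if self.max_literals < 1:
            raise ValueError("max_literals must be >= 1")
        if not (0.0 <= self.q <= 1.0):
            raise ValueError("q must be in [0, 1]")


def _random_expr(rng: np.random.Generator, vocab: tuple[str, ...],
                 budget: int) -> BoolExpr:
    """Random expression tree with at most ``budget`` leaves."""
    if budget <= 1:
        # mostly variables, occasionally a constant
        if rng.random() < 0.9:
            return Var(vocab[rng.integers(len(vocab))])
        return Const(int(rng.integers(2)))
    roll = rng.random()
    if roll < 0.25:
        return Not(_random_expr(rng, vocab, budget))
    if roll < 0.45:
        return _random_expr(rng, vocab, 1)
    left = int(rng.integers(1, budget))
    a = _random_expr(rng, vocab, left)
    b = _random_expr(rng, vocab, budget - left)
    return And((a, b)) if roll < 0.725 else Or((a, b))


def random_cspbn(config: GeneratorConfig) -> CSPBN:
    """Draw a random valid CS-PBN.

    Candidate counts are uniform on ``1..max_candidates``, selection
    probabilities come from a flat Dirichlet (last entry closed to an
    exact unit sum), expressions are random trees over all declared
    names, and ``x0``/``j0`` are drawn uniformly.  The same config
    (including seed) always yields the identical network.
    """
    rng = np.random.default_rng(config.seed)
    gene_names = tuple(f"x{i + 1}" for i in range(config.n))
    input_names = tuple(f"u{j + 1}" for j in range(config.m))
    vocab = gene_names + input_names

    genes = []
    for name in gene_names:
        l = int(rng.integers(1, config.max_candidates + 1))
        probs = rng.dirichlet(np.ones(l))
        probs[-1] = 1.0 - float(np.sum(probs[:-1]))  # close to exact 1
        cands = tuple(
            CandidateFunction(
                _random_expr(rng, vocab, config.max_literals),
                float(p))
            for p in probs)
        genes.append(GeneSpec(name, cands))

    x0 = tuple(int(v) for v in rng.integers(0, 2, size=config.n))
    j0 = tuple(int(rng.integers(1, g.l + 1)) for g in genes)
    return CSPBN(genes=tuple(genes), inputs=input_names, q=config.q,
                 x0=x0, j0=j0)
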