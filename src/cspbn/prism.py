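"""PRISM-language model generation for CS-PBNs.

Emits an MDP model in the PRISM 4.x language with, per gene ``i``, a
chain module ``CSPBNm<i>`` (variable ``d_i`` over candidate indices,
branch probabilities ``c_j*q`` plus ``(1-q)`` on the self branch) and a
state module ``CSPBN<i>`` (variable ``x_i``, update expression the
multilinear polynomial of the selected candidate, rendered in integer
arithmetic), plus one nondeterministic module per control input.  All
commands synchronize on the shared label ``[CSPBN]``, so one transition
of the product is one network step.  The matching bounded-reachability
property string ``Pmax=?[F<=N (...)]`` is produced separately.

The initial input value must be fixed in the emitted file, so one model
file is generated per ``u(0)`` (and per ``q``), mirroring one model
checker run per case.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

from .model import CSPBN, validate
from .polynomial import MultilinearPoly, to_polynomial
from .verification import ReachabilitySpec

__all__ = ["PrismModel", "emit_model", "emit_property"]

SYNC_LABEL = "CSPBN"

#: Reserved words of the PRISM language (plus the emitted constant name);
#: colliding model identifiers are renamed with a warning.
_PRISM_KEYWORDS = frozenset("""
    A bool clock const ctmc C double dtmc E endinit endinvariant endmodule
    endrewards endsystem false formula filter func F global G init invariant
    I int label max mdp min module X nondeterministic Pmax Pmin P pomdp
    pta rate rewards R S stochastic system true U W q
""".split())


@dataclass(frozen=True)
class PrismModel:
    """Generated PRISM model text plus bookkeeping metadata."""

    source: str
    module_names: tuple[str, ...]
    renamed: dict[str, str]

    def __str__(self) -> str:
        return self.source


def _safe_names(net: CSPBN) -> dict[str, str]:
    """Map declared names to PRISM-safe identifiers, renaming keyword
    collisions (``name`` -> ``name_``) with a warning."""
    mapping: dict[str, str] = {}
    taken = set(_PRISM_KEYWORDS)
    for name in net.names:
        safe = name
        while safe in taken:
            safe += "_"
        if safe != name:
            warnings.warn(
                f"identifier {name!r} collides with a PRISM keyword; "
                f"renamed to {safe!r}")
        mapping[name] = safe
        taken.add(safe)
    return mapping


def _poly_prism(poly: MultilinearPoly, rename: dict[str, str]) -> str:
    """Render a Boolean-derived polynomial as a PRISM integer expression.

    Coefficients of such polynomials are integers, so the rendered text
    stays in integer arithmetic and evaluates to 0 or 1 on binary
    variable values.
    """
    if not poly.terms:
        return "0"
    keys = sorted(poly.terms, key=lambda m: (len(m), sorted(m)))
    parts: list[str] = []
    for mono in keys:
        coef = poly.terms[mono]
        icoef = int(round(coef))
        if abs(coef - icoef) > 1e-12:
            raise ValueError(
                f"non-integer coefficient {coef} in Boolean-derived polynomial")
        body = "*".join(rename[v] for v in sorted(mono))
        if not mono:
            text = str(abs(icoef))
        elif abs(icoef) == 1:
            text = body
        else:
            text = f"{abs(icoef)}*{body}"
        parts.append(("- " if icoef < 0 else "+ ") + text)
    head = parts[0][2:] if parts[0].startswith("+ ") else "-" + parts[0][2:]
    return " ".join([head] + parts[1:])


def _fmt_prob(c: float) -> str:
    return repr(c) if c != int(c) else str(int(c))


def emit_model(net: CSPBN, u0: Sequence[int]) -> PrismModel:
    """Generate the complete PRISM MDP source for a CS-PBN.

    ``u0`` is the initial control-input vector ``u(0)`` (length ``m``),
    which the PRISM encoding requires up front.  The output contains
    ``2n + m`` modules: a selection-chain and a state module per gene
    and a four-command nondeterministic module per input.
    """
    problems = validate(net)
    if problems:
        raise ValueError("invalid network: " +
                         "; ".join(str(p) for p in problems))
    u0 = tuple(int(v) for v in u0)
    if len(u0) != net.m or any(v not in (0, 1) for v in u0):
        raise ValueError(f"u0 must be a binary vector of length {net.m}")

    rename = _safe_names(net)
    renamed = {k: v for k, v in rename.items() if k != v}
    lines: list[str] = ["mdp", "", f"const double q = {_fmt_prob(net.q)};", ""]
    module_names: list[str] = []

    for i, gene in enumerate(net.genes, start=1):
        d = f"d{i}"
        mod = f"CSPBNm{i}"
        module_names.append(mod)
        lines.append(f"module {mod}")
        lines.append(f"  {d} : [1..{gene.l}] init {net.j0[i - 1]};")
        for j_from in range(1, gene.l + 1):
            branches = []
            for j_to in range(1, gene.l + 1):
                c = gene.candidates[j_to - 1].prob
                p = f"{_fmt_prob(c)}*q"
                if j_to == j_from:
                    p += " + (1-q)"
                branches.append(f"{p} : ({d}'={j_to})")
            lines.append(f"  [{SYNC_LABEL}] {d}={j_from} -> " +
                         " + ".join(branches) + ";")
        lines.append("endmodule")
        lines.append("")

    for i, gene in enumerate(net.genes, start=1):
        x = rename[gene.name]
        d = f"d{i}"
        mod = f"CSPBN{i}"
        module_names.append(mod)
        lines.append(f"module {mod}")
        lines.append(f"  {x} : [0..1] init {net.x0[i - 1]};")
        for j, cand in enumerate(gene.candidates, start=1):
            poly = _poly_prism(to_polynomial(cand.expr), rename)
            lines.append(f"  [{SYNC_LABEL}] {d}={j} -> 1.0 : ({x}'={poly});")
        lines.append("endmodule")
        lines.append("")

    for j, name in enumerate(net.inputs, start=1):
        u = rename[name]
        mod = f"input{j}"
        module_names.append(mod)
        lines.append(f"module {mod}")
        lines.append(f"  {u} : [0..1] init {u0[j - 1]};")
        for cur in (0, 1):
            for nxt in (0, 1):
                lines.append(f"  [{SYNC_LABEL}] {u}={cur} -> ({u}'={nxt});")
        lines.append("endmodule")
        lines.append("")

    return PrismModel(source="\n".join(lines),
                      module_names=tuple(module_names),
                      renamed=renamed)


def emit_property(spec: ReachabilitySpec, net: CSPBN | None = None,
                  unbounded: bool = False) -> str:
    """Render the bounded (or unbounded) maximum-reachability property.

    Produces ``Pmax=?[F<=N (xj=v)&...]`` over the spec's output genes;
    with ``unbounded`` the step bound is omitted.  Gene names come from
    ``net`` when given, else the canonical ``x<j>``.
    """
    atoms = []
    for j, v in zip(spec.output_indices, spec.target):
        if net is not None:
            name = _safe_names(net)[net.genes[j - 1].name]
        else:
            name = f"x{j}"
        atoms.append(f"({name}={v})")
    cond = "&".join(atoms)
    op = "F" if unbounded else f"F<={spec.horizon}"
    return f"Pmax=?[{op} {cond}]"
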