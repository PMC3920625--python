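"""Multilinear polynomial extensions of Boolean expressions.

Every Boolean function has a unique *multilinear extension*: the real
polynomial, affine in each variable, that agrees with the function on
all binary points.  It is obtained by the rewrite rules

    NOT a   ->  1 - a
    a OR b  ->  a + b - a*b
    a AND b ->  a * b

with idempotent powers reduced via ``a**2 = a``.  Evaluated at a point
of the unit hypercube whose coordinates are independent Bernoulli
success probabilities, the extension equals the expectation of the
Boolean function — which is what the expected-state recursion of the
network exploits.
"""

from __future__ import annotations

from typing import Mapping

from .model import And, BoolExpr, Const, Not, Or, Var

__all__ = ["MultilinearPoly", "to_polynomial", "evaluate_poly"]

Monomial = frozenset  # set of variable names; the empty set is the constant term


class MultilinearPoly:
    """Sparse multilinear polynomial: monomial (a set of variables,
    each with exponent one) mapped to a real coefficient.

    The representation is canonical — zero coefficients are dropped —
    so two polynomials are equal iff they are structurally equal.
    """

    __slots__ = ("terms",)

    def __init__(self, terms: Mapping[Monomial, float] | None = None):
        cleaned = {}
        if terms:
            for mono, coef in terms.items():
                if coef != 0:
                    cleaned[frozenset(mono)] = coef
        self.terms: dict[Monomial, float] = cleaned

    # -- constructors -----------------------------------------------------
    @classmethod
    def constant(cls, value: float) -> "MultilinearPoly":
        return cls({frozenset(): value})

    @classmethod
    def variable(cls, name: str) -> "MultilinearPoly":
        return cls({frozenset({name}): 1.0})

    # -- algebra ----------------------------------------------------------
    def __add__(self, other: "MultilinearPoly") -> "MultilinearPoly":
        terms = dict(self.terms)
        for mono, coef in other.terms.items():
            terms[mono] = terms.get(mono, 0.0) + coef
        return MultilinearPoly(terms)

    def __sub__(self, other: "MultilinearPoly") -> "MultilinearPoly":
        terms = dict(self.terms)
        for mono, coef in other.terms.items():
            terms[mono] = terms.get(mono, 0.0) - coef
        return MultilinearPoly(terms)

    def __mul__(self, other: "MultilinearPoly") -> "MultilinearPoly":
        # frozenset union implements the idempotent reduction x**2 = x
        terms: dict[Monomial, float] = {}
        for m1, c1 in self.terms.items():
            for m2, c2 in other.terms.items():
                mono = m1 | m2
                terms[mono] = terms.get(mono, 0.0) + c1 * c2
        return MultilinearPoly(terms)

    def scale(self, factor: float) -> "MultilinearPoly":
        return MultilinearPoly({m: factor * c for m, c in self.terms.items()})

    def __eq__(self, other) -> bool:
        return isinstance(other, MultilinearPoly) and self.terms == other.terms

    def __hash__(self):
        return hash(frozenset(self.terms.items()))

    # -- inspection -------------------------------------------------------
    def variables(self) -> frozenset[str]:
        out: set[str] = set()
        for mono in self.terms:
            out |= mono
        return frozenset(out)

    def coefficient(self, *names: str) -> float:
        """Coefficient of the monomial over ``names`` (no names: constant)."""
        return self.terms.get(frozenset(names), 0.0)

    def __call__(self, assignment: Mapping[str, float]) -> float:
        return evaluate_poly(self, assignment)

    def __str__(self) -> str:
        if not self.terms:
            return "0"
        # deterministic ordering: by degree, then lexicographically
        keys = sorted(self.terms, key=lambda m: (len(m), sorted(m)))
        chunks = []
        for mono in keys:
            coef = self.terms[mono]
            body = "*".join(sorted(mono))
            if not mono:
                text = _fmt_num(abs(coef))
            elif abs(coef) == 1:
                text = body
            else:
                text = f"{_fmt_num(abs(coef))}*{body}"
            sign = "-" if coef < 0 else "+"
            chunks.append((sign, text))
        head_sign, head = chunks[0]
        out = ("-" if head_sign == "-" else "") + head
        for sign, text in chunks[1:]:
            out += f" {sign} {text}"
        return out

    def __repr__(self) -> str:
        return f"MultilinearPoly({self})"


def _fmt_num(value: float) -> str:
    if value == int(value):
        return str(int(value))
    return repr(value)


def to_polynomial(expr: BoolExpr) -> MultilinearPoly:
    """Convert a Boolean expression to its multilinear extension.

    The result agrees with the Boolean evaluation on every binary
    assignment; like terms are collected and zero coefficients dropped.
    For a Boolean-derived polynomial all coefficients are integers.
    """
    if isinstance(expr, Var):
        return MultilinearPoly.variable(expr.name)
    if isinstance(expr, Const):
        return MultilinearPoly.constant(float(expr.value))
    if isinstance(expr, Not):
        return MultilinearPoly.constant(1.0) - to_polynomial(expr.arg)
    if isinstance(expr, And):
        out = to_polynomial(expr.args[0])
        for a in expr.args[1:]:
            out = out * to_polynomial(a)
        return out
    if isinstance(expr, Or):
        out = to_polynomial(expr.args[0])
        for a in expr.args[1:]:
            p = to_polynomial(a)
            out = out + p - out * p
        return out
    raise TypeError(f"not a Boolean expression node: {expr!r}")


def evaluate_poly(poly: MultilinearPoly,
                  assignment: Mapping[str, float]) -> float:
    """Evaluate a multilinear polynomial at a (possibly fractional) point.

    Every variable occurring in ``poly`` must be assigned; a missing one
    raises ``KeyError`` naming the variable.  For polynomials derived
    from Boolean expressions and assignments inside the unit hypercube,
    the value lies in ``[0, 1]``.
    """
    total = 0.0
    for mono, coef in poly.terms.items():
        prod = coef
        for name in mono:
            if name not in assignment:
                raise KeyError(f"no value assigned to variable {name!r}")
            prod *= assignment[name]
        total += prod
    return total
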