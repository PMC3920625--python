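"""Context-sensitive probabilistic Boolean network (CS-PBN) models.

A CS-PBN describes a gene regulatory network in which each gene ``x_i``
has ``l(i)`` candidate Boolean update functions ``f_j^(i)(x, u)`` with
selection probabilities ``c_j^(i)`` summing to one, and in which the
currently selected function is re-drawn only with *switching probability*
``q`` per time step (with probability ``1 - q`` each gene keeps its
current function).  Binary control inputs ``u_1..u_m`` may appear in the
update expressions.

This module defines the Boolean-expression AST, its parser/printer, the
network container :class:`CSPBN`, semantic validation, and a YAML-based
plain-text file format with full round-trip fidelity.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence, Union

import yaml

__all__ = [
    "BoolExpr",
    "Var",
    "Const",
    "Not",
    "And",
    "Or",
    "CandidateFunction",
    "GeneSpec",
    "CSPBN",
    "Violation",
    "ExprSyntaxError",
    "UnknownVariableError",
    "ModelFormatError",
    "CapacityError",
    "parse_expr",
    "validate",
    "read_model",
    "write_model",
    "loads_model",
    "dumps_model",
]

#: Tolerance for "candidate probabilities sum to one" checks.
PROB_TOL = 1e-9


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class ExprSyntaxError(ValueError):
    """Raised on malformed Boolean-expression text.

    ``position`` is the 0-based character offset of the offending token.
    """

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class UnknownVariableError(ValueError):
    """Raised when an expression references an undeclared identifier."""

    def __init__(self, name: str, position: int = -1):
        loc = f" (at position {position})" if position >= 0 else ""
        super().__init__(f"unknown identifier {name!r}{loc}")
        self.name = name
        self.position = position


class ModelFormatError(ValueError):
    """Raised on a malformed or semantically invalid model file."""


class CapacityError(RuntimeError):
    """Raised when a problem exceeds a configured enumeration cap."""


# ---------------------------------------------------------------------------
# Boolean expression AST
# ---------------------------------------------------------------------------

class BoolExpr:
    """Base class for Boolean-expression nodes.

    Supported connectives are negation, conjunction and disjunction plus
    the constants 0/1; this is the fragment the network update functions
    are written in.
    """

    __slots__ = ()

    def evaluate(self, env: Mapping[str, int]) -> int:
        raise NotImplementedError

    def variables(self) -> frozenset[str]:
        raise NotImplementedError

    # precedence used by the printer: Or=0, And=1, Not=2, atom=3
    _prec = 3

    def _fmt(self) -> str:
        raise NotImplementedError

    def __str__(self) -> str:
        return self._fmt()

    def __repr__(self) -> str:
        return f"{type(self).__name__}({self._fmt()!r})"


@dataclass(frozen=True, repr=False)
class Var(BoolExpr):
    name: str

    def evaluate(self, env: Mapping[str, int]) -> int:
        try:
            return int(env[self.name])
        except KeyError:
            raise UnknownVariableError(self.name) from None

    def variables(self) -> frozenset[str]:
        return frozenset({self.name})

    def _fmt(self) -> str:
        return self.name


@dataclass(frozen=True, repr=False)
class Const(BoolExpr):
    value: int

    def __post_init__(self):
        if self.value not in (0, 1):
            raise ValueError(f"Boolean constant must be 0 or 1, got {self.value}")

    def evaluate(self, env: Mapping[str, int]) -> int:
        return self.value

    def variables(self) -> frozenset[str]:
        return frozenset()

    def _fmt(self) -> str:
        return str(self.value)


@dataclass(frozen=True, repr=False)
class Not(BoolExpr):
    arg: BoolExpr
    _prec = 2

    def evaluate(self, env: Mapping[str, int]) -> int:
        return 1 - self.arg.evaluate(env)

    def variables(self) -> frozenset[str]:
        return self.arg.variables()

    def _fmt(self) -> str:
        inner = self.arg._fmt()
        if self.arg._prec < self._prec:
            inner = f"({inner})"
        return f"!{inner}"


@dataclass(frozen=True, repr=False)
class And(BoolExpr):
    args: tuple[BoolExpr, ...]
    _prec = 1

    def __post_init__(self):
        if len(self.args) < 2:
            raise ValueError("And requires at least two operands")

    def evaluate(self, env: Mapping[str, int]) -> int:
        out = 1
        for a in self.args:
            out &= a.evaluate(env)
        return out

    def variables(self) -> frozenset[str]:
        return frozenset().union(*(a.variables() for a in self.args))

    def _fmt(self) -> str:
        parts = [
            f"({a._fmt()})" if a._prec < self._prec else a._fmt()
            for a in self.args
        ]
        return " & ".join(parts)


@dataclass(frozen=True, repr=False)
class Or(BoolExpr):
    args: tuple[BoolExpr, ...]
    _prec = 0

    def __post_init__(self):
        if len(self.args) < 2:
            raise ValueError("Or requires at least two operands")

    def evaluate(self, env: Mapping[str, int]) -> int:
        out = 0
        for a in self.args:
            out |= a.evaluate(env)
        return out

    def variables(self) -> frozenset[str]:
        return frozenset().union(*(a.variables() for a in self.args))

    def _fmt(self) -> str:
        parts = [
            f"({a._fmt()})" if a._prec < self._prec else a._fmt()
            for a in self.args
        ]
        return " | ".join(parts)


# ---------------------------------------------------------------------------
# Expression parser (grammar: `!` binds tighter than `&` tighter than `|`)
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\s*(?:(?P<ident>[A-Za-z_][A-Za-z_0-9]*)|(?P<op>[!&|()])"
                       r"|(?P<const>[01]))")

_Token = tuple[str, str, int]  # (kind, text, position)


def _tokenize(text: str) -> list[_Token]:
    tokens: list[_Token] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.end() == pos:
            # skip leading whitespace-only tail
            rest = text[pos:]
            if rest.strip() == "":
                break
            bad = pos + len(rest) - len(rest.lstrip())
            raise ExprSyntaxError(f"unexpected character {text[bad]!r}", bad)
        kind = m.lastgroup
        tokens.append((kind, m.group(kind), m.start(kind)))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, tokens: list[_Token], text: str,
                 vocabulary: frozenset[str] | None):
        self.tokens = tokens
        self.text = text
        self.vocab = vocabulary
        self.i = 0

    def peek(self) -> _Token | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> _Token:
        tok = self.peek()
        if tok is None:
            raise ExprSyntaxError("unexpected end of expression", len(self.text))
        self.i += 1
        return tok

    def parse(self) -> BoolExpr:
        expr = self.parse_or()
        tok = self.peek()
        if tok is not None:
            raise ExprSyntaxError(f"unexpected token {tok[1]!r}", tok[2])
        return expr

    def parse_or(self) -> BoolExpr:
        parts = [self.parse_and()]
        while (tok := self.peek()) is not None and tok[1] == "|":
            self.next()
            parts.append(self.parse_and())
        return parts[0] if len(parts) == 1 else Or(tuple(parts))

    def parse_and(self) -> BoolExpr:
        parts = [self.parse_factor()]
        while (tok := self.peek()) is not None and tok[1] == "&":
            self.next()
            parts.append(self.parse_factor())
        return parts[0] if len(parts) == 1 else And(tuple(parts))

    def parse_factor(self) -> BoolExpr:
        tok = self.next()
        kind, text, pos = tok
        if text == "!":
            return Not(self.parse_factor())
        if text == "(":
            inner = self.parse_or()
            closing = self.next()
            if closing[1] != ")":
                raise ExprSyntaxError(
                    f"expected ')', got {closing[1]!r}", closing[2])
            return inner
        if kind == "const":
            return Const(int(text))
        if kind == "ident":
            if self.vocab is not None and text not in self.vocab:
                raise UnknownVariableError(text, pos)
            return Var(text)
        raise ExprSyntaxError(f"unexpected token {text!r}", pos)


def parse_expr(text: str,
               vocabulary: Iterable[str] | None = None) -> BoolExpr:
    """Parse a Boolean expression string into an AST.

    Grammar: identifiers, ``!`` (NOT), ``&`` (AND), ``|`` (OR),
    parentheses and the literals ``0``/``1``; ``!`` binds tighter than
    ``&``, which binds tighter than ``|``.

    Parameters
    ----------
    text
        The expression, e.g. ``"!x2 & u"``.
    vocabulary
        Declared identifiers; when given, any other identifier raises
        :class:`UnknownVariableError` naming the offending token.
    """
    vocab = frozenset(vocabulary) if vocabulary is not None else None
    tokens = _tokenize(text)
    if not tokens:
        raise ExprSyntaxError("empty expression", 0)
    return _Parser(tokens, text, vocab).parse()


# ---------------------------------------------------------------------------
# Network containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CandidateFunction:
    """One candidate update rule ``f_j^(i)`` with selection probability
    ``c_j^(i)``."""

    expr: BoolExpr
    prob: float


@dataclass(frozen=True)
class GeneSpec:
    """A gene with its ordered candidate functions (``l(i) >= 1``)."""

    name: str
    candidates: tuple[CandidateFunction, ...]

    def __post_init__(self):
        object.__setattr__(self, "candidates", tuple(self.candidates))

    @property
    def l(self) -> int:
        """Number of candidate functions ``l(i)``."""
        return len(self.candidates)

    @property
    def probs(self) -> tuple[float, ...]:
        return tuple(c.prob for c in self.candidates)


@dataclass(frozen=True)
class CSPBN:
    """A context-sensitive probabilistic Boolean network.

    Attributes
    ----------
    genes
        Ordered gene specifications (count ``n``).
    inputs
        Ordered control-input names (count ``m``).
    q
        Switching probability in ``[0, 1]``: per step, each gene re-draws
        its update function from the candidate distribution with
        probability ``q`` and keeps the current one with ``1 - q``.
    x0
        Initial binary state, length ``n``.
    j0
        Initial 1-based candidate indices, length ``n`` (``j0[i]`` in
        ``1..l(i)``): the update function in effect at time ``k = 0``.
    """

    genes: tuple[GeneSpec, ...]
    inputs: tuple[str, ...]
    q: float
    x0: tuple[int, ...]
    j0: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "genes", tuple(self.genes))
        object.__setattr__(self, "inputs", tuple(self.inputs))
        object.__setattr__(self, "x0", tuple(int(v) for v in self.x0))
        object.__setattr__(self, "j0", tuple(int(v) for v in self.j0))

    @property
    def n(self) -> int:
        return len(self.genes)

    @property
    def m(self) -> int:
        return len(self.inputs)

    @property
    def gene_names(self) -> tuple[str, ...]:
        return tuple(g.name for g in self.genes)

    @property
    def names(self) -> tuple[str, ...]:
        """All declared identifiers: gene names followed by input names."""
        return self.gene_names + self.inputs

    def joint_state_count(self) -> int:
        """Size of the explicit joint space ``2^n * prod l(i) * 2^m``."""
        out = 2 ** self.n * 2 ** self.m
        for g in self.genes:
            out *= g.l
        return out

    def replace(self, **kwargs) -> "CSPBN":
        """Return a copy with the given fields replaced."""
        data = dict(genes=self.genes, inputs=self.inputs, q=self.q,
                    x0=self.x0, j0=self.j0)
        data.update(kwargs)
        return CSPBN(**data)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Violation:
    """One violated model invariant; ``gene`` is a 0-based index or None
    for network-level problems."""

    gene: int | None
    message: str

    def __str__(self) -> str:
        where = f"gene {self.gene + 1}" if self.gene is not None else "network"
        return f"[{where}] {self.message}"


_IDENT_RE = re.compile(r"^[A-Za-z_][A-Za-z_0-9]*$")


def validate(net: CSPBN) -> list[Violation]:
    """Check every model invariant; return all violations (empty if valid).

    Checks probability sums (tolerance ``1e-9``), probability and ``q``
    ranges, name uniqueness and well-formedness, ``x0``/``j0`` shapes and
    ranges, and that every expression references only declared names.
    The model is never mutated and probabilities are never renormalized.
    """
    out: list[Violation] = []
    names = list(net.gene_names) + list(net.inputs)
    seen: set[str] = set()
    for name in names:
        if not _IDENT_RE.match(name):
            out.append(Violation(None, f"invalid identifier {name!r}"))
        if name in seen:
            out.append(Violation(None, f"duplicate name {name!r}"))
        seen.add(name)

    if not (0.0 <= net.q <= 1.0):
        out.append(Violation(None, f"switching probability q={net.q} outside [0, 1]"))
    if len(net.x0) != net.n:
        out.append(Violation(None,
                             f"x0 has length {len(net.x0)}, expected n={net.n}"))
    if len(net.j0) != net.n:
        out.append(Violation(None,
                             f"j0 has length {len(net.j0)}, expected n={net.n}"))

    declared = frozenset(names)
    for i, gene in enumerate(net.genes):
        if gene.l < 1:
            out.append(Violation(i, "gene has no candidate functions"))
            continue
        total = math.fsum(c.prob for c in gene.candidates)
        if abs(total - 1.0) > PROB_TOL:
            out.append(Violation(
                i, f"candidate probabilities sum to {total:.10g}, expected 1"))
        for j, cand in enumerate(gene.candidates):
            if not (0.0 <= cand.prob <= 1.0):
                out.append(Violation(
                    i, f"candidate {j + 1} probability {cand.prob} outside [0, 1]"))
            undeclared = cand.expr.variables() - declared
            for name in sorted(undeclared):
                out.append(Violation(
                    i, f"candidate {j + 1} references undeclared variable {name!r}"))
        if i < len(net.x0) and net.x0[i] not in (0, 1):
            out.append(Violation(i, f"x0 entry {net.x0[i]} is not binary"))
        if i < len(net.j0) and not (1 <= net.j0[i] <= gene.l):
            out.append(Violation(
                i, f"j0 entry {net.j0[i]} outside 1..{gene.l}"))
    return out


# ---------------------------------------------------------------------------
# File format (YAML documents; schema shipped in docs/model-schema.json)
# ---------------------------------------------------------------------------

def _net_to_dict(net: CSPBN) -> dict:
    return {
        "genes": [
            {
                "name": g.name,
                "functions": [
                    {"expr": str(c.expr), "prob": c.prob}
                    for c in g.candidates
                ],
            }
            for g in net.genes
        ],
        "inputs": list(net.inputs),
        "q": net.q,
        "x0": list(net.x0),
        "j0": list(net.j0),
    }


def _require(doc: Mapping, key: str):
    if key not in doc:
        raise ModelFormatError(f"model file is missing required field {key!r}")
    return doc[key]


def _net_from_dict(doc: Mapping) -> CSPBN:
    if not isinstance(doc, Mapping):
        raise ModelFormatError("model document must be a mapping")
    raw_genes = _require(doc, "genes")
    inputs = _require(doc, "inputs")
    q = _require(doc, "q")
    x0 = _require(doc, "x0")
    j0 = _require(doc, "j0")
    if not isinstance(raw_genes, Sequence) or isinstance(raw_genes, str):
        raise ModelFormatError("'genes' must be a list")
    if not isinstance(inputs, Sequence) or isinstance(inputs, str):
        raise ModelFormatError("'inputs' must be a list of names")
    try:
        q = float(q)
    except (TypeError, ValueError):
        raise ModelFormatError(f"'q' must be a number, got {q!r}") from None

    names = []
    for gi, g in enumerate(raw_genes):
        if not isinstance(g, Mapping) or "name" not in g:
            raise ModelFormatError(f"genes[{gi}] must be a mapping with a 'name'")
        names.append(str(g["name"]))
    vocabulary = frozenset(names) | frozenset(str(s) for s in inputs)

    genes = []
    for gi, g in enumerate(raw_genes):
        if "functions" not in g:
            raise ModelFormatError(f"genes[{gi}] is missing 'functions'")
        cands = []
        for fi, f in enumerate(g["functions"]):
            if not isinstance(f, Mapping) or "expr" not in f or "prob" not in f:
                raise ModelFormatError(
                    f"genes[{gi}].functions[{fi}] needs 'expr' and 'prob'")
            try:
                expr = parse_expr(str(f["expr"]), vocabulary)
            except ValueError as exc:
                raise ModelFormatError(
                    f"genes[{gi}].functions[{fi}].expr: {exc}") from exc
            cands.append(CandidateFunction(expr, float(f["prob"])))
        genes.append(GeneSpec(str(g["name"]), tuple(cands)))

    try:
        net = CSPBN(
            genes=tuple(genes),
            inputs=tuple(str(s) for s in inputs),
            q=q,
            x0=tuple(int(v) for v in x0),
            j0=tuple(int(v) for v in j0),
        )
    except (TypeError, ValueError) as exc:
        raise ModelFormatError(f"malformed model fields: {exc}") from exc

    problems = validate(net)
    if problems:
        detail = "; ".join(str(p) for p in problems)
        raise ModelFormatError(f"model is semantically invalid: {detail}")
    return net


def dumps_model(net: CSPBN) -> str:
    """Serialize a network to YAML text (round-trip exact)."""
    return yaml.safe_dump(_net_to_dict(net), sort_keys=False,
                          default_flow_style=None)


def loads_model(text: str) -> CSPBN:
    """Parse YAML text into a validated :class:`CSPBN`."""
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ModelFormatError(f"not valid YAML: {exc}") from exc
    return _net_from_dict(doc)


def write_model(net: CSPBN, path) -> None:
    """Write a network file; see :func:`read_model`."""
    with open(path, "w") as fh:
        fh.write(dumps_model(net))


def read_model(path) -> CSPBN:
    """Read and validate a network file.

    The format is a YAML document with fields ``genes`` (name plus list
    of ``{expr, prob}``), ``inputs``, ``q``, ``x0``, ``j0``; a JSON
    Schema for it ships with the package documentation.  Raises
    :class:`ModelFormatError` naming the offending field, with any
    semantic violations from :func:`validate` embedded.
    """
    with open(path) as fh:
        return loads_model(fh.read())
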