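"""Gene-protein-reaction (GPR) rules.

A GPR rule is a boolean expression over gene identifiers that states when a
reaction's catalyst is available: ``AND`` joins subunits of a complex (all
required), ``OR`` joins isoenzymes (any suffices).  A reaction with no
association is always available, regardless of which genes are deleted.

Expressions are immutable trees.  The text dialect accepted by :func:`parse_gpr`
is the COBRA convention used in SBML notes fields::

    (YAL001C and YBR002W) or YCL003C

with ``and``/``or`` case-insensitive and parentheses for grouping.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Set, Tuple, Union

__all__ = [
    "GprExpression",
    "GeneRef",
    "BoolAnd",
    "BoolOr",
    "NoAssociation",
    "parse_gpr",
    "gpr_to_string",
]


@dataclass(frozen=True)
class GeneRef:
    """A single gene leaf: true iff the gene has not been deleted."""

    gene: str

    def evaluate(self, deleted: Set[str]) -> bool:
        return self.gene not in deleted

    def genes(self) -> frozenset:
        return frozenset((self.gene,))


@dataclass(frozen=True)
class BoolAnd:
    """Complex: every child must be available."""

    children: Tuple["GprExpression", ...]

    def __post_init__(self):
        if len(self.children) < 2:
            raise ValueError("AND node requires at least 2 children")

    def evaluate(self, deleted: Set[str]) -> bool:
        return all(c.evaluate(deleted) for c in self.children)

    def genes(self) -> frozenset:
        return frozenset().union(*(c.genes() for c in self.children))


@dataclass(frozen=True)
class BoolOr:
    """Isoenzymes: any child suffices."""

    children: Tuple["GprExpression", ...]

    def __post_init__(self):
        if len(self.children) < 2:
            raise ValueError("OR node requires at least 2 children")

    def evaluate(self, deleted: Set[str]) -> bool:
        return any(c.evaluate(deleted) for c in self.children)

    def genes(self) -> frozenset:
        return frozenset().union(*(c.genes() for c in self.children))


@dataclass(frozen=True)
class NoAssociation:
    """No gene association: the reaction is unaffected by any deletion."""

    def evaluate(self, deleted: Set[str]) -> bool:
        return True

    def genes(self) -> frozenset:
        return frozenset()


GprExpression = Union[GeneRef, BoolAnd, BoolOr, NoAssociation]

_TOKEN = re.compile(r"\(|\)|\band\b|\bor\b|[^\s()]+", re.IGNORECASE)


def _and(children: Iterable[GprExpression]) -> GprExpression:
    flat: list = []
    for c in children:
        flat.extend(c.children if isinstance(c, BoolAnd) else [c])
    return flat[0] if len(flat) == 1 else BoolAnd(tuple(flat))


def _or(children: Iterable[GprExpression]) -> GprExpression:
    flat: list = []
    for c in children:
        flat.extend(c.children if isinstance(c, BoolOr) else [c])
    return flat[0] if len(flat) == 1 else BoolOr(tuple(flat))


def parse_gpr(text: str) -> GprExpression:
    """Parse a COBRA-style rule string into an expression tree.

    Empty or whitespace-only text yields :class:`NoAssociation`.  Nested
    same-operator nodes are flattened, so ``A and (B and C)`` and
    ``A and B and C`` produce identical trees.
    """
    tokens = _TOKEN.findall(text or "")
    if not tokens:
        return NoAssociation()
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def take():
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> GprExpression:
        terms = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            take()
            terms.append(parse_and())
        return _or(terms)

    def parse_and() -> GprExpression:
        terms = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            take()
            terms.append(parse_atom())
        return _and(terms)

    def parse_atom() -> GprExpression:
        tok = peek()
        if tok is None:
            raise ValueError(f"unexpected end of GPR rule: {text!r}")
        if tok == "(":
            take()
            inner = parse_or()
            if peek() != ")":
                raise ValueError(f"unbalanced parentheses in GPR rule: {text!r}")
            take()
            return inner
        if tok in (")",) or tok.lower() in ("and", "or"):
            raise ValueError(f"malformed GPR rule near {tok!r}: {text!r}")
        return GeneRef(take())

    expr = parse_or()
    if pos != len(tokens):
        raise ValueError(f"trailing tokens in GPR rule: {text!r}")
    return expr


def gpr_to_string(expr: GprExpression) -> str:
    """Render an expression in the text dialect accepted by :func:`parse_gpr`.

    ``NoAssociation`` renders as the empty string.  The output re-parses to a
    tree with an identical truth table.
    """
    if isinstance(expr, NoAssociation):
        return ""
    if isinstance(expr, GeneRef):
        return expr.gene

    def render(e: GprExpression) -> str:
        if isinstance(e, GeneRef):
            return e.gene
        op = " and " if isinstance(e, BoolAnd) else " or "
        parts = []
        for c in e.children:
            s = render(c)
            if not isinstance(c, GeneRef):
                s = f"({s})"
            parts.append(s)
        return op.join(parts)

    return render(expr)
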