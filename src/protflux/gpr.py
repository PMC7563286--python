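"""Gene-protein-reaction (GPR) Boolean expressions.

A GPR rule links a reaction to the genes encoding its catalyst:
``AND`` joins subunits of an enzyme complex, ``OR`` joins isoenzymes.
Evaluated against quantitative expression levels, ``AND`` takes the
minimum of its children (a complex is limited by its scarcest subunit)
and ``OR`` the maximum (the most abundant isoenzyme carries the flux).

Genes without a measured level evaluate to the sentinel
:data:`UNMEASURED`; how that propagates is governed by a
:class:`MissingPolicy`.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from typing import Mapping, Union


class _Unmeasured:
    """Singleton sentinel for 'no expression level available'."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - repr cosmetics
        return "UNMEASURED"


#: Returned by :func:`evaluate_gpr` when no level can be assigned.
UNMEASURED = _Unmeasured()

GPRValue = Union[float, _Unmeasured]


class MissingPolicy(str, enum.Enum):
    """How unmeasured genes propagate through a GPR tree.

    unbounded
        An unmeasured ``OR`` branch is ignored when a measured sibling
        exists (evidence from the measured isoenzyme is kept); an
        unmeasured ``AND`` child makes the whole complex unmeasured,
        so the constraint is dropped and default bounds apply.
    zero
        Unmeasured genes count as level 0 (absent protein).
    ignore
        Unmeasured leaves are dropped everywhere; an operator whose
        children are all unmeasured is itself unmeasured.
    """

    UNBOUNDED = "unbounded"
    ZERO = "zero"
    IGNORE = "ignore"


class GPRParseError(ValueError):
    """Raised for malformed GPR text; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class Gene:
    id: str

    def genes(self) -> set[str]:
        return {self.id}

    def unparse(self) -> str:
        return self.id


@dataclass(frozen=True)
class And:
    children: tuple["GPRExpression", ...]

    def __post_init__(self):
        if len(self.children) < 2:
            raise ValueError("AND node requires >= 2 children")

    def genes(self) -> set[str]:
        return set().union(*(c.genes() for c in self.children))

    def unparse(self) -> str:
        return "(" + " and ".join(c.unparse() for c in self.children) + ")"


@dataclass(frozen=True)
class Or:
    children: tuple["GPRExpression", ...]

    def __post_init__(self):
        if len(self.children) < 2:
            raise ValueError("OR node requires >= 2 children")

    def genes(self) -> set[str]:
        return set().union(*(c.genes() for c in self.children))

    def unparse(self) -> str:
        return "(" + " or ".join(c.unparse() for c in self.children) + ")"


GPRExpression = Union[Gene, And, Or]

_TOKEN_RE = re.compile(r"\s*(\(|\)|[^\s()]+)")


def _tokenize(text: str) -> list[tuple[str, int]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


def parse_gpr(text: str) -> GPRExpression:
    """Parse GPR text into an expression tree.

    Grammar: gene identifiers, ``and``/``or`` (case-insensitive; ``&&``
    and ``||`` accepted), parentheses.  ``and`` binds tighter than
    ``or``.  Raises :class:`GPRParseError` on malformed input.
    """
    tokens = _tokenize(text)
    if not tokens:
        raise GPRParseError("empty GPR expression", 0)

    idx = 0

    def peek():
        return tokens[idx] if idx < len(tokens) else (None, len(text))

    def is_op(tok: str | None, name: str) -> bool:
        if tok is None:
            return False
        low = tok.lower()
        return low == name or (name == "and" and tok == "&&") or (
            name == "or" and tok == "||"
        )

    def parse_or():
        nonlocal idx
        children = [parse_and()]
        while is_op(peek()[0], "or"):
            idx += 1
            children.append(parse_and())
        return children[0] if len(children) == 1 else Or(tuple(children))

    def parse_and():
        nonlocal idx
        children = [parse_atom()]
        while is_op(peek()[0], "and"):
            idx += 1
            children.append(parse_atom())
        return children[0] if len(children) == 1 else And(tuple(children))

    def parse_atom():
        nonlocal idx
        tok, pos = peek()
        if tok is None:
            raise GPRParseError("unexpected end of expression", pos)
        if tok == "(":
            idx += 1
            inner = parse_or()
            tok2, pos2 = peek()
            if tok2 != ")":
                raise GPRParseError("unbalanced parentheses", pos2)
            idx += 1
            return inner
        if tok == ")" or is_op(tok, "and") or is_op(tok, "or"):
            raise GPRParseError(f"unexpected token {tok!r}", pos)
        idx += 1
        return Gene(tok)

    expr = parse_or()
    tok, pos = peek()
    if tok is not None:
        raise GPRParseError(f"trailing token {tok!r}", pos)
    return expr


def evaluate_gpr(
    expr: GPRExpression,
    levels: Mapping[str, float],
    missing_policy: MissingPolicy | str = MissingPolicy.UNBOUNDED,
) -> GPRValue:
    """Evaluate a GPR tree to a numeric level under min/max semantics.

    ``AND`` -> min of children, ``OR`` -> max of children.  Genes
    absent from ``levels`` follow ``missing_policy`` (see
    :class:`MissingPolicy`).
    """
    policy = MissingPolicy(missing_policy)

    def ev(node: GPRExpression) -> GPRValue:
        if isinstance(node, Gene):
            if node.id in levels:
                return float(levels[node.id])
            if policy is MissingPolicy.ZERO:
                return 0.0
            return UNMEASURED
        vals = [ev(c) for c in node.children]
        measured = [v for v in vals if not isinstance(v, _Unmeasured)]
        any_unmeasured = len(measured) < len(vals)
        if isinstance(node, And):
            if policy is MissingPolicy.UNBOUNDED and any_unmeasured:
                # a complex with an unmeasured subunit cannot be bounded
                return UNMEASURED
            if not measured:
                return UNMEASURED
            return min(measured)
        # OR: unmeasured isoenzymes are ignored if a measured one exists
        if not measured:
            return UNMEASURED
        return max(measured)

    return ev(expr)
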