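"""Gene-protein-reaction (GPR) rule trees.

A GPR rule is a boolean formula over gene identifiers with ``and`` / ``or``
operators.  ``and`` models enzyme subunits (all gene products required),
``or`` models isoforms (any product suffices).  The parser respects the
standard precedence: ``and`` binds tighter than ``or`` unless parenthesized.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, FrozenSet, Iterator, Tuple, Union

__all__ = ["GPRRule", "Gene", "BoolOp", "GPRParseError", "parse_gpr"]


class GPRParseError(ValueError):
    """Raised when a GPR string cannot be parsed; carries the token position."""


@dataclass(frozen=True)
class Gene:
    """Leaf node: a single gene identifier (opaque string)."""

    name: str

    def genes(self) -> FrozenSet[str]:
        return frozenset({self.name})

    def evaluate(self, is_present: Callable[[str], bool]) -> bool:
        return bool(is_present(self.name))

    def to_string(self) -> str:
        return self.name


@dataclass(frozen=True)
class BoolOp:
    """Internal node: ``and`` (subunits) or ``or`` (isoforms) over >=2 children."""

    op: str  # "and" | "or"
    children: Tuple["GPRRule", ...]

    def __post_init__(self) -> None:
        if self.op not in ("and", "or"):
            raise ValueError(f"unknown GPR operator {self.op!r}")
        if len(self.children) < 2:
            raise ValueError("BoolOp requires at least 2 children")

    def genes(self) -> FrozenSet[str]:
        out: FrozenSet[str] = frozenset()
        for child in self.children:
            out = out | child.genes()
        return out

    def evaluate(self, is_present: Callable[[str], bool]) -> bool:
        results = (c.evaluate(is_present) for c in self.children)
        return all(results) if self.op == "and" else any(results)

    def to_string(self) -> str:
        sep = f" {self.op} "
        parts = []
        for child in self.children:
            text = child.to_string()
            if isinstance(child, BoolOp) and child.op != self.op:
                text = f"({text})"
            parts.append(text)
        return sep.join(parts)


GPRRule = Union[Gene, BoolOp]

_TOKEN_RE = re.compile(r"\s*(\(|\)|[^\s()]+)")


def _tokenize(text: str) -> Iterator[Tuple[int, str]]:
    pos = 0
    while pos < len(text):
        match = _TOKEN_RE.match(text, pos)
        if match is None:
            break
        yield match.start(1), match.group(1)
        pos = match.end()


class _Parser:
    # grammar:  expr := term ("or" term)* ; term := factor ("and" factor)* ;
    #           factor := GENE | "(" expr ")"
    def __init__(self, text: str):
        self.text = text
        self.tokens = list(_tokenize(text))
        self.index = 0

    def peek(self) -> Union[Tuple[int, str], None]:
        return self.tokens[self.index] if self.index < len(self.tokens) else None

    def advance(self) -> Tuple[int, str]:
        token = self.tokens[self.index]
        self.index += 1
        return token

    def fail(self, message: str) -> None:
        where = self.peek()
        pos = where[0] if where is not None else len(self.text)
        raise GPRParseError(f"{message} at position {pos} in {self.text!r}")

    def parse(self) -> GPRRule:
        if not self.tokens:
            self.fail("empty GPR rule")
        node = self.expr()
        if self.peek() is not None:
            self.fail(f"unexpected token {self.peek()[1]!r}")
        return node

    def expr(self) -> GPRRule:
        children = [self.term()]
        while self._eat_keyword("or"):
            children.append(self.term())
        return children[0] if len(children) == 1 else _flatten("or", children)

    def term(self) -> GPRRule:
        children = [self.factor()]
        while self._eat_keyword("and"):
            children.append(self.factor())
        return children[0] if len(children) == 1 else _flatten("and", children)

    def factor(self) -> GPRRule:
        token = self.peek()
        if token is None:
            self.fail("dangling operator")
        _, value = token
        if value == "(":
            self.advance()
            node = self.expr()
            closing = self.peek()
            if closing is None or closing[1] != ")":
                self.fail("unbalanced parenthesis")
            self.advance()
            return node
        if value == ")":
            self.fail("unbalanced parenthesis")
        if value.lower() in ("and", "or", "&", "|", "&&", "||"):
            self.fail(f"dangling operator {value!r}")
        self.advance()
        return Gene(value)

    def _eat_keyword(self, keyword: str) -> bool:
        token = self.peek()
        if token is None:
            return False
        value = token[1].lower()
        aliases = {"and": ("and", "&", "&&"), "or": ("or", "|", "||")}[keyword]
        if value in aliases:
            self.advance()
            return True
        return False


def _flatten(op: str, children: list) -> BoolOp:
    flat: list = []
    for child in children:
        if isinstance(child, BoolOp) and child.op == op:
            flat.extend(child.children)
        else:
            flat.append(child)
    return BoolOp(op, tuple(flat))


def parse_gpr(rule_text: str) -> GPRRule:
    """Parse a GPR string into an evaluable tree.

    ``and`` binds tighter than ``or``; parentheses override.  Gene IDs are any
    whitespace-delimited tokens other than the operators and parentheses
    (colons, dots etc. are allowed, e.g. ``HGNC:4141``).

    Raises :class:`GPRParseError` (with position) on unbalanced parentheses or
    dangling operators.
    """
    return _Parser(rule_text).parse()


def simplify_without(rule: GPRRule, absent: FrozenSet[str]):
    """Partial-evaluate *rule* with genes in *absent* fixed to FALSE.

    Returns the simplified tree, or ``None`` when the whole rule evaluates to
    FALSE (the associated reaction cannot be catalyzed).
    """
    if isinstance(rule, Gene):
        return None if rule.name in absent else rule
    kept = []
    for child in rule.children:
        sub = simplify_without(child, absent)
        if sub is None:
            if rule.op == "and":
                return None  # a required subunit is gone
        else:
            kept.append(sub)
    if not kept:
        return None
    if len(kept) == 1:
        return kept[0]
    return BoolOp(rule.op, tuple(kept))
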