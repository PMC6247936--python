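"""Tokenizer, parser and renderer for KEGG-style module definitions.

A module definition is a logical expression over gene identifiers.  The
top level is an ordered sequence of *blocks* (reaction steps) separated by
spaces; a module is complete when every block is satisfied.  Within a
block:

* ``,`` separates interchangeable alternatives (OR),
* ``+`` joins subunits of a complex that must all be present (AND),
* ``-X`` marks subunit ``X`` as optional (not required for completeness),
* ``--`` denotes a gap step that demands no gene,
* parentheses group, and a space *inside* parentheses is a conjunction of
  sub-steps rather than a new top-level block.

Operator precedence, loosest to tightest: space < ``,`` < ``+``/``-``;
all operators are left-associative.

Identifiers are KEGG Orthology numbers (``K`` + five digits) or Enzyme
Commission numbers (1-4 dot-separated components, each a number or a ``-``
wildcard, e.g. ``1.1.1.1`` or ``1.1.1.-``).  A single definition uses one
namespace throughout.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from typing import Iterator

from .errors import DefinitionSyntaxError, NamespaceMismatch

__all__ = [
    "Namespace",
    "GeneToken",
    "LexKind",
    "Lexeme",
    "tokenize",
    "Node",
    "Leaf",
    "Alternatives",
    "Complex",
    "OptionalNode",
    "Gap",
    "Sequence",
    "Never",
    "DefinitionAST",
    "parse_definition",
    "render_definition",
    "count_blocks",
    "leaf_tokens",
]


class Namespace(enum.Enum):
    """Identifier namespace of a gene token or definition."""

    ORTHOLOG = "ortholog"  # KEGG Orthology K numbers
    ENZYME = "enzyme"      # Enzyme Commission numbers


_K_RE = re.compile(r"K\d{5}\Z")
_EC_RE = re.compile(r"\d+(?:\.(?:\d+|-)){0,3}\Z")

# Lexing patterns; EC identifiers may themselves contain '-' and '.', so the
# identifier alternatives are tried before the double-dash gap marker.
_SCAN_K = re.compile(r"K\d{5}")
_SCAN_EC = re.compile(r"\d+(?:\.(?:\d+|-)){0,3}")
_SCAN_SPACE = re.compile(r" +")


def _identifier_is_valid(identifier: str, namespace: Namespace) -> bool:
    if namespace is Namespace.ORTHOLOG:
        return bool(_K_RE.match(identifier))
    return bool(_EC_RE.match(identifier))


@dataclass(frozen=True)
class GeneToken:
    """A gene identifier in a fixed namespace.

    Tokens compare equal iff both namespace and identifier are equal.
    """

    namespace: Namespace
    identifier: str

    def __post_init__(self) -> None:
        if not _identifier_is_valid(self.identifier, self.namespace):
            raise ValueError(
                f"{self.identifier!r} is not a valid "
                f"{self.namespace.value} identifier"
            )

    @classmethod
    def of(cls, identifier: str, namespace: Namespace | None = None) -> "GeneToken":
        """Build a token, inferring the namespace from the identifier shape
        when it is not given."""
        if namespace is None:
            namespace = (
                Namespace.ORTHOLOG if _K_RE.match(identifier) else Namespace.ENZYME
            )
        return cls(namespace, identifier)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.identifier


class LexKind(enum.Enum):
    IDENT = "ident"
    LPAREN = "lparen"
    RPAREN = "rparen"
    SPACE = "space"
    COMMA = "comma"
    PLUS = "plus"
    MINUS = "minus"
    GAP = "gap"  # the literal "--"


@dataclass(frozen=True)
class Lexeme:
    kind: LexKind
    text: str
    pos: int  # 0-based character offset of the first character


_SINGLE = {
    "(": LexKind.LPAREN,
    ")": LexKind.RPAREN,
    ",": LexKind.COMMA,
    "+": LexKind.PLUS,
    "-": LexKind.MINUS,
}


def tokenize(definition_text: str) -> list[Lexeme]:
    """Lex a definition string into a lossless lexeme sequence.

    Concatenating the ``text`` of the returned lexemes reproduces the
    input exactly.  Raises :class:`DefinitionSyntaxError` with the 0-based
    offset of the first character outside the lexeme alphabet.
    """
    if not definition_text.strip():
        raise DefinitionSyntaxError("empty definition", 0)
    out: list[Lexeme] = []
    i, n = 0, len(definition_text)
    while i < n:
        c = definition_text[i]
        if c == "K":
            m = _SCAN_K.match(definition_text, i)
            if not m:
                raise DefinitionSyntaxError("malformed K number", i)
            out.append(Lexeme(LexKind.IDENT, m.group(), i))
            i = m.end()
        elif c.isdigit():
            m = _SCAN_EC.match(definition_text, i)
            assert m is not None
            out.append(Lexeme(LexKind.IDENT, m.group(), i))
            i = m.end()
        elif definition_text.startswith("--", i):
            out.append(Lexeme(LexKind.GAP, "--", i))
            i += 2
        elif c in _SINGLE:
            out.append(Lexeme(_SINGLE[c], c, i))
            i += 1
        elif c == " ":
            m = _SCAN_SPACE.match(definition_text, i)
            assert m is not None
            out.append(Lexeme(LexKind.SPACE, m.group(), i))
            i = m.end()
        else:
            raise DefinitionSyntaxError(f"unexpected character {c!r}", i)
    return out


# --------------------------------------------------------------------------
# AST node kinds


class Node:
    """Base class of definition expression-tree nodes."""

    __slots__ = ()


@dataclass(frozen=True)
class Leaf(Node):
    """A single gene requirement."""

    token: GeneToken


@dataclass(frozen=True)
class Alternatives(Node):
    """Interchangeable alternatives: satisfied when any child is."""

    children: tuple[Node, ...]


@dataclass(frozen=True)
class Complex(Node):
    """Protein complex: satisfied when all non-optional children are."""

    children: tuple[Node, ...]


@dataclass(frozen=True)
class OptionalNode(Node):
    """A subunit not required for completeness; never blocks satisfaction."""

    child: Node


@dataclass(frozen=True)
class Gap(Node):
    """A definition step with no gene requirement (``--``)."""


@dataclass(frozen=True)
class Sequence(Node):
    """Conjunction of sub-steps.  The root sequence's children are the
    top-level blocks; nested sequences arise from spaces inside
    parentheses."""

    children: tuple[Node, ...]


@dataclass(frozen=True)
class Never(Node):
    """An unsatisfiable placeholder produced when translating a definition
    whose source token has no image in the mapping.  ``source`` keeps the
    original identifier for rendering and diagnostics."""

    source: str


@dataclass(frozen=True)
class DefinitionAST:
    """A parsed module definition: a root block sequence plus namespace."""

    root: Sequence
    namespace: Namespace

    @property
    def blocks(self) -> tuple[Node, ...]:
        return self.root.children


# --------------------------------------------------------------------------
# Parser (recursive descent, precedence SPACE < COMMA < PLUS/MINUS)


class _Parser:
    def __init__(self, lexemes: list[Lexeme], namespace: Namespace):
        # Collapse runs of spaces: a SPACE lexeme acts as one separator.
        self.toks = lexemes
        self.ns = namespace
        self.i = 0

    def _peek(self) -> Lexeme | None:
        return self.toks[self.i] if self.i < len(self.toks) else None

    def _next(self) -> Lexeme:
        tok = self.toks[self.i]
        self.i += 1
        return tok

    def _expect_operand(self, where: int | None) -> None:
        raise DefinitionSyntaxError("expected an identifier or '('", where)

    def parse(self) -> Sequence:
        # strip leading/trailing spaces
        if self._peek() and self._peek().kind is LexKind.SPACE:
            self._next()
        blocks = [self.parse_block()]
        while True:
            tok = self._peek()
            if tok is None:
                break
            if tok.kind is LexKind.SPACE:
                self._next()
                if self._peek() is None:
                    break  # trailing whitespace
                blocks.append(self.parse_block())
            else:
                raise DefinitionSyntaxError(
                    f"unexpected {tok.text!r}", tok.pos
                )
        return Sequence(tuple(blocks))

    def parse_block(self) -> Node:
        return self.parse_alternatives()

    def parse_alternatives(self) -> Node:
        parts = [self.parse_complex_chain()]
        while (tok := self._peek()) is not None and tok.kind is LexKind.COMMA:
            self._next()
            parts.append(self.parse_complex_chain())
        if len(parts) == 1:
            return parts[0]
        return Alternatives(tuple(parts))

    def parse_complex_chain(self) -> Node:
        parts: list[Node] = []
        tok = self._peek()
        if tok is not None and tok.kind is LexKind.MINUS:
            # leading optional marker, e.g. "-K00002"
            self._next()
            parts.append(OptionalNode(self.parse_atom()))
        else:
            parts.append(self.parse_atom())
        while (tok := self._peek()) is not None and tok.kind in (
            LexKind.PLUS,
            LexKind.MINUS,
        ):
            op = self._next()
            operand = self.parse_atom()
            if op.kind is LexKind.MINUS:
                operand = OptionalNode(operand)
            parts.append(operand)
        if len(parts) == 1:
            return parts[0]
        return Complex(tuple(parts))

    def parse_atom(self) -> Node:
        tok = self._peek()
        if tok is None:
            self._expect_operand(None)
        if tok.kind is LexKind.IDENT:
            self._next()
            if not _identifier_is_valid(tok.text, self.ns):
                raise NamespaceMismatch(
                    f"identifier {tok.text!r} is not in the "
                    f"{self.ns.value} namespace"
                )
            return Leaf(GeneToken(self.ns, tok.text))
        if tok.kind is LexKind.GAP:
            self._next()
            return Gap()
        if tok.kind is LexKind.LPAREN:
            self._next()
            inner = self.parse_inner()
            closing = self._peek()
            if closing is None or closing.kind is not LexKind.RPAREN:
                raise DefinitionSyntaxError(
                    "unbalanced parentheses", tok.pos
                )
            self._next()
            return inner
        self._expect_operand(tok.pos)

    def parse_inner(self) -> Node:
        """Inside parentheses a space is a conjunction of sub-steps."""
        parts = [self.parse_alternatives()]
        while (tok := self._peek()) is not None and tok.kind is LexKind.SPACE:
            self._next()
            nxt = self._peek()
            if nxt is None or nxt.kind is LexKind.RPAREN:
                break
            parts.append(self.parse_alternatives())
        if len(parts) == 1:
            return parts[0]
        return Sequence(tuple(parts))


def parse_definition(
    definition_text: str, namespace: Namespace = Namespace.ORTHOLOG
) -> DefinitionAST:
    """Parse a definition string into an expression tree.

    Raises :class:`DefinitionSyntaxError` on malformed input and
    :class:`NamespaceMismatch` when an identifier does not belong to
    ``namespace``.
    """
    lexemes = tokenize(definition_text.strip())
    root = _Parser(lexemes, namespace).parse()
    return DefinitionAST(root, namespace)


# --------------------------------------------------------------------------
# Rendering.  Precedence levels: sequence 0 < alternatives 1 < complex 2
# < atom 3.  A node is parenthesized when its level is below the level its
# context requires, so redundant parentheses are normalized away.


def _level(node: Node) -> int:
    if isinstance(node, Sequence):
        return 0
    if isinstance(node, Alternatives):
        return 1
    if isinstance(node, Complex):
        return 2
    return 3  # Leaf, Gap, Never, OptionalNode (renders as prefixed atom)


def _render(node: Node, required: int) -> str:
    if isinstance(node, Leaf):
        return node.token.identifier
    if isinstance(node, Never):
        return node.source
    if isinstance(node, Gap):
        return "--"
    if isinstance(node, OptionalNode):
        # bare optional outside a complex chain: "-X"
        return "-" + _render(node.child, 3)
    if isinstance(node, Sequence):
        body = " ".join(_render(c, 1) for c in node.children)
    elif isinstance(node, Alternatives):
        body = ",".join(_render(c, 2) for c in node.children)
    elif isinstance(node, Complex):
        parts = []
        for j, child in enumerate(node.children):
            if isinstance(child, OptionalNode):
                parts.append(("-" if j else "-") + _render(child.child, 3))
            else:
                parts.append(("+" if j else "") + _render(child, 3))
        body = "".join(parts)
    else:  # pragma: no cover - exhaustive above
        raise TypeError(f"unknown node {node!r}")
    if _level(node) < required:
        return "(" + body + ")"
    return body


def render_definition(ast: DefinitionAST) -> str:
    """Render a tree back to canonical definition text.

    ``parse_definition(render_definition(ast))`` is structurally equal to
    ``ast``; whitespace and redundant parentheses are normalized.
    """
    return " ".join(_render(b, 1) for b in ast.root.children)


def count_blocks(ast: DefinitionAST, count_gaps: str = "excluded") -> int:
    """Number of top-level blocks of a definition.

    Gap (``--``) blocks demand no gene; with ``count_gaps="excluded"``
    (default) they do not count, with ``"as-satisfied"`` they do.
    """
    if count_gaps not in ("excluded", "as-satisfied"):
        raise ValueError(f"count_gaps={count_gaps!r}")
    blocks = ast.root.children
    if count_gaps == "as-satisfied":
        return len(blocks)
    return sum(1 for b in blocks if not isinstance(b, Gap))


def _iter_leaves(node: Node) -> Iterator[GeneToken]:
    if isinstance(node, Leaf):
        yield node.token
    elif isinstance(node, OptionalNode):
        yield from _iter_leaves(node.child)
    elif isinstance(node, (Sequence, Alternatives, Complex)):
        for child in node.children:
            yield from _iter_leaves(child)
    # Gap, Never: no tokens


def leaf_tokens(ast: DefinitionAST) -> frozenset[GeneToken]:
    """All gene tokens of a definition, including optional subunits."""
    return frozenset(_iter_leaves(ast.root))
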