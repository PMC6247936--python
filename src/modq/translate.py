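"""Translation of ortholog-based definitions to enzyme-based ones.

KEGG modules are defined over K numbers; enzyme-centric analyses need the
same definitions over EC numbers.  Given a K-to-EC mapping, every leaf is
replaced by the alternatives of its images; a K number with several EC
images becomes an OR over them, so any gene set satisfying the original
leaf has an EC image satisfying the translated one.  Translation is
performed leaf by leaf on the parsed tree, which preserves block structure
and parenthesization exactly.

K numbers with no image are handled by policy: ``KEEP_UNSATISFIABLE``
(default) replaces the leaf with an always-false sentinel so enzyme-based
completeness is never overstated; ``DROP_OPTIONALIZE`` marks the leaf
optional instead.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .errors import NamespaceMismatch
from .grammar import (
    Alternatives,
    Complex,
    DefinitionAST,
    Gap,
    GeneToken,
    Leaf,
    Namespace,
    Never,
    Node,
    OptionalNode,
    Sequence,
)

__all__ = ["UnmappedPolicy", "MappingTable", "translate_definition"]


class UnmappedPolicy(enum.Enum):
    KEEP_UNSATISFIABLE = "keep-unsatisfiable"
    DROP_OPTIONALIZE = "drop-optionalize"


@dataclass(frozen=True)
class MappingTable:
    """A many-to-many bipartite mapping between two identifier namespaces.

    ``pairs`` holds (from, to) identifier strings.  The binary-matrix view
    has one row per distinct from-identifier, one column per distinct
    to-identifier and a 1 exactly where a pair exists.
    """

    from_namespace: str
    to_namespace: str
    pairs: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.from_namespace == self.to_namespace:
            raise ValueError("mapping namespaces must be distinct")
        for a, b in self.pairs:
            if a == b:
                raise ValueError(f"self-pair {a!r}")

    def images(self, key: str) -> list[str]:
        """Sorted to-identifiers mapped from ``key``."""
        return sorted(b for a, b in self.pairs if a == key)

    def image_index(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for a, b in sorted(self.pairs):
            out.setdefault(a, []).append(b)
        return out

    def to_matrix(self) -> pd.DataFrame:
        """Binary matrix view: rows = from-tokens, cols = to-tokens."""
        rows = sorted({a for a, _ in self.pairs})
        cols = sorted({b for _, b in self.pairs})
        mat = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
        for a, b in self.pairs:
            mat.at[a, b] = 1
        return mat

    def __len__(self) -> int:
        return len(self.pairs)


def _translate_node(
    node: Node,
    index: dict[str, list[str]],
    policy: UnmappedPolicy,
    unmapped: list[str],
) -> Node:
    if isinstance(node, Leaf):
        images = index.get(node.token.identifier, [])
        if not images:
            unmapped.append(node.token.identifier)
            if policy is UnmappedPolicy.KEEP_UNSATISFIABLE:
                return Never(node.token.identifier)
            return OptionalNode(Never(node.token.identifier))
        leaves = [Leaf(GeneToken(Namespace.ENZYME, e)) for e in images]
        if len(leaves) == 1:
            return leaves[0]
        return Alternatives(tuple(leaves))
    if isinstance(node, (Gap, Never)):
        return node
    if isinstance(node, OptionalNode):
        return OptionalNode(_translate_node(node.child, index, policy, unmapped))
    if isinstance(node, Alternatives):
        return Alternatives(
            tuple(_translate_node(c, index, policy, unmapped) for c in node.children)
        )
    if isinstance(node, Complex):
        return Complex(
            tuple(_translate_node(c, index, policy, unmapped) for c in node.children)
        )
    if isinstance(node, Sequence):
        return Sequence(
            tuple(_translate_node(c, index, policy, unmapped) for c in node.children)
        )
    raise TypeError(f"unknown node {node!r}")


def translate_definition(
    ast: DefinitionAST,
    mapping: MappingTable,
    unmapped_policy: UnmappedPolicy = UnmappedPolicy.KEEP_UNSATISFIABLE,
) -> DefinitionAST:
    """Translate an ortholog-namespace definition to the enzyme namespace.

    Each K leaf becomes the OR of its EC images (a single leaf when the
    image is unique).  Block count and tree shape are preserved.  Unmapped
    K numbers follow ``unmapped_policy`` and are reported in a warning.
    """
    if ast.namespace is not Namespace.ORTHOLOG:
        raise NamespaceMismatch(
            f"can only translate ortholog definitions, got {ast.namespace.value}"
        )
    index = mapping.image_index()
    unmapped: list[str] = []
    root = _translate_node(ast.root, index, unmapped_policy, unmapped)
    assert isinstance(root, Sequence)
    if unmapped:
        warnings.warn(
            "unmapped K numbers in definition: " + ", ".join(sorted(set(unmapped))),
            UserWarning,
            stacklevel=2,
        )
    return DefinitionAST(root, Namespace.ENZYME)
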